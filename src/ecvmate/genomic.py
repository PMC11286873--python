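"""Genomic relationship (VanRaden) and ridge-regression BLUP.

The relationship matrix follows VanRaden's first method: with marker
dosages ``X`` (0/1/2), observed allele frequencies ``p`` and centred
scores ``Z = X - 2p``,

    G = Z Z' / (2 * sum_m p_m (1 - p_m)).

Markers observed to be monomorphic are excluded from both numerator and
denominator; frequencies are clipped to [0.01, 0.99] so the denominator
cannot collapse as selection drives markers toward fixation.

GEBVs come from an effects-space ridge-regression BLUP: marker effects
solve ``(X'X + lambda I) u = X'(y - ybar)`` with the ridge parameter
``lambda = sigma_e^2 / sigma_u^2`` estimated by restricted maximum
likelihood on the equivalent mixed model, worked in the rank-``q`` SVD
basis of the centred dosage matrix so the fit costs O(n m^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .population import HaplotypePopulation

__all__ = [
    "RelationshipMatrix",
    "VanRadenG",
    "vanraden_G",
    "GebvModel",
    "fit_rrblup",
    "predict_gebv",
]

logger = logging.getLogger(__name__)

_FREQ_CLIP = (0.01, 0.99)


@dataclass
class RelationshipMatrix:
    """Dense K x K VanRaden relationship matrix with its marker provenance."""

    G: np.ndarray
    marker_ids: tuple[str, ...]
    allele_freqs: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.G.shape[0]


class VanRadenG:
    """VanRaden relationship with lazy row evaluation.

    For large populations the full K x K matrix is never needed by the
    selectors — only rows of individuals that surface during the search —
    so rows are computed (and cached) on demand from the centred score
    matrix.
    """

    def __init__(
        self,
        dosage: np.ndarray,
        marker_ids: tuple[str, ...] | None = None,
        freqs: np.ndarray | None = None,
    ):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2:
            raise ValueError("dosage must be a K x M matrix")
        p = dosage.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
        if p.shape != (dosage.shape[1],):
            raise ValueError("one allele frequency per marker is required")
        keep = (p > 0.0) & (p < 1.0)
        if not keep.any():
            raise ValueError("all markers are monomorphic; relationship matrix undefined")
        p = np.clip(p[keep], *_FREQ_CLIP)
        self.marker_ids = (
            tuple(np.asarray(marker_ids)[keep]) if marker_ids is not None else tuple()
        )
        self.allele_freqs = p
        self._Z = dosage[:, keep] - 2.0 * p[None, :]
        self._denom = 2.0 * float(np.sum(p * (1.0 - p)))
        self._rows: dict[int, np.ndarray] = {}

    @classmethod
    def from_population(
        cls, pop: HaplotypePopulation, freqs: np.ndarray | None = None
    ) -> "VanRadenG":
        """Build from the population's neutral markers only.

        ``freqs`` fixes the centring allele frequencies (e.g. the founder
        generation's) instead of the observed current-generation ones, so
        that relatedness accumulated over generations of selection remains
        visible on the founder scale.
        """
        idx = pop.map.marker_indices
        if idx.size == 0:
            raise ValueError("population map contains no marker loci")
        ids = tuple(pop.map.locus_id[i] for i in idx)
        return cls(pop.dosage(idx), marker_ids=ids, freqs=freqs)

    @property
    def n_individuals(self) -> int:
        return self._Z.shape[0]

    def row(self, k: int) -> np.ndarray:
        cached = self._rows.get(k)
        if cached is None:
            cached = self._Z @ self._Z[k] / self._denom
            self._rows[k] = cached
        return cached

    def pair(self, k1: int, k2: int) -> float:
        if k1 in self._rows:
            return float(self._rows[k1][k2])
        if k2 in self._rows:
            return float(self._rows[k2][k1])
        return float(self._Z[k1] @ self._Z[k2] / self._denom)

    def full_matrix(self) -> np.ndarray:
        return self._Z @ self._Z.T / self._denom


def vanraden_G(pop: HaplotypePopulation) -> RelationshipMatrix:
    """Dense VanRaden relationship matrix from the population's markers."""
    lazy = VanRadenG.from_population(pop)
    return RelationshipMatrix(
        G=lazy.full_matrix(), marker_ids=lazy.marker_ids, allele_freqs=lazy.allele_freqs
    )


# ---------------------------------------------------------------------------
# RR-BLUP
# ---------------------------------------------------------------------------


@dataclass
class GebvModel:
    """Fitted ridge-BLUP marker-effect model.

    ``shrinkage`` is the ridge parameter lambda = sigma_e^2 / sigma_u^2;
    ``column_means`` are the training dosage means used for centring at
    prediction time.
    """

    marker_effects: np.ndarray
    intercept: float
    shrinkage: float
    column_means: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.marker_effects)):
            raise ValueError("marker effects must be finite")
        if self.shrinkage <= 0:
            raise ValueError("shrinkage must be strictly positive")


_LAMBDA_BOUNDS = (-18.0, 18.0)  # log-lambda search window


def fit_rrblup(
    markers: np.ndarray,
    phenotypes: np.ndarray,
    heritability_fallback: float = 0.5,
) -> GebvModel:
    """Fit ridge-regression BLUP with REML-estimated shrinkage.

    Restricted likelihood is profiled over lambda in the SVD basis of the
    centred dosage matrix: rotated components carry variance
    sigma_u^2 (s_i^2 + lambda) and the orthogonal complement sigma_u^2
    lambda, so the profile is one-dimensional and deterministic.  If the
    phenotypes are constant all effects are zero; if the REML surface is
    degenerate, lambda falls back to ``M (1 - h^2) / h^2`` with the
    configured heritability.
    """
    X = np.asarray(markers, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("markers must be n x M with one phenotype per row")
    n, m = X.shape
    mu = float(y.mean())
    col_means = X.mean(axis=0)
    fallback = m * (1.0 - heritability_fallback) / heritability_fallback
    if np.ptp(y) == 0.0:
        logger.warning("constant phenotypes: returning all-zero marker effects")
        return GebvModel(np.zeros(m), mu, fallback, col_means)

    Xc = X - col_means[None, :]
    yc = y - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    pos = s > 1e-10 * max(s.max(), 1.0)
    U, s, Vt = U[:, pos], s[pos], Vt[pos]
    q = s.size
    z = U.T @ yc
    rss_perp = max(float(yc @ yc - z @ z), 0.0)
    df_perp = n - 1 - q  # intercept absorbed by centring

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = s**2 + lam
        quad = float(np.sum(z**2 / d))
        logdet = float(np.sum(np.log(d)))
        if df_perp > 0:
            quad += rss_perp / lam
            logdet += df_perp * np.log(lam)
        sigma_u2 = quad / max(n - 1, 1)
        if sigma_u2 <= 0:
            return np.inf
        return 0.5 * (logdet + (n - 1) * np.log(sigma_u2))

    res = minimize_scalar(neg_restricted_ll, bounds=_LAMBDA_BOUNDS, method="bounded")
    if res.success and np.isfinite(res.fun):
        lam = float(np.exp(res.x))
    else:  # pragma: no cover - REML failure path
        logger.warning("REML did not converge; falling back to lambda=%.3g", fallback)
        lam = fallback
    effects = Vt.T @ (s / (s**2 + lam) * z)
    return GebvModel(marker_effects=effects, intercept=mu, shrinkage=lam, column_means=col_means)


def predict_gebv(model: GebvModel, markers: np.ndarray) -> np.ndarray:
    """GEBV per individual: intercept + centred dosages times effects."""
    X = np.asarray(markers, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.marker_effects.size:
        raise ValueError("marker columns do not match the trained model")
    return model.intercept + (X - model.column_means[None, :]) @ model.marker_effects
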