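"""Generalized least squares estimation of source mixing proportions.

The sink count vector ``x`` (depth ``C``) is modeled as multinomial with
taxon probabilities ``beta_j = sum_i alpha_i * gamma_ij`` — a convex
combination of the source relative-abundance profiles ``gamma_i`` plus an
unobserved source absorbed by a regression intercept.  On the count scale
this is the linear model

    x_j = at_0 + sum_i at_i * gamma_ij + eps_j,

with ``at_i = C * alpha_i`` and multinomial error covariance
``Cov(eps) = C * (diag(beta) - beta beta^T)``.  Plugging in the empirical
``beta_hat = x / C`` gives Sigma, and the GLS estimate

    alpha_hat = (1/C) (gamma^T Sigma^- gamma)^{-1} (gamma^T Sigma^- x),

where ``gamma`` is the N x (K+1) design matrix whose first column is all
ones.  Sigma is singular by construction (rank <= N-1), so Sigma^- is
either the Moore-Penrose pseudoinverse (default) or the ordinary inverse
after deleting one taxon row/column ("drop" mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .exceptions import (
    CollinearityError,
    DegenerateSampleError,
    EstimationError,
    SingularityError,
)
from .io import CommunitySet, SourceProfiles, profiles_from_counts

import logging

logger = logging.getLogger("mixtrack")

#: Relative singular-value cutoff for the pseudoinverse.
DEFAULT_PINV_RTOL = 1e-10
#: Condition-number ceiling beyond which a matrix is treated as singular.
CONDITION_LIMIT = 1e12
#: Max-norm distance below which two source profiles count as duplicates.
COLLINEARITY_TOL = 1e-12
#: Floor applied to fitted probabilities before normalization.
FITTED_PROB_FLOOR = 1e-12

__all__ = [
    "DesignMatrix",
    "MultinomialCovariance",
    "SigmaInverse",
    "MixingEstimate",
    "build_design_matrix",
    "multinomial_covariance",
    "regularized_inverse",
    "gls_solve",
    "postprocess_raw_estimates",
    "estimate_proportions",
]


@dataclass
class DesignMatrix:
    """N x (K+1) regression design: intercept column then source profiles."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] < 2:
            raise ValueError("design matrix must be N x (K+1) with K >= 1")
        if not np.allclose(m[:, 0], 1.0):
            raise ValueError("first design column must be identically 1")
        sums = m[:, 1:].sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("profile columns must each sum to 1")
        self.matrix = m

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1] - 1


@dataclass
class MultinomialCovariance:
    """Plug-in multinomial covariance Sigma of the sink counts.

    Sigma_jj = C * bh_j (1 - bh_j), Sigma_jk = -C * bh_j bh_k (j != k),
    with bh = x / C.  Symmetric, rows sum to 0, rank <= N - 1.
    """

    sigma: np.ndarray
    sink_counts: np.ndarray
    depth: int


@dataclass
class SigmaInverse:
    """Inverse operator for Sigma plus reduced-dimension bookkeeping.

    ``pinv`` mode applies the Moore-Penrose pseudoinverse through the
    eigendecomposition of Sigma (eigenvalues below rtol * max are treated
    as zero).  ``drop`` mode deletes taxon ``drop_index`` from Sigma and
    inverts the remainder; :meth:`reduce` drops the matching row from the
    design and the sink vector.
    """

    mode: Literal["pinv", "drop"]
    drop_index: Optional[int] = None
    #: True when the operator annihilates the all-ones direction — the
    #: case for the pseudoinverse of a multinomial covariance, whose rows
    #: sum to zero.  The solver then eliminates the intercept analytically.
    annihilates_ones: bool = False
    _basis: Optional[np.ndarray] = None      # eigenvectors kept (pinv)
    _eigenvalues: Optional[np.ndarray] = None
    _inverse: Optional[np.ndarray] = None    # dense inverse (drop)

    def reduce(self, arr: np.ndarray) -> np.ndarray:
        """Remove the dropped taxon row from a vector or matrix."""
        if self.mode == "pinv":
            return arr
        return np.delete(arr, self.drop_index, axis=0)

    def apply(self, arr: np.ndarray) -> np.ndarray:
        """Compute Sigma^- @ arr on the (possibly reduced) taxon space."""
        if self.mode == "pinv":
            proj = self._basis.T @ arr
            return self._basis @ (proj / self._eigenvalues[..., None]
                                  if arr.ndim == 2 else proj / self._eigenvalues)
        return self._inverse @ arr


def build_design_matrix(profiles: SourceProfiles) -> DesignMatrix:
    """Prepend the intercept column (the unobserved source) to the profiles."""
    gamma = profiles.profiles
    if gamma.shape[1] <= gamma.shape[0]:
        logger.warning(
            "N = %d taxa <= K = %d sources: the regression is weakly "
            "determined; proceeding anyway", gamma.shape[1], gamma.shape[0]
        )
    design = np.column_stack([np.ones(gamma.shape[1]), gamma.T])
    return DesignMatrix(design)


def multinomial_covariance(sink_counts: np.ndarray) -> MultinomialCovariance:
    """Plug-in covariance of the sink counts under the multinomial model."""
    x = np.asarray(sink_counts, dtype=float)
    depth = x.sum()
    if depth <= 0:
        raise DegenerateSampleError("sink has zero total count")
    beta_hat = x / depth
    sigma = depth * (np.diag(beta_hat) - np.outer(beta_hat, beta_hat))
    return MultinomialCovariance(sigma=sigma, sink_counts=x, depth=int(depth))


def regularized_inverse(
    cov: MultinomialCovariance,
    mode: Literal["pinv", "drop"] = "pinv",
    drop_index: Optional[int] = None,
    pinv_rtol: float = DEFAULT_PINV_RTOL,
) -> SigmaInverse:
    """Build an invertible surrogate for the singular covariance.

    ``pinv``: Moore-Penrose pseudoinverse with eigenvalues below
    ``pinv_rtol`` times the largest treated as zero.  ``drop``: delete one
    taxon row/column (default: the taxon with the largest sink count, for
    conditioning) and invert the remaining (N-1) x (N-1) block.
    """
    if mode == "pinv":
        w, v = np.linalg.eigh(cov.sigma)
        cutoff = pinv_rtol * max(w.max(), 0.0)
        keep = w > cutoff
        if not np.any(keep):
            raise SingularityError("covariance has no eigenvalue above the cutoff")
        basis = v[:, keep]
        ones = np.ones(cov.sigma.shape[0])
        annihilates = bool(
            np.linalg.norm(basis.T @ ones) < 1e-8 * np.sqrt(ones.size)
        )
        return SigmaInverse(mode="pinv", annihilates_ones=annihilates,
                            _basis=basis, _eigenvalues=w[keep])
    if mode == "drop":
        if drop_index is None:
            drop_index = int(np.argmax(cov.sink_counts))
        reduced = np.delete(np.delete(cov.sigma, drop_index, axis=0),
                            drop_index, axis=1)
        if np.linalg.cond(reduced) > CONDITION_LIMIT:
            raise SingularityError(
                "reduced covariance is numerically singular after dropping "
                f"taxon {drop_index}; use mode='pinv' instead"
            )
        return SigmaInverse(mode="drop", drop_index=drop_index,
                            _inverse=np.linalg.inv(reduced))
    raise ValueError(f"unknown inverse mode {mode!r}")


def _check_collinearity(profiles: SourceProfiles) -> None:
    gamma = profiles.profiles
    k = gamma.shape[0]
    for i in range(k):
        dist = np.max(np.abs(gamma[i + 1:] - gamma[i]), axis=1)
        hits = np.flatnonzero(dist < COLLINEARITY_TOL)
        if hits.size:
            j = i + 1 + int(hits[0])
            raise CollinearityError(
                f"source profiles {i} and {j} are identical; "
                "their proportions are not separable"
            )


def gls_solve(
    sink_counts: np.ndarray,
    design: DesignMatrix,
    sigma_inv: SigmaInverse,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the GLS normal equations; returns (alpha_tilde, alpha_hat_raw).

    ``alpha_tilde`` is on the count scale; ``alpha_hat_raw`` is
    ``alpha_tilde / C`` — the unconstrained estimate, before any clipping
    or renormalization.

    When the inverse operator annihilates the all-ones direction (the
    pseudoinverse of a multinomial covariance always does: Sigma's rows
    sum to zero), the intercept column is invisible to the quadratic form
    and the literal normal matrix is singular.  The sum of the regression
    equations over taxa, 1^T x = C = N * at_0 + sum_i at_i, is a
    zero-variance direction that any GLS solution must fit exactly; the
    solver therefore eliminates the intercept, solves the K-column system
    on the profile columns, and recovers at_0 = (C - sum_i at_i) / N.
    """
    x = np.asarray(sink_counts, dtype=float)
    depth = x.sum()
    g = sigma_inv.reduce(design.matrix)
    xr = sigma_inv.reduce(x)
    if sigma_inv.annihilates_ones:
        cols = g[:, 1:]
        normal = cols.T @ sigma_inv.apply(cols)
        if np.linalg.cond(normal) > CONDITION_LIMIT:
            raise SingularityError(
                "normal matrix gamma^T Sigma^- gamma is numerically singular "
                "(near-collinear sources or too few informative taxa)"
            )
        coeffs = np.linalg.solve(normal, cols.T @ sigma_inv.apply(xr))
        intercept = (depth - coeffs.sum()) / design.n_taxa
        alpha_tilde = np.concatenate([[intercept], coeffs])
    else:
        normal = g.T @ sigma_inv.apply(g)
        if np.linalg.cond(normal) > CONDITION_LIMIT:
            raise SingularityError(
                "normal matrix gamma^T Sigma^- gamma is numerically singular "
                "(near-collinear sources or too few informative taxa)"
            )
        alpha_tilde = np.linalg.solve(normal, g.T @ sigma_inv.apply(xr))
    return alpha_tilde, alpha_tilde / depth


def postprocess_raw_estimates(
    alpha_tilde: np.ndarray,
    depth: float,
    n_taxa: int,
    clip: bool = True,
) -> tuple[np.ndarray, float, bool]:
    """Map the unconstrained GLS solution onto the probability simplex.

    Observed proportions are ``alpha_tilde_i / C`` clipped at 0; the
    unknown-source proportion is ``N * alpha_tilde_0 / C`` (the intercept
    spread over all N taxa), clipped at 0.  The total is renormalized to 1.
    """
    alpha_tilde = np.asarray(alpha_tilde, dtype=float)
    observed = alpha_tilde[1:] / depth
    unknown = n_taxa * alpha_tilde[0] / depth
    clipped = False
    if clip:
        clipped = bool(np.any(observed < 0) or unknown < 0)
        observed = np.clip(observed, 0.0, None)
        unknown = max(unknown, 0.0)
    total = observed.sum() + unknown
    if total <= 0:
        raise EstimationError("all estimated contributions are <= 0")
    return observed / total, unknown / total, clipped


@dataclass
class MixingEstimate:
    """Result of the GLS fit.

    ``alpha_tilde`` / ``alpha_hat_raw`` are the unconstrained estimates on
    the count and proportion scales; ``alpha_observed`` plus
    ``alpha_unknown`` are the post-processed simplex proportions.
    ``fitted_beta`` holds the fitted sink taxon probabilities used by the
    directionality score.
    """

    alpha_tilde: np.ndarray
    alpha_hat_raw: np.ndarray
    alpha_observed: np.ndarray
    alpha_unknown: float
    fitted_beta: np.ndarray
    inverse_mode: str
    clipped: bool
    source_ids: list[str] = field(default_factory=list)

    @property
    def proportions(self) -> np.ndarray:
        """Unknown-first proportion vector (alpha_0, alpha_1..alpha_K)."""
        return np.concatenate([[self.alpha_unknown], self.alpha_observed])


def estimate_proportions(
    community: CommunitySet,
    inverse_mode: Literal["pinv", "drop"] = "pinv",
    drop_index: Optional[int] = None,
    pinv_rtol: float = DEFAULT_PINV_RTOL,
    clip: bool = True,
) -> MixingEstimate:
    """End-to-end GLS estimate of source contributions to the sink."""
    profiles = profiles_from_counts(community.source_counts)
    _check_collinearity(profiles)
    design = build_design_matrix(profiles)
    cov = multinomial_covariance(community.sink_counts)
    sigma_inv = regularized_inverse(cov, mode=inverse_mode,
                                    drop_index=drop_index, pinv_rtol=pinv_rtol)
    alpha_tilde, alpha_hat_raw = gls_solve(community.sink_counts, design, sigma_inv)
    observed, unknown, clipped = postprocess_raw_estimates(
        alpha_tilde, community.sink_depth, community.n_taxa, clip=clip
    )
    mu = design.matrix @ alpha_tilde
    floored = np.maximum(mu, FITTED_PROB_FLOOR)
    fitted_beta = floored / floored.sum()
    return MixingEstimate(
        alpha_tilde=alpha_tilde,
        alpha_hat_raw=alpha_hat_raw,
        alpha_observed=observed,
        alpha_unknown=unknown,
        fitted_beta=fitted_beta,
        inverse_mode=inverse_mode,
        clipped=clipped,
        source_ids=list(community.source_ids),
    )
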