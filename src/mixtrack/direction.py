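"""Source/sink directionality inference by Bayesian-network scoring.

When roles are unknown, each of the K+1 samples is tried as the sink
(Model k: X = S_k, sources = the rest).  Every candidate model is a star
graph of identical complexity, so the score is the unpenalized joint
log-likelihood

    log Pr(x, y_1..y_K) = log Pr(x | y_1..y_K) + sum_i log Pr(y_i),

where the conditional term uses the GLS-fitted sink probabilities and each
marginal term uses the plug-in MLE y_i / C_i.  The model with the maximum
joint log-likelihood designates the sink.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, xlogy

from .exceptions import DegenerateSampleError, DirectionalityError, MixtrackError
from .gls import MixingEstimate, estimate_proportions
from .io import UnlabeledSampleSet

logger = logging.getLogger("mixtrack")

__all__ = [
    "CandidateModelScore",
    "DirectionalityResult",
    "multinomial_log_pmf",
    "marginal_loglik",
    "conditional_loglik",
    "score_candidate_model",
    "infer_directionality",
    "write_directionality",
]


def multinomial_log_pmf(counts: np.ndarray, probs: np.ndarray) -> float:
    """Full multinomial log-pmf, including the combinatorial coefficient.

    Conventions: 0 * log 0 = 0; a positive count on a zero-probability
    taxon gives -inf.
    """
    counts = np.asarray(counts)
    probs = np.asarray(probs, dtype=float)
    if counts.shape != probs.shape:
        raise ValueError("counts and probs must have the same length")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(probs < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {probs.sum():.12g}, expected 1")
    if np.any((counts > 0) & (probs == 0)):
        return float("-inf")
    total = counts.sum()
    coeff = gammaln(total + 1) - gammaln(counts + 1).sum()
    return float(coeff + xlogy(counts, probs).sum())


def marginal_loglik(source_counts: np.ndarray) -> float:
    """log Pr(y_i) at the plug-in MLE probabilities y_i / C_i."""
    y = np.asarray(source_counts)
    total = y.sum()
    if total <= 0:
        raise DegenerateSampleError("source sample has zero total count")
    return multinomial_log_pmf(y, y / total)


def conditional_loglik(sink_counts: np.ndarray, estimate: MixingEstimate) -> float:
    """log Pr(x | y_1..y_K) at the GLS-fitted sink probabilities."""
    return multinomial_log_pmf(sink_counts, estimate.fitted_beta)


@dataclass
class CandidateModelScore:
    """Joint-likelihood score for one candidate sink assignment."""

    candidate_index: int
    sample_id: str
    conditional_loglik: float
    marginal_loglik_sum: float
    joint_loglik: float
    estimate: Optional[MixingEstimate]


@dataclass
class DirectionalityResult:
    """All K+1 candidate scores plus the selected sink."""

    scores: list[CandidateModelScore]
    selected_sink: int
    margin: float
    tie: bool

    @property
    def selected_sample_id(self) -> str:
        return self.scores[self.selected_sink].sample_id


def score_candidate_model(
    samples: UnlabeledSampleSet, k: int, **options
) -> CandidateModelScore:
    """Fit Model k (sample k as sink) and assemble its joint log-likelihood.

    A candidate whose GLS fit fails scores -inf rather than aborting the
    whole inference.
    """
    sample_id = samples.sample_ids[k]
    try:
        community = samples.as_community(k)
        estimate = estimate_proportions(community, **options)
        cond = conditional_loglik(community.sink_counts, estimate)
        marg = sum(marginal_loglik(row) for row in community.source_counts)
    except MixtrackError as exc:
        logger.warning("candidate sink %r failed to fit: %s", sample_id, exc)
        return CandidateModelScore(k, sample_id, float("-inf"), float("-inf"),
                                   float("-inf"), None)
    return CandidateModelScore(
        candidate_index=k,
        sample_id=sample_id,
        conditional_loglik=cond,
        marginal_loglik_sum=marg,
        joint_loglik=cond + marg,
        estimate=estimate,
    )


def infer_directionality(samples: UnlabeledSampleSet, **options) -> DirectionalityResult:
    """Score all K+1 candidate sink assignments and select the argmax.

    Ties are broken by the lowest sample index and flagged.
    """
    scores = [score_candidate_model(samples, k, **options)
              for k in range(samples.n_samples)]
    joints = np.array([s.joint_loglik for s in scores])
    if np.all(np.isneginf(joints)):
        raise DirectionalityError("every candidate sink assignment failed to fit")
    best = int(np.argmax(joints))
    finite = np.isfinite(joints)
    tie = bool(np.sum(joints == joints[best]) > 1)
    if finite.sum() > 1:
        margin = float(joints[best] - np.partition(joints[finite], -2)[-2])
    else:
        margin = float("inf")
    return DirectionalityResult(scores=scores, selected_sink=best,
                                margin=margin, tie=tie)


def write_directionality(result: DirectionalityResult, path) -> None:
    """Write the per-candidate score table as TSV."""
    import pandas as pd

    rows = [
        {
            "SampleID": s.sample_id,
            "ConditionalLogLik": s.conditional_loglik,
            "MarginalLogLikSum": s.marginal_loglik_sum,
            "JointLogLik": s.joint_loglik,
            "Selected": int(s.candidate_index == result.selected_sink),
        }
        for s in result.scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")
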