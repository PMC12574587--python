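"""Synthetic community generation for the fully simulated study design.

Each replicate draws K+1 source relative-abundance profiles (one of them
unobserved) from a symmetric Dirichlet, draws mixing proportions with a
major/minor structure — n_major major sources each contributing at least
10% and jointly exactly 90%, the residual 10% split between minor sources
and the unobserved source — mixes them into sink taxon probabilities
beta_j = sum_i alpha_i gamma_ij, and samples multinomial counts for the
sink and each observed source.  The unobserved source contributes to the
sink only through beta; its counts are never emitted.

Index convention: ``alpha_true[0]`` is always the unobserved source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import DegenerateSampleError, MixtrackError
from .io import CommunitySet, write_counts_table

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "draw_mixing_proportions",
    "draw_profiles",
    "mix_beta",
    "simulate_counts",
    "simulate_scenario1",
    "load_profiles_from_table",
]

#: Each major source must contribute at least this proportion.
MAJOR_FLOOR = 0.1
#: The major sources jointly contribute exactly this proportion.
MAJOR_MASS = 0.9


@dataclass
class SimulationConfig:
    """Free parameters of the synthetic study design.

    The study design fixes only the major/minor structure; taxon count,
    depths and Dirichlet concentrations are package defaults: N = 500
    taxa, all depths 1e5, sparse profiles (symmetric Dirichlet 0.5), and a
    flat Dirichlet(1) split of the residual minor mass.
    """

    K: int
    n_major: int
    N: int = 500
    sink_depth: int = 100_000
    source_depths: Union[int, Sequence[int]] = 100_000
    profile_concentration: float = 0.5
    minor_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (1 <= self.n_major <= self.K):
            raise ValueError("need 1 <= n_major <= K")
        if self.n_major * MAJOR_FLOOR > MAJOR_MASS + 1e-12:
            raise ValueError(
                f"infeasible constraint: {self.n_major} majors each >= "
                f"{MAJOR_FLOOR} cannot sum to {MAJOR_MASS}"
            )
        if self.N < 2:
            raise ValueError("N must be >= 2")
        depths = self.resolved_source_depths
        if self.sink_depth < 1 or np.any(depths < 1):
            raise ValueError("depths must be >= 1")
        if self.profile_concentration <= 0 or self.minor_concentration <= 0:
            raise ValueError("Dirichlet concentrations must be > 0")

    @property
    def resolved_source_depths(self) -> np.ndarray:
        if np.isscalar(self.source_depths):
            return np.full(self.K, int(self.source_depths))
        return np.asarray(self.source_depths, dtype=int)


@dataclass
class SimulationTruth:
    """Ground truth of one replicate; alpha_true[0] is the unobserved source."""

    alpha_true: np.ndarray
    gamma_true: np.ndarray
    community: CommunitySet
    major_indices: list[int]
    seed: int
    config: Optional[SimulationConfig] = None


def _draw_major_mass(n_major: int, rng: np.random.Generator,
                     max_redraws: int = 100_000) -> tuple[np.ndarray, int]:
    """Rejection-sample the major proportions: uniform on the simplex,
    scaled to total 0.9, accepted once every entry is >= 0.1."""
    if n_major == 1:
        return np.array([MAJOR_MASS]), 0
    for redraws in range(max_redraws):
        majors = MAJOR_MASS * rng.dirichlet(np.ones(n_major))
        if np.all(majors >= MAJOR_FLOOR):
            return majors, redraws
    raise MixtrackError("major-proportion rejection sampling did not terminate")


def draw_mixing_proportions(
    K: int,
    n_major: int,
    rng: np.random.Generator,
    minor_concentration: float = 1.0,
) -> np.ndarray:
    """Draw alpha_true of length K+1 (unobserved source first).

    The first n_major observed sources are the majors; the residual 0.1 is
    split across the K - n_major minor sources plus the unobserved source
    by a symmetric Dirichlet.
    """
    if n_major > int(MAJOR_MASS / MAJOR_FLOOR):
        raise ValueError(
            f"infeasible constraint: cannot have {n_major} majors each >= "
            f"{MAJOR_FLOOR} summing to {MAJOR_MASS}"
        )
    if n_major > K:
        raise ValueError("n_major must be <= K")
    majors, _ = _draw_major_mass(n_major, rng)
    n_residual = K - n_major + 1  # minors plus the unobserved source
    residual = (1.0 - MAJOR_MASS) * rng.dirichlet(
        np.full(n_residual, minor_concentration)
    )
    alpha = np.empty(K + 1)
    alpha[0] = residual[0]
    alpha[1:n_major + 1] = majors
    alpha[n_major + 1:] = residual[1:]
    return alpha


def draw_profiles(
    n_sources: int, N: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent symmetric-Dirichlet relative-abundance profiles (rows sum 1)."""
    if N < 2:
        raise ValueError("need at least 2 taxa")
    return rng.dirichlet(np.full(N, concentration), size=n_sources)


def mix_beta(alpha_true: np.ndarray, gamma_true: np.ndarray) -> np.ndarray:
    """Sink taxon probabilities beta_j = sum_i alpha_i gamma_ij."""
    alpha = np.asarray(alpha_true, dtype=float)
    gamma = np.asarray(gamma_true, dtype=float)
    if alpha.shape[0] != gamma.shape[0]:
        raise ValueError("alpha and gamma disagree on the number of sources")
    return alpha @ gamma


def simulate_counts(
    alpha_true: np.ndarray,
    gamma_true: np.ndarray,
    sink_depth: int,
    source_depths: Union[int, Sequence[int]],
    rng: np.random.Generator,
    taxon_ids: Optional[list[str]] = None,
) -> CommunitySet:
    """Sample sink and observed-source counts from the mixed-proportion model.

    gamma_true rows: index 0 the unobserved source, 1..K the observed
    sources. The unobserved source enters only through the sink's beta.
    """
    beta = mix_beta(alpha_true, gamma_true)
    K = gamma_true.shape[0] - 1
    depths = (np.full(K, int(source_depths)) if np.isscalar(source_depths)
              else np.asarray(source_depths, dtype=int))
    sink = rng.multinomial(int(sink_depth), beta)
    sources = np.vstack([
        rng.multinomial(int(depths[i]), gamma_true[i + 1]) for i in range(K)
    ])
    n = gamma_true.shape[1]
    return CommunitySet(
        taxon_ids=taxon_ids or [f"taxon_{j + 1}" for j in range(n)],
        sink_counts=sink,
        source_counts=sources,
        sink_id="sink",
        source_ids=[f"source_{i + 1}" for i in range(K)],
    )


def simulate_scenario1(
    config: SimulationConfig,
    out_prefix: Optional[Union[str, Path]] = None,
    profiles: Optional[np.ndarray] = None,
) -> SimulationTruth:
    """Generate one fully synthetic replicate.

    If ``profiles`` is given (K+1 x N, e.g. from a real table via
    :func:`load_profiles_from_table`), it replaces the Dirichlet profile
    draw for semi-synthetic simulation.  With ``out_prefix`` the counts
    table, role mapping and a truth JSON are written alongside.
    """
    rng = np.random.default_rng(config.seed)
    alpha = draw_mixing_proportions(config.K, config.n_major, rng,
                                    config.minor_concentration)
    if profiles is None:
        gamma = draw_profiles(config.K + 1, config.N,
                              config.profile_concentration, rng)
    else:
        gamma = np.asarray(profiles, dtype=float)
        if gamma.shape[0] != config.K + 1:
            raise ValueError("profiles must have K+1 rows (unobserved first)")
    community = simulate_counts(alpha, gamma, config.sink_depth,
                                config.resolved_source_depths, rng)
    truth = SimulationTruth(
        alpha_true=alpha,
        gamma_true=gamma,
        community=community,
        major_indices=list(range(1, config.n_major + 1)),
        seed=config.seed,
        config=config,
    )
    if out_prefix is not None:
        _write_truth(truth, Path(out_prefix))
    return truth


def _write_truth(truth: SimulationTruth, prefix: Path) -> None:
    community = truth.community
    sample_ids = community.source_ids + [community.sink_id]
    counts = np.column_stack([community.source_counts.T,
                              community.sink_counts])
    write_counts_table(f"{prefix}_counts.tsv", community.taxon_ids,
                       sample_ids, counts)
    with open(f"{prefix}_mapping.tsv", "w") as fh:
        fh.write("SampleID\tEnv\tSourceSink\n")
        for sid in community.source_ids:
            fh.write(f"{sid}\tsimulated\tsource\n")
        fh.write(f"{community.sink_id}\tsimulated\tsink\n")
    meta = {
        "alpha_true": truth.alpha_true.tolist(),
        "major_indices": truth.major_indices,
        "seed": truth.seed,
        "config": asdict(truth.config) if truth.config else None,
    }
    if meta["config"] is not None and not np.isscalar(
            meta["config"]["source_depths"]):
        meta["config"]["source_depths"] = list(
            map(int, meta["config"]["source_depths"]))
    with open(f"{prefix}_truth.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_profiles_from_table(path: Union[str, Path]) -> np.ndarray:
    """Read a counts or frequency table and return row-normalized profiles.

    Rows are taxa in the file; the returned matrix is samples x taxa with
    each row summing to 1, directly usable in place of a Dirichlet draw.
    """
    import pandas as pd

    from .exceptions import FormatError

    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    mat = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(mat)) or np.any(mat < 0):
        raise FormatError(f"{path}: table must hold non-negative numbers")
    totals = mat.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise DegenerateSampleError(
            f"sample column {df.columns[bad]!r} has zero total"
        )
    return mat / totals[:, None]
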