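import numpy as np
import pytest

import mixtrack as mt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts_tsv(tmp_path):
    """3 taxa x 2 samples with column sums (10, 10)."""
    path = tmp_path / "counts.tsv"
    path.write_text(
        "#TaxonID\tsampleA\tsampleB\n"
        "t1\t5\t0\n"
        "t2\t3\t2\n"
        "t3\t2\t8\n"
    )
    return path


@pytest.fixture
def noiseless_community():
    """Exact 30/70 mixture of two non-collinear sources, zero unknown.

    Depths chosen so the mixed probabilities times the sink depth are
    exact integers — no rounding noise anywhere.
    """
    g1 = np.array([0.4, 0.3, 0.2, 0.1])
    g2 = np.array([0.05, 0.15, 0.3, 0.5])
    alpha = np.array([0.3, 0.7])
    beta = alpha @ np.vstack([g1, g2])
    sink = np.round(beta * 20_000)
    assert np.allclose(sink, beta * 20_000)
    return mt.CommunitySet(
        taxon_ids=[f"t{j}" for j in range(4)],
        sink_counts=sink.astype(int),
        source_counts=np.vstack([(g1 * 10_000).astype(int),
                                 (g2 * 10_000).astype(int)]),
    ), alpha


def make_mixture_samples(rng, k=2, n_taxa=60, depth=50_000,
                         weights=None, concentration=0.5):
    """K source samples plus a sink that is a true mixture of them.

    A larger ``concentration`` keeps taxon probabilities away from zero,
    which guarantees positive counts everywhere (needed by drop-mode GLS).
    """
    gamma = rng.dirichlet(np.full(n_taxa, concentration), size=k)
    if weights is None:
        weights = rng.dirichlet(np.ones(k))
    beta = weights @ gamma
    sources = np.vstack([rng.multinomial(depth, gamma[i]) for i in range(k)])
    sink = rng.multinomial(depth, beta)
    return mt.UnlabeledSampleSet(
        taxon_ids=[f"t{j}" for j in range(n_taxa)],
        counts=np.vstack([sources, sink]),
        sample_ids=[f"S{i + 1}" for i in range(k + 1)],
    )
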