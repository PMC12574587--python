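# mixtrack

Microbial source tracking by generalized least squares, with
likelihood-based inference of source/sink directionality.

## The problem

A sink microbiome sample (a gut sample, a contaminated surface, a water
body) is often a mixture of several candidate source communities plus some
unknown contribution. Microbial source tracking asks: what fraction of the
sink is attributable to each source? Existing mixture-model tools answer
this with iterative EM or MCMC estimation, which scales poorly in the
number of sources — and none of them answer the converse question of
*which* sample is the sink when roles are not known in advance. mixtrack
targets both questions with a closed-form estimator, aimed at
microbiome researchers who have taxa-by-sample count tables (16S or
shotgun-derived) and SourceTracker-style metadata.

## The model

Let x be the sink count vector over N taxa with depth C = Σ_j x_j, and
y_1..y_K the source count vectors (depths C_i). The sink is multinomial,

    X ~ multinom(C, β),   β_j = Σ_{i=0}^{K} α_i γ_ij,

where γ_ij is the relative abundance of taxon j in source i (estimated by
y_i/C_i), α_i the mixing proportions, and i = 0 an unobserved source. With
an exchangeable unobserved contribution (α_0 γ_0j constant over j), the
count-scale means obey the linear regression

    x_j = α̃_0 + Σ_i α̃_i γ_ij + ε_j,   α̃_i = C α_i,

with multinomial error covariance Cov(ε) = C(diag(β) − ββᵀ). Plugging in
β̂ = x/C gives Σ, and the mixing proportions come from generalized least
squares:

    α̂ = (1/C) (γᵀ Σ⁻ γ)⁻¹ (γᵀ Σ⁻ x),

with γ the N×(K+1) design matrix whose first column is all ones. Σ is
singular by construction (rank ≤ N−1), so Σ⁻ is either the Moore–Penrose
pseudoinverse (default) or an ordinary inverse after deleting one taxon
row/column (`--inverse drop`). Negative coefficients are clipped to zero
and the vector renormalized; the unknown-source share is N·α̃_0/C.

When roles are unknown, each of the K+1 samples is tried as the sink and
the candidate star-graph models are scored by the Bayesian-network joint
likelihood

    log Pr(x, y_1..y_K) = log Pr(x | y_1..y_K) + Σ_i log Pr(y_i),

with the conditional term evaluated at the GLS-fitted sink probabilities
and each marginal at its plug-in MLE. All candidate graphs have equal
complexity, so no AIC/BIC penalty is needed; the argmax designates the
sink.

## Worked example

Simulate a community with 3 observed sources (2 major), estimate, and
infer directionality:

```sh
mixtrack simulate --k 3 --n-major 2 --n-taxa 200 --depth 50000 --seed 42 --out-prefix demo
mixtrack estimate --counts demo_counts.tsv --mapping demo_mapping.tsv --out demo_props.tsv
cat demo_props.tsv
```

```text
SourceID        Proportion      RawCoefficient
source_1        0.477684346511  0.477684346511
source_2        0.462349235422  0.462349235422
source_3        0.00323367828558        0.00323367828558
Unknown 0.0567327397814 0.000283663698907
```

The simulated truth (in `demo_truth.json`) was α = (0.089 unknown, 0.456,
0.444, 0.011): the two major sources are recovered within ~0.02 and the
minor source and unknown share are correctly small. The `Proportion`
column sums to 1; `RawCoefficient` is the unconstrained GLS value before
clipping (the Unknown row shows the raw intercept α̃_0/C).

```sh
mixtrack direction --counts demo_counts.tsv --out demo_dir.tsv
# selected sink: sink (margin 6102.48 log-units)
```

The per-candidate table in `demo_dir.tsv` shows the joint log-likelihood
of each sample as sink; the true sink wins by ~6100 log-units over the
best source-as-sink model.

The same operations are available as library calls
(`mixtrack.estimate_proportions`, `mixtrack.infer_directionality`,
`mixtrack.simulate_scenario1`), and `mixtrack benchmark` runs accuracy
sweeps over a grid of (K, n_major) settings.

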