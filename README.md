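# spikevar

Spike-in-calibrated technical-noise modelling, biological/technical variance
decomposition, and a simulation-based test for stochastic allele-specific
expression (ASE) in single-cell RNA-seq.

## The problem

Single-cell RNA-seq counts carry large technical noise: most mRNA molecules
are lost before sequencing (capture efficiencies of roughly 10–40%), and the
surviving molecules are observed through amplification and counting noise.
At low expression this technical noise alone produces dramatic apparent
cell-to-cell variability — including apparent monoallelic expression, where
one allele of a heterozygous gene seems silent in a cell purely because its
few molecules dropped out. Anyone quantifying transcriptional noise or
allele-specific expression in single cells needs to know how much of the
observed variability technical noise explains.

`spikevar` calibrates a generative noise model on external RNA spike-ins
(e.g. the ERCC mix), which are added at the same known quantity *n_s* to
every cell's lysate, so that all cross-cell variation in their counts is
technical.

## The model

For cell *c*, capture efficiency θ_c and sequencing efficiency γ_c are
i.i.d. across cells with moments (μ_θ, σ²_θ) and (μ_γ, σ²_γ), independent of
each other. An entity with true molecule count *m* in cell *c* is observed as

    z | m ~ Binomial(m, θ_c)        (stochastic dropout)
    x | z ~ Poisson(z · γ_c)        (amplification + shot noise)

By the law of total variance, for a gene whose true abundance has mean E[m]
and variance Var(m) across cells,

    E[x]   = E[m] · μ_η,      μ_η = μ_θ μ_γ
    Var(x) = E[m] · A + E[m]² · B + Var(m) · E[θ²] E[γ²]

    A = μ_θ μ_γ + (μ_θ − E[θ²]) E[γ²],     B = E[θ²] E[γ²] − μ_θ² μ_γ²

Spike-ins have constant m = n_s, so Var(x_s) = n_s·A + n_s²·B is purely
technical and identifies the four moment parameters. A gene's biological
variance follows by subtracting the technical terms from its observed
variance — no distributional assumption on the true molecule counts is
needed.

The same machinery simulates **pseudo cells** under a technical-only model
("T") or with added Gamma–Poisson biological variability ("T+B"). The
stochastic-ASE test estimates each allele's mean expression, simulates the
null distribution of the mean allelic ratio (most-expressed allele / total,
per cell, averaged over informative cells) under "T" with independent
alleles, and reports an add-one empirical p-value, calibrated for the
plug-in estimation of the allelic means.

## Worked example

Generate a ground-truthed synthetic experiment (100 cells, 92-species
spike-in dilution series, plus allele-level counts for 20 balanced, 5
imprinted-like and 5 stochastic-ASE genes), fit the noise model, and test
for stochastic ASE:

```sh
spikevar make-synthetic --outdir data --cells 100 --seed 7
spikevar fit-technical --counts data/counts.tsv \
    --spikeins data/spikein_reference.tsv --model-out model.json --seed 0
spikevar ase-test --alleles data/allele_counts.tsv --model model.json \
    --nsim 2000 --cells 100 --seed 1 --out ase.tsv
```

which prints

```
fitted: mu_theta=0.1028 var_theta=0.0002951 mu_gamma=0.6814 var_gamma=0.04804
tested 30 units, called 5 at alpha=0.001; monoallelic unit fraction 1.000
```

The fitted capture efficiency (~10%) and sequencing efficiency (~0.7 counts
per captured molecule) recover the generator's settings. All 30 allele units
show monoallelic expression (ratio > 0.95) in at least one cell — yet the
test calls only the 5 genes simulated with genuinely stochastic allelic
choice; the balanced and imprinted-like genes are explained by technical
noise plus unequal allelic means. Per-unit statistics (observed mean ratio,
null mean, empirical p) are in `ase.tsv`.

The same steps are available as a library of sklearn-style estimators:

```python
import spikevar as sv

exp = sv.generate_synthetic_experiment(seed=7)
model = sv.TechnicalNoiseModel().fit(exp.matrix, exp.reference)
model.technical_variance(50)            # technical variance at 50 molecules
sv.VarianceDecomposer(model).fit(exp.matrix).results_   # per-gene table
sv.StochasticASETest(model, n_sim=10_000).fit(exp.allele_table).results_
```

`spikevar run --config config.yaml` executes the full QC → normalization →
model fit → decomposition → ASE-test pipeline with a manifest that
reproduces every output byte-identically.

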