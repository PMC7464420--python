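# Methods

## The F-model and its likelihood

Each pairwise scan treats the two breeds as populations that diverged from
a common ancestral gene pool. At locus *i* the ancestral allele frequency
is *p_i*; population *j*'s current frequency is modelled as a Beta draw
around *p_i* with dispersion set by the population- and locus-specific
differentiation F_ST^ij. Writing θ_ij = (1 − F_ST^ij)/F_ST^ij, the
frequency is Beta(θ_ij·p_i, θ_ij·(1 − p_i)) and, after integrating the
frequency out of binomial sampling of alleles, the observed count a_ij of
n_ij called alleles has the beta-binomial marginal likelihood

    P(a | n, p, θ) = C(n, a) · B(a + θp, n − a + θ(1 − p)) / B(θp, θ(1 − p)).

Differentiation is decomposed on the logit scale, logit(F_ST^ij) = α_i +
β_j, equivalently θ_ij = exp(−(α_i + β_j)). β_j captures demography
(drift since divergence) shared by all loci of population *j*; α_i is a
locus effect, non-zero only under locus-specific selection. The model
assumes unlinked biallelic loci, Hardy–Weinberg sampling within
populations, and no shared selective events among the "neutral" loci.

Priors: α_i | δ_i = 1 ~ N(0, 1), with inclusion indicator δ_i having
prior odds P(δ=0)/P(δ=1) = 10; β_j ~ N(−1, 1.8²); p_i ~ Uniform(0, 1).
These are the documented defaults of the established Bayesian
F_ST-outlier software for biallelic data, adopted unchanged because the
analysis this package reproduces reports no deviation from them. All are
configurable (`MCMCConfig`).

## Sampler

A reversible-jump MCMC targets the joint posterior of (α, δ, β, p):

- *p_i*: Gaussian random walk on logit(p_i), with the Jacobian term
  log p(1−p) accounting for the uniform prior.
- *α_i* (when included): Gaussian random walk.
- *δ_i*: a jump proposing inclusion draws α′ from a Gaussian whose mean
  and standard deviation are estimated from the pilot-run samples of α_i
  (conditional on inclusion; falling back to the prior when a locus was
  included in fewer than 20 pilot sweeps, with the proposal sd floored at
  0.15). The acceptance ratio includes the prior-odds and proposal terms.
- *β_j*: Gaussian random walk over the summed likelihood of all loci.

Proposal widths are rescaled after each pilot run toward acceptance rates
in [0.25, 0.45] (multiplying by 1.4 / 0.7 outside that band) and frozen
before burn-in, preserving detailed balance for the retained sample.
Defaults are 20 pilot runs of 5000 sweeps, 50,000 burn-in sweeps, and
5000 retained samples at thinning 10.

Numerical choices: logit(F_ST) arguments are clamped at ±25 before
exponentiation; the binomial coefficient is dropped inside the sampler
(constant in the parameters) but included in the public
`beta_binomial_loglik`; cells with n = 0 contribute zero log-likelihood.
Loci carrying a single allele across both populations of a pair (possible
after pair subsetting despite the global MAF filter) hold no
differentiation information and bypass the sampler with γ = 0, PEP = 1,
and a q-value pinned to 1 so they can never be called significant.

Random numbers: every locus owns a counter-based stream keyed by the
chain seed and a hash of its marker name, and loci are processed
internally in hash order; population-effect updates use one pair-level
stream. Consequently results are bit-reproducible given the seed and
exactly invariant to the input order of loci. In the multi-pair design,
each pair's chain seed is derived from the master seed and the breed
names.

The posterior inclusion probability γ_i is the fraction of retained
samples with δ_i = 1; PEP_i = 1 − γ_i. q-values sort PEPs ascending and
assign the running mean at each rank (ties share the q of their last tied
rank); a locus is significant when q < 0.05 (strict).

## Quality control

Filter semantics follow the standard PLINK commands rather than a literal
reading of the thresholds' prose description: individuals and loci are
removed when their missing-call fraction strictly exceeds 0.1 (`--mind`,
`--geno`), and loci are kept when their minor allele frequency is at
least 0.01 (`--maf`). Order: autosome restriction (Bos taurus labels
1–29), then individuals, then locus call rate, then MAF, so locus
statistics are computed on the retained individual set. Each filter is a
projection (idempotent), and report counts are conserved per axis.

## Multi-cohort aggregation and annotation

The contrast design is the full Cartesian product of test ("grey") and
reference breeds in grey-major order. Per-pair significant sets are
counted per marker and per reference breed; the retention rule uses the
overall count with "at least" semantics (≥ 15 of 60 by default, i.e.
25%; configurable as an absolute count or a fraction, the absolute count
winning when both are set). Retained markers become ±250 kbp windows
(1-based inclusive, clamped at position 1 and optionally at a supplied
chromosome length); overlapping or book-ended windows can be merged into
non-redundant regions, and a marker-delimited interval (outermost marker
positions, no flanks) supports narrative summaries of dense signals. Gene
overlap requires at least one shared base on 1-based inclusive
coordinates, ignoring strand; BED input (0-based half-open) is converted
on read, GFF3 gene rows are used as-is. The per-marker report table keeps
one unmerged window per marker, matching the layout of the original
study's summary table.

## Synthetic data generator

The generator emulates a downsampled BovineSNP50-style multi-breed panel:
by default 15 grey and 4 reference breeds of 24 diploid individuals and
1000 unlinked autosomal loci. Ancestral frequencies are uniform on
(0.05, 0.95); breed effects β_j ~ N(−2, 0.3²) set per-breed
differentiation near logistic(−2) ≈ 0.12, a realistic between-breed
F_ST for taurine cattle. Neutral loci draw each breed's frequency from
the Balding–Nichols Beta with that differentiation. At "selected" loci
(2% by default) every grey breed instead draws around a shared derived
frequency p′ = clamp(p + 0.5, 0.05, 0.95) with differentiation
logistic(α_selected + β_j), α_selected = 2.5 by default, producing
elevated divergence of the same locus in every grey breed. Genotypes are
Binomial(2, freq) under Hardy–Weinberg; calls are dropped i.i.d. at 2%.
Everything is reproducible from one seed.

What the generator does not emulate: linkage disequilibrium (loci are
independent, so window-level clustering of signals cannot arise),
ascertainment bias of array SNPs, relatedness within breeds, and
admixture between breeds. Passing tests on this generator therefore
validate the statistics and the pipeline plumbing, not robustness to
those real-data features.

A structural property of the selected-locus mechanism is worth stating
plainly: a Beta draw with differentiation ≈ 0.62 is close to bimodal, so
individual grey breeds frequently land near fixation on either allele
rather than near p′, and for loci with high ancestral frequency the
derived shift is small after clamping. The realized grey-vs-reference
contrasts are therefore highly variable across loci and breeds. With the
conservative F-model test (prior odds 10) at 24 individuals per breed,
end-to-end recovery of the selected class through the ≥ 25% occurrence
rule is partial: the suite measures roughly 15% recovery at the default
settings (with neutral retention at 0%), and the corresponding
end-to-end test documents the 80% recovery target it falls short of.
Increasing α_selected beyond ≈ 2.5 does not help (the draw distribution
saturates); power rises instead with per-breed sample size and with the
number of jointly strong loci, whose small PEPs let the q-value running
mean admit borderline loci.

## Problem sizes and test scaling

Simulation-backed tests and the acceptance script run reduced chains
(4 pilot runs of 300 sweeps, 1000 burn-in, 1500–2000 retained samples at
thinning 1), chosen after checking on a design pair that PEPs agree with
chains five times longer to well within the decision tolerances.
Sampler-vs-quadrature checks use ≤ 3 loci, where the full posterior is
tractable by dense grid integration over (α, β₁, β₂, p) for every
inclusion configuration. Property tests of the multi-pair machinery use
panels of 2–5 breeds and 80–300 loci; the full 19-breed, 1000-locus,
60-contrast design is exercised once end to end.

## Known limitations

- Biallelic codominant markers only; no multiallelic or
  dominant-marker likelihoods, and no balancing-selection-specific
  reporting mode.
- Convergence diagnostics are limited to acceptance-rate logging.
- PED/MAP orientation: the A allele is defined as first-seen in the
  file; round-trips are bit-exact on reader-produced (canonical)
  datasets, while arbitrary in-memory matrices canonicalize after one
  write/read cycle.
- Genome coordinates are assumed to be on the reporting assembly
  already; no liftover is provided.
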