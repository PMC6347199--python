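# Methods

## Model

`smclone` deconvolves paired matrices of variant read counts **Y** and total
read counts **V** (T loci × S tumor samples) into an unknown number C of
subclones. Each subclone c has a ternary genotype per locus,
z_tc ∈ {0, 0.5, 1} (wild-type, heterozygous, homozygous), and a cellular
proportion w_cs in each sample; an extra row w_0s absorbs signal not
explained by the subclones. Variant counts are binomial,

    y_ts ~ Binomial(v_ts, p_ts),
    p_ts = w_0s · p + Σ_c z_tc · w_cs,

where p is a small background error rate. Stacking loci, the expected VAF
matrix factorizes as P = [p **Z**] · **W**, with each column of **W** on the
simplex.

Loci are processed sequentially. The genotype rows follow a three-category
Indian buffet process: locus 1 opens Poisson(α) columns; locus t ≥ 2 reuses
an existing column with probability m_c/t (m_c = its previous non-zero
entries), splitting the reuse mass between 0.5 and 1 by the pseudo-counts
(β + m_c1)/(β* + m_c) and (β + m_c2)/(β* + m_c) with β* = 2β, and opens
Poisson(α/t) fresh columns. Columns are never deleted; after T loci the
expected column count is α·H_T. The static parameters are handled with
artificial dynamics: the unnormalized proportions θ (w = θ/Σθ columnwise)
and p take Gaussian random-walk steps each locus, truncated positive
(rejection) for θ and reflected into (0,1) for p. Initialization draws
θ_0s ~ Gamma(a0, 1), θ_cs ~ Gamma(a1, 1), p ~ Beta(a00, b00).

## Inference

A particle filter tracks N hypotheses (partial **Z**, θ, p). Weights are
normalized by log-sum-exp and the ensemble is resampled at every step
(multinomial by default; systematic available). Two importance
distributions are implemented.

**Prior proposal** (`proposal="prior"`): the plain bootstrap filter — state
proposed from the prior transition, weight multiplied by the binomial
likelihood of the new locus. This is the simplest construction but it is
not usable at realistic depths: with v ≈ 100 and S ≈ 10 the per-locus
likelihood is so peaked that the effective sample size collapses to ≈ 1 at
every step, the static proportions never converge (they are explored only
by blind walk steps), and extra columns are pure likelihood gain against a
one-time prior cost of a few nats, so the column count inflates severely
(posterior modes of 6–12 at a generative C = 3 in our experiments, at any
walk scale and up to N = 3000). It is retained as a reference mode.

**Guided proposal** (default): each locus is absorbed in K tempered
substeps (each contributes the likelihood to the power 1/K, with the
random-walk dynamics applied between substeps). Each substep performs a
marginalized move:

* the ternary row over existing columns is enumerated exactly (all 3^C
  combinations; above `enum_top` = 32 rows a point-θ screen keeps the best
  32) with its exact process prior;
* θ is integrated over a proposal mixture — the truncated random-walk
  kernel with probability 1−ρ per entry, a fresh draw from the
  initialization prior with probability ρ = 0.25 — using M = 12 Monte-Carlo
  draws and an exact per-entry importance ratio against the model's own
  dynamics. Because the likelihood factorizes over samples given a genotype
  row, the per-sample integrals are one-dimensional and low-variance, and
  after a row is chosen the concrete θ is selected per sample in proportion
  to its likelihood contribution (a nested sampling-importance-resampling
  step). The fresh component is what lets a mis-scaled column re-scale in a
  single move; without it, a column whose weight locked onto half the true
  scale can only be patched by opening a spurious sibling column.
* on the final substep the column-opening decision is a branch whose
  new-column θ integral is computed the same way, so opening pays its
  honest Occam factor; the weight increment is the total predictive
  estimate. One birth per locus is allowed except at locus 1, where d = 0…5
  simultaneous births are enumerated: the first locus has no committed
  columns, and restricting it to one birth would merge distinct subclones
  active at that locus into one column that the sequential construction can
  never split (this materially biased the subclone count downward for
  C ≥ 4). Multi-column branch integrals at later loci were tried and
  rejected: their Monte-Carlo noise, exponentiated by the branch selection,
  systematically over-opened columns.

The walk scale for θ used by the guided move decays as σ0/√t (σ0 = 0.5,
floored at `sigma_theta`), mirroring the ~1/√t contraction of the posterior
on the proportions: early loci face parameter uncertainty far wider than
any stationary walk scale, while late loci need a narrow kernel so that two
subclones with similar proportions stay resolved. With a fixed kernel of
0.1 the proportion estimates stayed permanently blurred and the genotype
error on late loci plateaued near 0.11; with the decaying kernel it falls
to ~0.02.

The target distribution (cIBP prior, random-walk dynamics, binomial
likelihood) is identical in both modes; only the importance distribution
and the corresponding proper weights differ.

## Posterior summaries

The posterior over C is the weighted frequency of per-particle column
counts; its mode (ties toward the smaller count) is the MAP estimate. All
other estimates condition on the MAP-count particles: their columns are
aligned to the highest-weight such particle by minimum-L1 assignment on
genotype columns (the same Hungarian matcher used by the evaluation
metrics), genotypes are the weighted elementwise mode (ties toward the
smaller value), proportions the weighted mean renormalized columnwise, and
the fitted VAF matrix is rebuilt as P̂ = [p̂ Ẑ]·Ŵ.

## Defaults

| parameter | default | meaning |
|---|---|---|
| α | 1.0 | new-column rate; prior E[C] ≈ 3.6 after 20 loci |
| β | 0.5 | category pseudo-count (heterozygous/homozygous split) |
| N | 1000 | particles |
| σ_θ | 0.01 | stationary walk scale for θ (floor of the σ0/√t schedule) |
| σ_p | 0.003 | walk scale for p |
| a0 | 0.1 | Gamma shape, noise proportion row |
| a1 | 1.0 | Gamma shape, subclone proportion rows |
| a00, b00 | 1, 30 | Beta shapes for p (prior mean ≈ 0.032) |
| K | 5 | tempered substeps per locus |
| M | 12 | Monte-Carlo draws for θ integrals (4× at locus 1) |
| ρ | 0.25 | fresh-prior refresh probability per θ entry |

a0 = 0.1 matches the noise weight of the generative Dirichlet([0.1, …])
used in the simulation study; larger values open a "noise sink": the model
is only identified through the product w_0s·p, and a loosely constrained
noise row absorbs real subclonal signal. For the same reason p itself is
weakly identified — its point estimate can drift along the w_0s·p ridge
without affecting the fit, so p̂ should be read together with ŵ_0s.

## Synthetic data

The generator reproduces the simulation study's recipe: v_ts ~ Poisson(r);
each proportion column ~ Dirichlet([0.1, a_1…a_C]) with the subclone
concentrations drawn once per dataset uniformly from {2, 4, 5, 6, 7, 8};
genotypes i.i.d. over {0, 0.5, 1} with probabilities (0.5, 0.1, 0.4)
(ternary mode) or over {0, 0.5} with (0.3, 0.7) (binary mode, the
convention for comparing against presence/absence-only methods, where an
estimated 1 is scored as 0.5); p = 0.02; y_ts ~ Binomial(v_ts, p_ts). Zero
Poisson depths are retained (y = 0 deterministically). What this does not
emulate: copy-number variation, tumor purity confounding, mapping artifacts
and overdispersion of real read counts — passing tests demonstrate
correctness of the implementation under the model's own assumptions, not
robustness to those violations.

## Evaluation metrics

Reconstructions are identified only up to column relabeling, so estimates
are matched to truth by the permutation minimizing the mean absolute
genotype deviation, found exactly by minimum-cost assignment (equivalent to
exhaustive search because the cost is a sum of independent column-pair
terms). The reported errors are e_Z (mean |ẑ − z| over T·C entries), e_W
(sum of |ŵ − w| over all C+1 rows divided by C·S — the divisor is C·S even
though C+1 rows enter, matching the printed definition), and e_pts (mean
|p̂_ts − p_ts| over T·S, permutation-invariant). When the estimated and true
column counts differ, the narrower matrix is padded with zero columns (and
W with zero rows) and the report flags the mismatch.

## Numerical choices

All likelihood arithmetic is in log space with binomial coefficients from
log-gamma; success probabilities are clipped to [1e-12, 1−1e-12] so a
structurally impossible read yields a finite penalty instead of −inf.
Ties are broken deterministically everywhere (smaller C, smaller genotype,
first index), and a single seeded generator drives every random choice in a
fixed order, so identical seeds and inputs give bitwise-identical output.
Row order of the input table is the processing order of the sequential
prior; a `--shuffle-loci` flag permutes it (reporting estimates in the
original order) as a sensitivity diagnostic.

## Problem sizes and known limitations

The packaged checks run the regimes of the simulation study at desk scale:
subclone-count recovery at T=20, S=10, N=1000 over five seeds per case, and
a many-loci surrogate at T=200, S=5 with 300 particles (the full T=2000
benchmark is available in `scripts/table_benchmark.py --full` and takes
hours on one CPU).

Known limitations, measured on the generator's own data:

* at a generative C=5 with only T=20 loci the posterior mode is typically
  4 (and sometimes 3): the smallest subclones are absorbed into neighbors.
  C=3 is recovered on roughly three quarters of datasets in this regime;
  C=4 recovery is mixed — the mode regularly lands on 3. Which way a given
  dataset falls is a property of the dataset (how separated its proportion
  columns are), not of the run seed.
* occasional datasets place two subclones at nearly identical proportions
  across all samples; the corresponding columns then blur into each other
  and the genotype error for those columns stays near 0.15 regardless of
  particle count. This is a property of the dataset (weak identifiability
  at small S), not of the seed.
* the error rate p is identified only through w_0s·p (see above).
* rejuvenation of past loci (resample-move) is deliberately out of scope;
  early-locus genotype calls can therefore retain errors made before the
  proportions converged, which dominates e_Z at small T.
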