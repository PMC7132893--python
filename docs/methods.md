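# Methods

This note documents the statistical model behind `georif`, the conventions
chosen where the underlying method leaves room, the synthetic fixtures used
to validate it, and known limitations.

## Differential expression on counts

Counts are modelled negative-binomially with the mean–variance law
`v = μ + αμ²` (α ≥ 0; α = 0 is Poisson).

**Normalization.** Sequencing-depth and composition differences are removed
with trimmed-mean-of-M-values (TMM) factors: per sample, a weighted mean of
log₂ expression ratios against a reference sample (the one whose
upper-quartile expression fraction is closest to the mean, unless given),
after trimming 30% of M-values and 5% of A-values from each tail; weights
are inverse asymptotic variances of M. Factors are rescaled to geometric
mean 1. Expression is reported as log₂ counts-per-million on effective
library sizes with pseudocount 0.5 (configurable); genes with zero counts
in all samples are dropped with a logged count.

**Dispersion.** The common dispersion maximizes the conditional NB
log-likelihood (each group's likelihood conditional on its total), summed
over genes, on counts rescaled to a common effective library size and
rounded half-to-even. The 1-D maximization runs on α ∈ [10⁻⁶, 10] with
tolerance 10⁻⁶. Per-gene ("tagwise", the default) estimates are per-gene
conditional MLEs shrunk toward the common value with a fixed prior weight
of 10 pseudo-genes: `α_g = (w·α_c + n_g·α̂_g)/(w + n_g)` with `n_g` the
sample count. This fixed-weight shrinkage is a deliberate simplification of
empirical-Bayes weighted-likelihood schemes; `dispersion="common"` disables
it.

**Exact test.** Per gene, group totals (s₁, s₂) on equalized libraries are
compared under the null of equal means: the total of n_k samples is NB with
mean n_k·μ̂ and dispersion α_g/n_k, and the two-sided p-value sums the
conditional probabilities of all splits no more probable than the observed
one (exact ties included; the modal split gets exactly p = 1; zero-total
genes get p = 1). BH step-up adjustment controls FDR; a gene is DE when
`fdr < cutoff` (strict; default cutoff 0.05, configurable — the method's
original applications do not fix a threshold). The test is unpaired; pair
labels are carried but unused (a documented limitation for paired designs).

Calibration on null NB fixtures (2000 genes, 10+10 samples, α = 0.4,
20 seeds) is part of the acceptance checks: the mean DE fraction at
FDR < 0.05 and the p-value ECDF at 0.05 are computed fresh on every run of
`scripts/acceptance.py`, as is dispersion recovery over 50 runs.

## Association measures

Profiles are log₂-CPM rows restricted to one condition's samples, in
count-matrix order (used identically in both conditions).

* **Pearson / Spearman** — sample correlation, Spearman via mid-ranks.
  Zero-variance profiles get association 0 with a warning, never NaN.
* **Fisher information metric** — profiles are embedded on the probability
  simplex (shift by −min + δ, δ = 10⁻⁸·range or 10⁻⁸ for a constant
  profile, then normalize; the embedding is shift- and scale-invariant) and
  the geodesic distance `arccos Σ√(pᵢqᵢ)` ∈ [0, π/2] is computed, in the
  numerically exact half-angle form `2·arcsin(‖√p − √q‖/2)`. The factor-2
  geodesic convention would only rescale distances and cancels in the
  association mapping, so it is omitted.
* **Sobolev metric** (order k, default 1) — `d² = Σₘ₌₀..ₖ ‖Δᵐ(p − q)‖²`
  with Δ the circular first difference; k = 0 is the Euclidean norm. The
  circular boundary makes the finite-difference form exactly
  Parseval-equivalent to the spectral form `Σₜ (1 + |1 − e^{2πit/n}|²)|ŵₜ|²`,
  which the tests verify. Because the "derivative" runs along the sample
  axis, the Sobolev distance depends on sample order; the input order of
  the count matrix is used, identically in both conditions, and reordering
  samples changes results.

**Distance → association.** `a = 1 − d/d_max`, strictly decreasing in d and
unsigned (range [0, 1]). `d_max = π/2` (theoretical) for Fisher; for
Sobolev it is the maximum distance observed over all regulator–gene pairs
in *both* conditions of the run, recorded in the result so runs are
reproducible. This mapping is a declared convention of this package: the
RIF formalism needs a correlation-like quantity in [−1, 1] slots and no
published convention exists for the geometric metrics. A signed variant
(multiplying by the sign of the pairwise Pearson correlation) is available
(`signed_geometric=True`) but is *not* the default: in planted-recovery
simulations the sign flips inject ±2a jumps per pair and markedly degrade
regulator ranking.

## RIF scoring

PIF, DW, RIF1 and RIF2 are as in the README. Two conventions matter:

* **DW is squared inside RIF1** (`PIF·DW²`), following the original RIF
  formulation; `rif1_linear_dw=True` gives the unsquared product.
* **Standardization and selection.** Raw scores are z-scored across
  regulators within each measure (sample sd, ddof = 1; zero spread gives a
  zero vector with a warning), ranked by descending |z| (dense ranks; ties
  broken toward the positive score, then ascending gene id), and the union
  of the top-k by |RIF1 z| and top-k by |RIF2 z| is selected (≤ 2k per
  measure, default k = 10). Standardization before ranking is the default
  because RIF scores are conventionally reported as z-scores; `select` can
  switch extremity from |z| to signed z.

Relabelling the two conditions negates PIF, DW, RIF1 and RIF2 *exactly*
(same floating-point products, opposite sign), so |z|, ranks and selection
are orientation-invariant; only signs flip. The orientation (which label is
"condition 1") is always an explicit setting, never inferred.

RIF1 and RIF2 fail differently. Under unsigned distance associations a
regulator whose own profile spread differs between conditions by chance is
uniformly nearer to (or farther from) *all* DE genes in one condition,
giving its whole DW row an offset that `PIF·DW²` accumulates; RIF2, which
contrasts expression-weighted associations, is much less sensitive to this.
In recovery simulations the planted regulator's best-of-two rank is
therefore the robust statistic, and both ranks are reported.

## PCIT network

Direct associations between the selected regulators are pooled-sample
Pearson correlations by default (PCIT is defined on correlations);
`pcit_metric="run"` switches to the run's own association measure. For
every trio (x, y, z) the three first-order partial correlations are
computed and the trio tolerance is the mean |partial/direct| over pairs
with non-zero direct correlation. The edge (x, y) is eliminated when some z
gives `|r_xy·z| < ε_z|r_xz|` and `|r_xy·z| < ε_z|r_yz|` — the partial,
compared strictly, so a pure chain x–z–y always loses its indirect edge
while an exactly balanced trio (three equal correlations, where the
partials tie with the tolerance bound) keeps all three. Surviving edges are
then thresholded at |direct r| ≥ 0.90 (the published operating point;
configurable), with an optional stricter `min_partial` bound on all
partials. Isolated nodes are retained: the "significant regulators" of a
run are the network's node set. With fewer than 3 selected regulators the
PCIT stage is skipped with a warning.

## Synthetic fixtures

The generator provides the two kinds of ground truth the pipeline needs.

* **Null preset** — NB counts with identical law in both conditions;
  baseline means log-uniform on [1, 1000] (spanning lowly to highly
  expressed genes), default 2000 genes, 20+20 paired samples. Used for
  type-I-error and dispersion-recovery checks.
* **Wired preset** — an expressed-gene fixture: baseline means log-uniform
  on [50, 1000], biological sample-to-sample variability as a log-normal
  latent layer with sd τ = 1.0 (natural log), residual NB dispersion
  α = 0.02, planted DE fold change 4. Wiring is implanted on the latent
  log-mean: each wired regulator follows a per-sample Gaussian factor, and
  its targets mix that factor with weight ρ in condition 1 only — so the
  induced correlation is controllable and visible to any association
  measure, and is realized near ρ at these noise levels (median count-scale
  correlation ≈ 0.87 at ρ = 0.9; heavier count noise attenuates it, which
  is why the residual dispersion is kept small and means start at 50).
  Counts are gamma-Poisson around the exponentiated latent. The default
  catalog plan tiles the regulator set as ~70% TF, 30% EF with a 10% TF∩EF
  overlap, and 10% lncRNA, mirroring the overlapping-class structure of
  real regulator databases.

What the fixtures do **not** emulate: gene length and GC effects,
read-level noise, fragment or positional bias, correlated gene modules
beyond the planted wiring, library-composition artifacts, or outlier
samples. Passing the recovery checks therefore demonstrates that the
statistics behave as designed under their own model, not that any
particular biological dataset will yield the same rankings.

**Run sizes.** The recovery evaluation uses 400-gene fixtures (1 wired
regulator, 20 targets, ρ = 0.9, 50 decoys, 20+20 samples, 100 seeds) and
the calibration evaluation 2000-gene fixtures over 20 (calibration) and 50
(dispersion) seeds — sizes chosen so a full evaluation completes in about a
minute on one CPU while keeping Monte-Carlo error on the reported rates
near the percent level.

## Numerical choices

* Fisher geodesic in half-angle form (exact at coinciding points; the
  arccos form loses half the floating-point digits near 0).
* Exact-test tie detection at relative tolerance 10⁻¹²; the modal split
  returns exactly 1.
* PCIT strict comparison with a 10⁻⁹ relative guard so exact ties survive
  under floating point.
* Half-to-even rounding for library equalization.
* Golden-section per-gene dispersion MLE on log α, 80 iterations,
  vectorized across genes.
* All outputs are TSV with full-`repr` floats; identical inputs and config
  reproduce outputs byte-for-byte (the log and resolved config embed paths
  and are excluded from that guarantee).

## Limitations

* The exact test ignores pairing; a paired design loses power but keeps
  validity.
* The unsigned distance→association convention cannot distinguish a
  correlation that flips sign from one that merely weakens.
* TMM assumes most genes are not DE; fixtures with majority-DE gene sets
  would bias normalization.
* The common/tagwise dispersion absorbs any latent biological layer into
  α; fitted values on heterogeneous cohorts are totals, not technical
  dispersions.
* PCIT on few regulators (< ~5) has little conditioning structure and
  mostly reduces to the direct-correlation threshold.
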