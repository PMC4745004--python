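# Methods

## The model

`mirepress` quantifies how strongly a cell's miRNA pool represses each
mRNA, and how that repression differs between tumor samples and a normal
control, using only a miRNA expression profile, a scored miRNA→mRNA
interaction table and pathway annotations.

**Normalization.** Raw abundances (sequencing counts or array
intensities — any non-negative abundance is accepted) are converted to
transcripts per million,

    TPM(a) = counts(a) / Σ_b counts(b) × 10^6 ,

so every profile sums to 10^6 and library size drops out.  The control
comparator is the per-miRNA arithmetic mean of the normal samples' TPM
profiles.  Averaging is done on the TPM scale, not on raw counts, so that
samples sequenced deeper do not dominate the control; miRNAs absent from
a sample enter the mean as zeros.

**Comprehensive repression.** Each miRNA's TPM is treated as a repression
mass apportioned across its predicted targets in proportion to the
interaction repression scores RS (miRanda-style, required non-negative):

    weight(a, α) = RS(a, α) / Σ_t RS(a, t)
    R(α)         = Σ_a TPM(a) · weight(a, α)

R(α) is the accumulated, abundance-weighted repression received by mRNA
α.  Two properties follow and are enforced by tests: each miRNA's weights
sum to 1, and total repression equals the summed TPM of target-bearing
miRNAs (mass is apportioned, never created).  A miRNA whose scores sum to
zero predicts no repression and is dropped with a logged warning rather
than given uniform weights.  Per-pair contributions TPM(a)·weight(a, α)
are kept alongside so interactions can be screened individually.

**Differential testing.** For each gene (or interaction pair), its
repression mass x out of the group total n is compared between control
(group 1) and a tumor sample (group 2) with the pooled two-proportion
z-test:

    p0 = (x1 + x2) / (n1 + n2)
    z  = (p̂1 − p̂2) / √(p0 (1 − p0) (1/n1 + 1/n2)) ,

two-sided against the standard normal.  Masses are real-valued and used
as-is; the test is stated on repression masses, not integer counts.  When
p0 is 0 or 1 the statistic is undefined and the p-value is set to 1 —
degeneracy never fabricates significance.  The default significance rule
is raw p < 0.05 (the screening is reproduce-first); Benjamini–Hochberg
adjustment is available behind a flag and then thresholds the q-value.
Neither the test's sidedness nor a threshold is canonical for this kind
of screen; both are explicit parameters.

**Enrichment and recurrence.** Per sample, the genes *significantly more
repressed in the tumor* (significant and p̂_test > p̂_control) are tested
for pathway over-representation with the one-sided upper-tail
hypergeometric test; the direction matters, because TPM is compositional —
when planted miRNAs rise, every other gene's share mechanically falls, and
a two-sided hit set would be flooded by those passive decreases.  The
default universe is the interaction table's genes annotated to at least
one pathway (a DAVID-style background is not recoverable and the universe
is overridable).  Pathways enriched in *every* tumor sample form the
overlapped set; the differential tables are then restricted to those
pathways' genes, and the miRNAs appearing in significant restricted
interactions (any direction, by |z|) and the significantly more-repressed
restricted mRNAs are intersected across samples, with full Venn-region
bookkeeping.

**Panel clustering.** A candidate biomarker panel is evaluated by
building the sample × panel matrix of log2(TPM + 1), clustering samples
agglomeratively (Euclidean distance, average linkage by default; both
selectable) and scoring the k = 2 cut against the known groups by
purity — the fraction of samples whose cluster's majority group is their
own.  The log transform, metric and linkage are conventional defaults,
not canonical choices.  Flat labels are obtained by cutting the merge
sequence, which yields exactly k non-empty clusters at every 1 ≤ k ≤ n
even when merge heights tie.

## Synthetic study design

The generator emulates the structure of a small tumor-versus-control
profiling study: 4 control and 4 tumor samples, ~300 miRNAs, 1000
annotated genes in 20 disjoint pathways, and a planted signal in 4
pathways.  Planting couples two moves: each planted pathway gets 2
dedicated miRNAs whose target sets are rewired so ≥ 80% of their targets
lie inside the pathway, and those miRNAs' expected expression is
multiplied by `fold_change` (default 4) in every tumor sample.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `baseline_mean` | 3000 counts | ≈10^6 reads over 300 miRNAs, deep small-RNA sequencing |
| mean spread | log-uniform over one decade | typical miRNA dynamic range without letting one species dominate the library |
| `dispersion` | 0.001 | gamma–Poisson at technical-replicate scale; see below |
| `targets_per_mirna` | 10–40 | enough in-pathway coverage (≈30 of 50 genes per planted pathway) for enrichment to be detectable |
| `planted_mirnas_per_pathway` | 2 | keeps the planted miRNAs' TPM share ≈3%, so the compositional down-shift of unplanted genes stays below the test's detection threshold |
| `score_range` | 20–200 | miRanda-like positive score magnitudes |

The dispersion default deserves emphasis.  The pooled-proportion test
models multinomial counting noise at the group-total scale (n ≈ 10^6
TPM).  Because each tumor sample is compared individually against the
averaged control, the relevant null variation is sampling/technical
noise, and the generator draws counts near-Poisson (variance
μ + 0.001·μ²).  Biological replicate dispersion in real cohorts is two
orders of magnitude larger and would violate the test's sampling model —
with realistic biological noise essentially every gene reaches
significance at n = 10^6.  Passing tests on this generator therefore show
that the pipeline recovers planted structure *under the method's own
noise model*; they do not show the proportion test is calibrated for
biologically replicated data.  This is a limitation of the method, not of
the implementation.

Pathways are disjoint by default so planted recovery is unambiguous
(`overlapping_pathways` relaxes this).  Three RNG streams (expression,
network, planting) are spawned from the master seed, so changing one
configuration field perturbs only its own component, and a fixed seed
reproduces the dataset bit for bit.

## Null calibration

The type-I error of the differential test is measured under its own null:
gene repression shares are taken from a `fold_change = 1` synthetic
dataset, and both groups are binomially resampled from the same share at
n = 10^6 (2000 gene-level tests).  The empirical rejection rate at
α = 0.05 is checked against the binomial 99% interval around 0.05.
Resampling is used rather than comparing two raw generated replicates
because the latter measures the generator's noise model, not the test's
calibration.

## Numerical choices

- TPM sum invariant enforced at 1e-9 relative; weight sums at 1e-12.
- Repression equality cross-checks use 1e-12 relative alongside 1e-10
  absolute: at TPM magnitude, summation order alone moves the last few
  ulps.
- Hypergeometric p-values come from `scipy.stats.hypergeom.sf` and are
  verified against exhaustive PMF summation for every universe N ≤ 60
  (max deviation ~4e-16).
- BH q-values are the standard step-up with monotonicity enforced by a
  reverse cumulative minimum, capped at 1.
- Agglomerative merges are computed by `scipy.cluster.hierarchy.linkage`
  on a condensed distance matrix, which is deterministic for a given
  input; ties are resolved by its fixed processing order.  Correlation
  distance for a constant row is undefined and mapped to the metric's
  maximum (2.0).
- Percentages in the literature tabulation are rounded half-up to one
  decimal using exact decimal arithmetic.

## Problem sizes

The default study design (300 miRNAs × 1000 genes × 8 samples) runs the
full pipeline in well under a second, so the recovery and monotonicity
properties are exercised across 10–20 replicate seeds and fold changes
{1, 2, 4, 8} directly at the default size.

## Known limitations

- The repression model assumes a miRNA's total repression capacity is
  proportional to its abundance and splits linearly by score; saturation,
  cooperative binding and target-site competition are not modeled.
- The proportion test treats repression masses as multinomial counts; its
  p-values are anti-conservative for biologically replicated data (see
  above).
- Identifiers are matched by exact string equality; mapping between
  annotation vocabularies, and converting raw miRanda output (positive
  alignment scores vs. negative binding energies) to non-negative
  repression scores, are the caller's responsibility.
- The literature table is a static curated snapshot; no mining is
  attempted, and wet-lab quantities (raw Ct values) are not reproduced —
  only the 2^(−ΔΔCt) transform is provided.
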