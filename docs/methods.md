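# Methods

## The GSVD as a comparative decomposition

Given tumor and normal matrices `D1 (K1 x L)`, `D2 (K2 x L)` with a shared,
ordered patient axis and full column rank `L <= Ki`, the package computes
the exact simultaneous factorization `Di = Ui Σi Vᵀ`.  The algorithm stacks
the pair, takes a thin QR `[D1; D2] = Q R`, and splits the partitioned
orthonormal factor by the cosine-sine construction: the SVD of the top
block `Q1 = P1 C Zᵀ` supplies the cosines `C`, and `Q2 Z` has orthogonal
columns whose norms are the sines `S = sqrt(I − C²)` (this is the CS
decomposition of the partitioned factor, computed blockwise because the
stacked factor is tall, not square).  Then `U1 = P1`, `U2 = Q2 Z S⁻¹`, and
the shared factor before normalization is `Xᵀ = Zᵀ R`.

**Normalization.** `Vᵀ` is `Xᵀ` with unit row norms; the absorbed row norm
`n_a` multiplies *both* cores, `σ_{1,a} = c_a n_a`, `σ_{2,a} = s_a n_a`.
Splitting the scale symmetrically is one of several valid conventions; it
is recorded on the result (`scale_convention`) and it leaves every ratio
`σ_{1,a}/σ_{2,a}` and hence every angular distance unchanged, which is all
the downstream interpretation uses.

**Ordering and phase.** Components are sorted by decreasing ratio, ties
broken by decreasing `σ_{1,a}` and then pre-sort index.  The ±1 phase of
each triplet `(u_{1,a}, u_{2,a}, v_a)` is fixed by making the
largest-magnitude entry of `v_a` positive.  Components whose ratios agree
within `1e-8` of the maximum ratio are reported as degenerate groups: the
decomposition is unique only up to rotation inside such a group, so
downstream flags are propagated group-wise.

**Rank.** Full column rank is enforced with a relative threshold
(`rank_tol`, default `1e-10`) on each input's singular-value spread; a
deficient input is reported by name.  `rank_tol` is at the machine-precision
scale of double arithmetic and is not meant as a model-selection knob.

## The tensor GSVD

For platform-matched tensors `Di (Ki x L x M)` with `LM <= Ki`, three pairs
of unfoldings are decomposed: the row-mode unfolding (`Ki x LM`, patient
index varying fastest) supplies `Ui`, `Σi` and the row-mode `Vᵀ`; the x- and
y-mode unfoldings supply the shared patient factor `Vx` and platform factor
`Vy`, each computed with the same normalization and sign conventions as the
matrix GSVD.  The cores follow by contraction,
`Ri = Σi Vᵀ (Vy⁻ᵀ ⊗ Vx⁻ᵀ)`, reshaped to `LM x L x M`.

Index conventions: the row-mode column for patient *l*, platform *m* sits
at `m·L + l`, which is exactly the Kronecker order of `Vy ⊗ Vx`, so the
core formula applies with no permutation.  The orders of the columns inside
the x/y unfoldings only affect the intermediate factors `U_ix, U_iy`; the
invariance of `Vx`, `Vy`, the sigmas and the cores under bin permutation is
itself a test.

The inverses `Vx⁻ᵀ, Vy⁻ᵀ` are obtained by solving linear systems; a
condition number above `1e8` is recorded as a warning on the result.  Where
`|r_{2,abc}|` falls below `1e-12` of the core's maximum, the tensor angular
distance is stored as NaN (undefined) rather than forced to ±π/4, because
the defining ratio has no meaning there.

## Component selection, classification, genotype calls

*Significance* of component *a* in dataset *i* is the information fraction
`P_{i,a} = σ_{i,a}²/Σ_b σ_{i,b}²` (threshold `p_min`, default 0.01);
*exclusivity* is `θ_a ≥ theta_min` (default 0.2 rad).  The selected pattern
is the max-θ component among those significant in the tumor dataset.  Both
thresholds are configurable; the defaults make "significant" mean
"carries at least the average component's information" at L = 100 and
"exclusive" mean "ratio above ~1.9".

*Patient classification.*  Each patient's tumor profile is Spearman-rank
correlated with the pattern (average ranks on ties; constant columns give
NaN).  High-by-correlation uses a strict cutoff of 0.35.  The coefficient
cutoff is 0.35 *divided by* the Euclidean norm of the correlation vector:
the shared row basis vector is unit-norm while the correlation vector is
not, so dividing maps the cutoff between the two scales; the opposite
("multiply") reading is available as an option.  Because the decomposition
fixes component signs by an arbitrary convention, the selected component is
oriented before classification so that the correlation vector's heavy tail
(the carriers, a minority) is positive — operationally, flip when the
skewness of the correlations is negative.

*Segment genotype calls.*  The dispersion unit is one MAD of the pattern
over all bins covered by the supplied arms.  Each segment's median is
compared, by default, with the *pooled* median over all arm bins; a segment
is amplified above `+t_mad` MADs, deleted below `−t_mad`, else unaltered.
The pooled reference is deliberate: an alteration spanning most of a single
arm — as an arm-wide loss does — *is* that arm's median, so a per-arm
reference could never call it.  Per-arm referencing remains available
(`reference='arm'`) and per-arm medians are always reported.  `t_mad`
defaults to 1.0.  Note one geometric consequence: when the majority of the
pattern's bins are altered (the default synthetic geometry alters 70%),
the MAD itself approaches the block amplitude and a full planted block
lands at ±1 MAD exactly, so calling planted blocks there needs `t_mad`
below 1.  Segments covering ≤ 30 probes are retained in output but flagged
as below the probe filter.

*Covariate association.*  Numeric covariates get Pearson and Spearman
correlations and, given a high/low split, a two-sided Mann-Whitney-Wilcoxon
comparison of the covariate between the high set and its complement.
Binary covariates are tested by MWW on the basis-vector entries between the
two groups; categorical covariates additionally get an upper-tail
hypergeometric enrichment P of the most-enriched level in the high set.
MWW uses the exact distribution for tie-free groups of ≤ 25, otherwise the
normal approximation with tie correction.

## Survival analysis

Kaplan-Meier curves, the two-group log-rank test and Cox
proportional-hazards fits are delegated to lifelines; the module owns the
contract.  Ties are handled by the Efron approximation (lifelines'
default, stated here so results are reproducible across languages).  A KM
median is the earliest time the curve reaches ≤ 0.5 and is *undefined*
when the curve ends above 0.5 — never the last observed time.  Stage
enters bivariate models ordinally (I–IV → 1–4).  Groups of unequal size
are analyzed as-is; no resampling or balancing is done.  PFS subsets keep
records with a recorded PFS at or above the threshold, so threshold 0
means "all patients who experienced PFS".

## The synthetic cohort

The generator plants, in known amounts, each signal class the comparative
decomposition is meant to separate:

| ingredient | default | emulates |
|---|---|---|
| dims | K1 = K2 = 600 bins, L = 100 patients, M = 2 platforms | desk-scale cohort |
| pattern | −1.0 over 45% of bins + +1.0 over 25%, carried by 20% of patients, tumor only | arm-wide loss + gain CNA genotype |
| shared variation | 3 rank-1 components, amplitude 0.5, same patient loadings in both datasets | germline CNV every genome carries |
| GC artifact | +0.5 x gc_fraction per bin, same per-patient loadings in both datasets | PCR under-representation of GC-poor sequence |
| batch offsets | 2 batches per dataset, independent assignments, profile sd 0.3 | unmatched sequencers |
| noise | i.i.d. Gaussian, sd 0.25 | measurement noise |
| survival | exponential PH, baseline hazard ln2/36 per month, carrier HR 3, 30% censoring | outcome linked to genotype |

Amplitudes the study conditions leave open (GC 0.5, batch 0.3, shared 0.5,
platform gains N(1, 0.05²)) were set once on the principle that
experimental artifacts are real but subdominant to a one-copy alteration;
the baseline hazard gives non-carriers a three-year median survival.
Stage and platinum status are sampled independently of carrier status, so
the pattern and stage are independent predictors by construction.  All
draws flow through one seeded generator in a fixed order: a fixed seed
reproduces the cohort bit for bit, and the planted block geometry is
seed-independent.

What the generator does *not* emulate: segmental (autocorrelated) noise,
intensity-dependent microarray effects, subclonal mixtures, aneuploidy
beyond the planted blocks, or informative censoring.  Passing the recovery
tests therefore shows the decomposition and classification machinery do
what they claim on data matching the model's assumptions — not that real
cohorts meet those assumptions.

Two numerical facts about the null worth knowing when interpreting the
tests: (i) for two *independent* 600 x 100 noise matrices the generalized
singular ratios have a random-matrix spread giving max |θ| ≈ 0.29 — well
below a planted pattern's θ ≈ 0.72 but far from 0, and independent of the
noise scale; (ii) with 70% of pattern bins altered, the pattern's MAD
equals the block amplitude (see segment calls above).

## Problem sizes

The test suite and the reproduction script run the exactness sweeps at
100 random pairs (K ≤ 50, L ≤ 10), the angle-bound sweep at 1000 pairs,
the tensor sweep at 50 pairs (K ≤ 40, L ≤ 4, M ≤ 3), the recovery study at
the default 600 x 100 cohort, and the Cox calibration at 200 replicates of
n = 500 — sizes at which every check completes in seconds to a few tens of
seconds on one CPU while leaving the measured errors at their asymptotic
(machine-precision or statistically stable) values.

## Known limitations

- The GSVD here is the two-matrix decomposition; no higher-order GSVD of
  more than two datasets, and tensors are limited to order 3.
- Segments are inputs (BED + arm table); no segmentation algorithm is
  included.
- Profile matrices must be complete; missing values are rejected rather
  than imputed.
- Near-degenerate ratio groups are flagged, not re-rotated; interpretation
  inside a flagged group is up to the analyst.
- The coefficient-cutoff convention ("divide") and the pooled segment
  reference are documented choices among readings the underlying rule
  leaves open; both alternatives are implemented and selectable.
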