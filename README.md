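# cospec

Comparative spectral decompositions — the generalized singular value
decomposition (GSVD) and its third-order tensor extension — for
patient-matched tumor/normal DNA copy-number profiles, with the downstream
analysis that turns a decomposition into biology: selection of
tumor-exclusive, significant components; amplified/unaltered/deleted
segment genotype calls; high/low patient classification; and
Kaplan-Meier / log-rank / Cox survival stratification.

## The problem

Copy-number studies of adenocarcinomas profile each patient's tumor DNA
*and* patient-matched normal DNA, often on more than one platform.  The two
datasets share their patient axis (and, with multiple platforms, a platform
axis) but have independent genomic row axes: tumor and normal genomes are
binned separately.  Buried in the tumor dataset are somatic alteration
patterns carried by a subset of patients; superimposed on both datasets are
germline copy-number variation, GC-content artifacts of PCR-based
sequencing, and batch effects of the particular sequencers used.  The GSVD
separates these blindly, using only the shared-column/independent-row
structure of the data.

## The model

For tumor and normal matrices `D1 (K1 x L)` and `D2 (K2 x L)` of full
column rank `L <= Ki`, the GSVD factorizes both simultaneously:

    Di = Ui Σi Vᵀ = Σ_a σ_{i,a} (u_{i,a} ⊗ v_aᵀ),   i = 1, 2

with dataset-specific column-wise orthonormal `Ui`, positive diagonal
`Σi = diag(σ_{i,a})`, and one shared invertible `V` whose transpose is
row-normalized.  Components are ordered by decreasing `σ_{1,a}/σ_{2,a}`,
and the **angular distance**

    θ_a = arctan(σ_{1,a}/σ_{2,a}) − π/4  ∈  (−π/4, π/4)

measures how exclusively component *a* belongs to the tumor dataset
(θ ≈ +π/4), the normal dataset (θ ≈ −π/4), or both (θ ≈ 0).  The fraction
`P_{i,a} = σ_{i,a}² / Σ_b σ_{i,b}²` measures a component's significance
within dataset *i*.

For platform-matched tensors `Di (Ki x L x M)` the tensor GSVD

    Di = Ri ×_a Ui ×_b Vx ×_c Vy

is computed from the GSVDs of three mode unfoldings; the core tensors
`Ri = Σi Vᵀ (Vy⁻ᵀ ⊗ Vx⁻ᵀ)` satisfy `|r_{1,abc}/r_{2,abc}| = σ_{1,a}/σ_{2,a}`
and `Θ_abc = arctan(|r1/r2|) − π/4 = θ_a` wherever defined, so exclusivity
is read off the row-mode angles alone.

Downstream, the selected component's tumor basis vector is the *pattern*:
segments are genotyped by the difference between segment and reference
medians in units of the pattern's median absolute deviation (MAD); patients
are called high/low by Spearman correlation of their tumor profile with the
pattern (cutoff 0.35) and by their superposition coefficient (cutoff
0.35 scaled by the norm of the correlation vector); and the high/low split
is carried into KM curves, log-rank tests and Cox models.

## Worked example

`examples/planted_pattern_recovery.py` generates the default synthetic
cohort — 600 bins x 100 patients, 20% of patients carrying a planted
loss + gain block pattern, plus shared germline variation, a GC artifact in
both datasets and dataset-exclusive sequencer batches — and decomposes it:

```
selected component 1: theta = 0.718 (pi/4 = 0.785)
corr(pattern, planted): 0.9809
corr(pattern, GC):      0.0235
batch component 2: theta = 0.666, MWW P vs batch labels = 4.37e-17
high-by-correlation: 20 patients (20 of 20 true carriers)
high-set overlap (coefficient vs correlation): 100%
```

The max-θ significant component recovers the planted pattern almost
perfectly while staying uncorrelated with the GC covariate; the next most
tumor-exclusive component is the sequencer-batch artifact (batches are
unmatched between tumor and normal, so the decomposition isolates them as
dataset-exclusive); and both patient-classification routes find exactly the
planted carriers.  `examples/survival_stratification.py` continues into
outcomes (planted 3x carrier hazard):

```
   carrier: n = 40, events = 35, KM median = 9.9 months
noncarrier: n = 160, events = 108, KM median = 36.8 months
log-rank: chi2 = 33.67, P = 6.52e-09
Cox carrier: HR = 3.13 [2.09, 4.68]
Cox stage: HR = 1.05 [0.89, 1.23]
```

The carrier hazard ratio recovers the planted 3x; stage, simulated
independently, stays near 1.  The other examples cover the GSVD basics,
the tensor identities, and the one-call pipeline
(`examples/full_pipeline.py`, or `cospec run --config run.yaml` from the
shell; `cospec simulate/gsvd/tgsvd/classify/survive` run the stages
individually).

## Layout

- `src/cospec/io.py` — data model (bins, profile matrices, matched pairs,
  segments, survival records) and TSV/BED/archive I/O
- `src/cospec/gsvd.py`, `src/cospec/tensor.py` — the decompositions
- `src/cospec/patterns.py` — component ranking, segment calls, patient
  classification, covariate association
- `src/cospec/survival.py` — KM / log-rank / Cox / PFS subsets
- `src/cospec/simulate.py` — synthetic cohorts with planted ground truth
- `src/cospec/pipeline.py`, `src/cospec/cli.py` — orchestration and the
  thin CLI
- `docs/methods.md` — modeling and numerical choices in detail
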