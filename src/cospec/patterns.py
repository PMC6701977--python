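"""Component selection, segment genotype calls, patient classification and
covariate association for GSVD/tensor-GSVD results.

The interpretation rules: a component is *exclusive* to the tumor dataset
when its angular distance theta_a is large and positive (ratio
sigma1/sigma2 >> 1), *significant* in a dataset when it captures a large
fraction P_{i,a} = sigma_{i,a}^2 / sum_b sigma_{i,b}^2 of that dataset's
squared information.  The component selected as "the pattern" is the most
exclusive among the significant ones.  Patients are then called high or low
by (a) their Spearman correlation with the pattern across bins and (b) the
superposition coefficient listed for them in the shared row basis vector;
segments are genotyped as amplified / unaltered / deleted by the difference
between segment and arm medians measured in units of the pattern's median
absolute deviation (MAD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gsvd import GSVDResult
from .io import GenomicBin, ProfileMatrix, SegmentSet
from .tensor import TensorGSVDResult


@dataclass
class ComponentRanking:
    """Exclusivity/significance flags per component and the selected index."""

    theta: np.ndarray
    significance1: np.ndarray
    significance2: np.ndarray
    exclusive_to_1: np.ndarray
    exclusive_to_2: np.ndarray
    significant_in_1: np.ndarray
    significant_in_2: np.ndarray
    selected: int | None
    theta_min: float
    p_min: float
    degenerate_groups: list[list[int]] = field(default_factory=list)


def rank_components(
    result: "GSVDResult | TensorGSVDResult",
    theta_min: float = 0.2,
    p_min: float = 0.01,
) -> ComponentRanking:
    """Flag tumor/normal-exclusive and significant components; select one.

    The selected component is the max-theta component among those
    significant in dataset 1.  Components inside a degenerate ratio group
    inherit the group's strongest flags, since the decomposition is only
    unique up to rotation there.
    """
    if isinstance(result, TensorGSVDResult):
        result = result.row_mode
    theta = result.theta
    p1, p2 = result.significance1, result.significance2
    excl1 = theta >= theta_min
    excl2 = theta <= -theta_min
    sig1 = p1 >= p_min
    sig2 = p2 >= p_min
    for group in result.degenerate_groups:
        idx = np.asarray(group)
        excl1[idx] = excl1[idx].any()
        excl2[idx] = excl2[idx].any()
        sig1[idx] = sig1[idx].any()
        sig2[idx] = sig2[idx].any()
    candidates = np.flatnonzero(sig1)
    if candidates.size == 0:
        warnings.warn("no component is significant in dataset 1", stacklevel=2)
        selected = None
    else:
        selected = int(candidates[np.argmax(theta[candidates])])
    return ComponentRanking(
        theta=theta,
        significance1=p1,
        significance2=p2,
        exclusive_to_1=excl1,
        exclusive_to_2=excl2,
        significant_in_1=sig1,
        significant_in_2=sig2,
        selected=selected,
        theta_min=theta_min,
        p_min=p_min,
        degenerate_groups=list(result.degenerate_groups),
    )


# ---------------------------------------------------------------------------
# segment genotype calls


@dataclass
class SegmentCall:
    label: str
    arm: str
    n_probes: int
    segment_median: float
    arm_median: float
    mad: float
    delta_in_mads: float
    call: str  # amplified | unaltered | deleted
    retained: bool


def _arm_spans(segments: SegmentSet) -> dict[str, tuple[str, int, int]]:
    spans: dict[str, tuple[str, int, int]] = {}
    for seg in segments:
        if seg.arm in spans:
            chrom, lo, hi = spans[seg.arm]
            if chrom != seg.chrom:
                raise ValueError(f"arm {seg.arm} spans multiple chromosomes")
            spans[seg.arm] = (chrom, min(lo, seg.start), max(hi, seg.end))
        else:
            spans[seg.arm] = (seg.chrom, seg.start, seg.end)
    return spans


def classify_segments(
    pattern: np.ndarray,
    bins: list[GenomicBin],
    segments: SegmentSet,
    t_mad: float = 1.0,
    min_probes: int = 30,
    arm_spans: "dict[str, tuple[str, int, int]] | None" = None,
    reference: str = "pooled",
) -> list[SegmentCall]:
    """Call segments amplified/unaltered/deleted against a bin-level pattern.

    The dispersion unit is one MAD of the pattern over all bins of the arms
    involved.  With ``reference='pooled'`` (default) each segment median is
    compared with the median over all arm bins pooled together — the right
    reference when an alteration spans most of a single arm, as a
    chromosome-arm-wide loss does, because that arm's own median *is* the
    altered level.  ``reference='arm'`` compares each segment with the
    median of its own arm instead.  A segment is called amplified when the
    difference exceeds ``t_mad`` MADs, deleted below ``-t_mad``, otherwise
    unaltered.  Segments covering ``min_probes`` probes or fewer are kept in
    the output but marked not retained.  Arm extents default to the span of
    each arm's own segments; pass ``arm_spans`` (arm -> (chrom, start, end))
    to override.

    Invariant under adding a constant to the whole pattern: medians shift
    together and the MAD is unchanged, so every call is preserved.
    """
    if reference not in ("pooled", "arm"):
        raise ValueError("reference must be 'pooled' or 'arm'")
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape[0] != len(bins):
        raise ValueError("pattern length must equal the number of bins")
    spans = arm_spans if arm_spans is not None else _arm_spans(segments)

    def bin_idx(chrom: str, start: int, end: int) -> np.ndarray:
        return np.array(
            [
                i
                for i, b in enumerate(bins)
                if b.chrom == chrom and b.start < end and b.end > start
            ],
            dtype=int,
        )

    arm_bins = {arm: bin_idx(*span) for arm, span in spans.items()}
    covered = sorted({i for idx in arm_bins.values() for i in idx})
    if not covered:
        raise ValueError("arms cover no bins")
    arm_values = pattern[covered]
    mad = float(stats.median_abs_deviation(arm_values, scale=1.0))
    pooled_median = float(np.median(arm_values))
    arm_medians = {arm: float(np.median(pattern[idx])) for arm, idx in arm_bins.items()}

    calls = []
    for seg in segments:
        idx = bin_idx(seg.chrom, seg.start, seg.end)
        if idx.size == 0:
            raise ValueError(f"segment {seg.label} maps to no bins")
        seg_median = float(np.median(pattern[idx]))
        n_probes = int(sum(bins[i].n_probes for i in idx))
        ref = pooled_median if reference == "pooled" else arm_medians[seg.arm]
        delta = (seg_median - ref) / mad if mad > 0 else 0.0
        if delta > t_mad:
            call = "amplified"
        elif delta < -t_mad:
            call = "deleted"
        else:
            call = "unaltered"
        calls.append(
            SegmentCall(
                label=seg.label,
                arm=seg.arm,
                n_probes=n_probes,
                segment_median=seg_median,
                arm_median=arm_medians[seg.arm],
                mad=mad,
                delta_in_mads=delta,
                call=call,
                retained=n_probes > min_probes,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# patient classification


def correlate_patients(pattern: np.ndarray, tumor: ProfileMatrix) -> np.ndarray:
    """Spearman correlation of every patient column with the pattern.

    Ties get average ranks; a constant column has undefined rank correlation
    and is stored as NaN.  Invariant under strictly monotone transforms of
    the pattern.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape[0] != tumor.k:
        raise ValueError("pattern length must equal the tumor bin count")
    pr = stats.rankdata(pattern)
    pr = pr - pr.mean()
    denom_p = np.sqrt(np.sum(pr**2))
    out = np.empty(tumor.l)
    for j in range(tumor.l):
        col = tumor.values[:, j]
        if np.ptp(col) == 0:
            out[j] = np.nan
            continue
        cr = stats.rankdata(col)
        cr = cr - cr.mean()
        out[j] = float(np.dot(pr, cr) / (denom_p * np.sqrt(np.sum(cr**2))))
    return out


@dataclass
class PatternClassification:
    patients: list[str]
    coefficients: np.ndarray
    correlations: np.ndarray
    high_by_coefficient: np.ndarray
    high_by_correlation: np.ndarray
    corr_cutoff: float
    coeff_cutoff: float
    scaling: str = "divide"

    @property
    def overlap_fraction(self) -> float:
        """|high-by-coeff intersect high-by-corr| / size of the smaller set."""
        a = set(np.flatnonzero(self.high_by_coefficient))
        b = set(np.flatnonzero(self.high_by_correlation))
        smaller = min(len(a), len(b))
        if smaller == 0:
            return float("nan")
        return len(a & b) / smaller


def classify_patients(
    correlations: np.ndarray,
    coefficients: np.ndarray,
    corr_cutoff: float = 0.35,
    patients: "list[str] | None" = None,
    scaling: str = "divide",
) -> PatternClassification:
    """Call patients high/low by correlation and by superposition coefficient.

    The correlation cutoff (default 0.35) applies directly to the Spearman
    correlations; the coefficient cutoff is obtained by scaling 0.35 by the
    Frobenius (Euclidean) norm of the correlation vector.  With the default
    ``scaling='divide'`` this reads corr_cutoff / ||correlations||: the
    unit-norm row basis vector is approximately the correlation vector
    rescaled to unit norm, so dividing maps the cutoff onto the coefficient
    scale.  ``scaling='multiply'`` is available for the opposite reading.
    Both comparisons are strict (">").
    """
    correlations = np.asarray(correlations, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    if correlations.shape != coefficients.shape:
        raise ValueError("correlations and coefficients must have equal length")
    valid = ~np.isnan(correlations)
    if not valid.any():
        raise ValueError("all correlations are missing")
    norm = float(np.linalg.norm(correlations[valid]))
    if scaling == "divide":
        coeff_cutoff = corr_cutoff / norm
    elif scaling == "multiply":
        coeff_cutoff = corr_cutoff * norm
    else:
        raise ValueError("scaling must be 'divide' or 'multiply'")
    high_corr = np.where(valid, correlations > corr_cutoff, False)
    high_coeff = coefficients > coeff_cutoff
    if patients is None:
        patients = [f"P{j}" for j in range(correlations.shape[0])]
    return PatternClassification(
        patients=list(patients),
        coefficients=coefficients,
        correlations=correlations,
        high_by_coefficient=high_coeff,
        high_by_correlation=high_corr,
        corr_cutoff=corr_cutoff,
        coeff_cutoff=coeff_cutoff,
        scaling=scaling,
    )


def orient_component(
    coefficients: np.ndarray, correlations: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Resolve the +-1 phase of a component for high/low classification.

    The GSVD sign convention fixes signs by the largest entry of v_a, which
    says nothing about which tail of the coefficient distribution carries
    the pattern.  A minority of carriers forms a heavy tail; orient so that
    tail is positive, i.e. flip when the correlation vector's skewness is
    negative.  Returns (coefficients, correlations, sign).
    """
    correlations = np.asarray(correlations, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    valid = correlations[~np.isnan(correlations)]
    sign = 1
    if valid.size >= 3 and stats.skew(valid) < 0:
        sign = -1
    return sign * coefficients, sign * correlations, sign


# ---------------------------------------------------------------------------
# covariate association


@dataclass
class CovariateAssociation:
    vector_id: str
    covariate: str
    pearson: float | None = None
    spearman: float | None = None
    mww_p: float | None = None
    hypergeom_p: float | None = None


def _mww(x: np.ndarray, y: np.ndarray) -> float | None:
    """Two-sided MWW P: exact for small tie-free groups, else asymptotic
    with tie correction."""
    if len(x) < 1 or len(y) < 1:
        return None
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def covariate_association(
    vector: np.ndarray,
    covariate: np.ndarray,
    high_set: "set[int] | None" = None,
    vector_id: str = "component",
    covariate_name: str = "covariate",
) -> CovariateAssociation:
    """Associate a basis vector with an experimental covariate.

    Numeric covariates get Pearson and Spearman correlations, plus (when a
    high/low split of the vector's entries is supplied) a two-sided MWW P
    comparing the covariate between the high set and its complement.
    Categorical covariates get a two-sided MWW P comparing the vector's
    entries between the two groups (binary case) and, given a high set, an
    upper-tail hypergeometric P for over-enrichment of each category's most
    enriched level in the high set.
    """
    vector = np.asarray(vector, dtype=float)
    covariate = np.asarray(covariate)
    if vector.shape[0] != covariate.shape[0]:
        raise ValueError("vector and covariate must have equal length")
    out = CovariateAssociation(vector_id=vector_id, covariate=covariate_name)
    numeric = np.issubdtype(covariate.dtype, np.number) and (
        len(np.unique(covariate)) > 2
    )
    n = vector.shape[0]
    if numeric:
        cov = covariate.astype(float)
        out.pearson = float(stats.pearsonr(vector, cov)[0])
        out.spearman = float(stats.spearmanr(vector, cov)[0])
        if high_set is not None:
            hi = np.array(sorted(high_set), dtype=int)
            lo = np.setdiff1d(np.arange(n), hi)
            out.mww_p = _mww(cov[hi], cov[lo])
    else:
        labels = np.unique(covariate)
        if len(labels) == 2:
            g0 = vector[covariate == labels[0]]
            g1 = vector[covariate == labels[1]]
            out.mww_p = _mww(g0, g1)
        if high_set is not None and len(labels) >= 2:
            hi = set(int(i) for i in high_set)
            best = None
            for lab in labels:
                members = set(np.flatnonzero(covariate == lab).tolist())
                k = len(hi & members)
                p = float(stats.hypergeom.sf(k - 1, n, len(members), len(hi)))
                best = p if best is None else min(best, p)
            out.hypergeom_p = best
    return out
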