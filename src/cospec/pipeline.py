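"""End-to-end orchestration: simulate/load -> decompose -> rank -> classify
-> survival, with a machine-readable summary."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gsvd as _gsvd
from . import io as _io
from . import patterns as _patterns
from . import simulate as _simulate
from . import survival as _survival
from . import tensor as _tensor

log = logging.getLogger("cospec")


@dataclass
class RunConfig:
    """One reproducible run: either simulate (with a SyntheticConfig) or load
    tumor/normal/clinical/segment files; thresholds are echoed verbatim into
    the summary so no default stays hidden."""

    out_dir: str
    simulate: "_simulate.SyntheticConfig | None" = None
    tumor_path: str | None = None
    normal_path: str | None = None
    clinical_path: str | None = None
    segments_bed: str | None = None
    arm_table: str | None = None
    mode: str = "matrix"  # matrix | tensor
    theta_min: float = 0.2
    p_min: float = 0.01
    corr_cutoff: float = 0.35
    t_mad: float = 1.0
    min_probes: int = 30
    platinum_only: bool = False
    min_pfs: float | None = None
    with_stage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.tumor_path is not None
        if (self.simulate is None) == (not has_files):
            raise ValueError("provide exactly one of a simulation config or input paths")
        if self.mode not in ("matrix", "tensor"):
            raise ValueError("mode must be 'matrix' or 'tensor'")


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_end_to_end(config: RunConfig) -> Path:
    """Run the whole workflow; returns the report directory.

    Stage order mirrors the analysis: decomposition -> component ranking ->
    segment genotype calls -> patient classification -> KM/log-rank/Cox.
    Deterministic for a fixed config and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "thresholds": {
            "theta_min": config.theta_min,
            "p_min": config.p_min,
            "corr_cutoff": config.corr_cutoff,
            "t_mad": config.t_mad,
            "min_probes": config.min_probes,
        },
        "seed": config.seed,
        "mode": config.mode,
        "stages": [],
    }

    # -- stage: inputs -----------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        pair, truth = _simulate.generate_matched_pair(sim)
        records = _simulate.generate_survival(truth, sim, pair.patients)
        segments = _simulate.pattern_segments(sim)
        _io.write_profile_matrix(pair.tumor, out / "tumor.tsv")
        _io.write_profile_matrix(pair.normal, out / "normal.tsv")
        _io.write_clinical(records, out / "clinical.tsv")
        _io.write_segments(segments, out / "segments.bed", out / "arms.tsv")
        _simulate.truth_to_json(truth, out / "ground_truth.json")
    else:
        tumor = _io.read_profile_matrix(config.tumor_path)
        normal = _io.read_profile_matrix(config.normal_path)
        pair = _io.match_patients(tumor, normal)
        records = (
            _io.read_clinical(config.clinical_path) if config.clinical_path else []
        )
        segments = (
            _io.read_segments(config.segments_bed, config.arm_table)
            if config.segments_bed
            else None
        )
    log.info("stage=inputs patients=%d k1=%d k2=%d", len(pair.patients),
             pair.tumor.k, pair.normal.k)
    summary["stages"].append("inputs")

    # -- stage: decomposition ---------------------------------------------
    result = _gsvd.compute_gsvd(pair)
    _io.save_archive(_gsvd.gsvd_factors_dict(result), out / "decomposition.npz")
    comp = pd.DataFrame(
        {
            "component": np.arange(1, result.n_components + 1),
            "sigma1": result.sigma1,
            "sigma2": result.sigma2,
            "ratio": result.ratios,
            "theta": result.theta,
            "significance1": result.significance1,
            "significance2": result.significance2,
        }
    )
    comp.to_csv(out / "components.tsv", sep="\t", index=False, float_format="%.10g")
    summary["stages"].append("decomposition")

    # -- stage: ranking ----------------------------------------------------
    ranking = _patterns.rank_components(result, config.theta_min, config.p_min)
    if ranking.selected is None:
        summary["selected_component"] = None
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return out
    a = ranking.selected
    pattern = result.U1[:, a]
    coefficients = result.Vt[a, :]
    summary["stages"].append("ranking")
    summary["selected_component"] = int(a) + 1
    summary["selected_theta"] = float(result.theta[a])

    # -- stage: classification ----------------------------------------------
    correlations = _patterns.correlate_patients(pattern, pair.tumor)
    coefficients, correlations, sign = _patterns.orient_component(
        coefficients, correlations
    )
    pattern = sign * pattern
    np.savetxt(out / "pattern.tsv", pattern, delimiter="\t")
    cls = _patterns.classify_patients(
        correlations, coefficients, config.corr_cutoff, patients=pair.patients
    )
    pd.DataFrame(
        {
            "patient_id": cls.patients,
            "coefficient": cls.coefficients,
            "spearman_correlation": cls.correlations,
            "high_by_coefficient": cls.high_by_coefficient.astype(int),
            "high_by_correlation": cls.high_by_correlation.astype(int),
        }
    ).to_csv(out / "classification.tsv", sep="\t", index=False, float_format="%.10g")
    summary["stages"].append("classification")
    summary["coeff_cutoff"] = cls.coeff_cutoff
    summary["n_high_by_correlation"] = int(cls.high_by_correlation.sum())
    summary["n_high_by_coefficient"] = int(cls.high_by_coefficient.sum())
    overlap = cls.overlap_fraction
    summary["high_set_overlap"] = None if np.isnan(overlap) else float(overlap)

    if segments is not None and len(segments) > 0:
        calls = _patterns.classify_segments(
            pattern, pair.tumor.bins, segments, config.t_mad, config.min_probes
        )
        pd.DataFrame(
            {
                "label": [c.label for c in calls],
                "arm": [c.arm for c in calls],
                "n_probes": [c.n_probes for c in calls],
                "delta_in_mads": [c.delta_in_mads for c in calls],
                "call": [c.call for c in calls],
                "retained": [int(c.retained) for c in calls],
            }
        ).to_csv(out / "segment_calls.tsv", sep="\t", index=False,
                 float_format="%.10g")
        summary["segment_calls"] = {c.label: c.call for c in calls}
        summary["stages"].append("segments")

    # -- stage: survival ----------------------------------------------------
    if records:
        if config.platinum_only:
            records = [r for r in records if r.platinum]
        if config.min_pfs is not None:
            records = _survival.pfs_subset(records, config.min_pfs)
        high = {p for p, h in zip(cls.patients, cls.high_by_correlation) if h}
        groups = {
            r.patient_id: ("high" if r.patient_id in high else "low")
            for r in records
        }
        n_high = sum(1 for g in groups.values() if g == "high")
        surv: dict = {"n": len(records), "n_high": n_high}
        if 0 < n_high < len(records):
            curves = _survival.km_curves(records, groups)
            surv["km_medians"] = {
                c.label: c.median_survival_months for c in curves
            }
            km_rows = []
            for c in curves:
                for t, s in zip(c.step_times, c.survival):
                    km_rows.append((c.label, t, s))
            pd.DataFrame(km_rows, columns=["group", "time", "survival"]).to_csv(
                out / "km_curves.tsv", sep="\t", index=False, float_format="%.10g"
            )
            lr = _survival.logrank(records, groups)
            surv["logrank_p"] = lr["p_value"]
            covs: dict[str, dict[str, float]] = {
                "pattern_high": {
                    r.patient_id: float(groups[r.patient_id] == "high")
                    for r in records
                }
            }
            if config.with_stage:
                covs["stage"] = {
                    r.patient_id: float(r.stage)
                    for r in records
                    if r.stage is not None
                }
            try:
                fit = _survival.cox_fit(records, covs)
                surv["cox"] = {
                    "hazard_ratios": fit.hazard_ratios,
                    "ci_lower": fit.ci_lower,
                    "ci_upper": fit.ci_upper,
                    "concordance": fit.concordance,
                    "n": fit.n,
                    "events": fit.events,
                }
            except (ValueError, RuntimeError) as exc:
                surv["cox"] = {"error": str(exc)}
        else:
            surv["logrank_p"] = None
        summary["survival"] = surv
        summary["stages"].append("survival")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("stage=done out=%s", out)
    return out
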