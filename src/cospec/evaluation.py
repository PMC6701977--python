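"""Benchmark routines that exercise the package under its reference study
conditions: numerical exactness sweeps for the decompositions, blind-source-
separation and classification recovery on the default synthetic cohort, and
survival-model calibration.  Each routine regenerates its inputs from a seed
and measures the result, so the numbers it returns are always recomputed."""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .gsvd import gsvd_matrices, reconstruct
from .io import MatchedTensorPair
from .patterns import (
    classify_patients,
    correlate_patients,
    covariate_association,
    orient_component,
    rank_components,
)
from .simulate import GroundTruth, SyntheticConfig, generate_matched_pair, generate_survival
from .survival import cox_fit, logrank
from .tensor import compute_tensor_gsvd, reconstruct_tensor

QUARTER_PI = np.pi / 4.0


def _random_pair(rng: np.random.Generator, k_max: int, l_max: int):
    l = int(rng.integers(2, l_max + 1))
    k1 = int(rng.integers(l, k_max + 1))
    k2 = int(rng.integers(l, k_max + 1))
    return rng.normal(size=(k1, l)), rng.normal(size=(k2, l))


def gsvd_exactness_suite(
    n_pairs: int = 100, seed: int = 0, k_max: int = 50, l_max: int = 10
) -> dict[str, float]:
    """Reconstruction, orthonormality, row-norm and generalized-eigenvalue
    oracle errors over seeded random full-column-rank pairs."""
    rng = np.random.default_rng(seed)
    recon = orth = rownorm = oracle = 0.0
    for _ in range(n_pairs):
        d1, d2 = _random_pair(rng, k_max, l_max)
        res = gsvd_matrices(d1, d2)
        l = d1.shape[1]
        for d, i in ((d1, 1), (d2, 2)):
            recon = max(
                recon,
                np.linalg.norm(reconstruct(res, i) - d) / np.linalg.norm(d),
            )
        for u in (res.U1, res.U2):
            orth = max(orth, float(np.max(np.abs(u.T @ u - np.eye(l)))))
        rownorm = max(
            rownorm, float(np.max(np.abs(np.linalg.norm(res.Vt, axis=1) - 1.0)))
        )
        eig = np.sort(linalg.eigvals(np.linalg.solve(d2.T @ d2, d1.T @ d1)).real)[::-1]
        oracle = max(
            oracle, float(np.max(np.abs(res.ratios**2 - eig) / np.abs(eig)))
        )
    return {
        "n_pairs": n_pairs,
        "max_reconstruction_error": recon,
        "max_orthonormality_error": orth,
        "max_row_norm_error": rownorm,
        "max_oracle_error": oracle,
    }


def theta_bound_suite(
    n_pairs: int = 1000, seed: int = 0, k_max: int = 30, l_max: int = 8
) -> dict[str, float]:
    """Angular distances over many random pairs; all must lie strictly
    inside (-pi/4, pi/4)."""
    rng = np.random.default_rng(seed)
    max_abs = 0.0
    all_inside = True
    for _ in range(n_pairs):
        d1, d2 = _random_pair(rng, k_max, l_max)
        res = gsvd_matrices(d1, d2)
        max_abs = max(max_abs, float(np.max(np.abs(res.theta))))
        all_inside &= bool(np.all(np.abs(res.theta) < QUARTER_PI))
    return {"n_pairs": n_pairs, "max_abs_theta": max_abs,
            "all_strictly_inside": float(all_inside)}


def tensor_identity_suite(
    n_pairs: int = 50, seed: int = 0, k_max: int = 40, l_max: int = 4,
    m_max: int = 3,
) -> dict[str, float]:
    """Multilinear reconstruction plus the core-ratio and Theta identities
    on seeded random tensor pairs."""
    rng = np.random.default_rng(seed)
    recon = ratio_err = theta_err = 0.0
    for _ in range(n_pairs):
        l = int(rng.integers(2, l_max + 1))
        m = int(rng.integers(2, m_max + 1))
        k1 = int(rng.integers(l * m, k_max + 1))
        k2 = int(rng.integers(l * m, k_max + 1))
        t1 = rng.normal(size=(k1, l, m))
        t2 = rng.normal(size=(k2, l, m))
        tpair = MatchedTensorPair(
            tumor=t1, normal=t2,
            patients=[f"p{i}" for i in range(l)],
            platforms=[f"m{i}" for i in range(m)],
        )
        res = compute_tensor_gsvd(tpair)
        for i, t in ((1, t1), (2, t2)):
            recon = max(
                recon,
                np.linalg.norm(reconstruct_tensor(res, i) - t)
                / np.linalg.norm(t),
            )
        sig_ratio = res.row_mode.sigma1 / res.row_mode.sigma2
        defined = np.abs(res.R2) > 1e-10 * np.max(np.abs(res.R2))
        obs = np.abs(res.R1[defined] / res.R2[defined])
        exp = np.broadcast_to(sig_ratio[:, None, None], res.R1.shape)[defined]
        ratio_err = max(ratio_err, float(np.max(np.abs(obs - exp) / exp)))
        th = np.broadcast_to(
            res.row_mode.theta[:, None, None], res.Theta.shape
        )
        mask = ~np.isnan(res.Theta)
        theta_err = max(
            theta_err, float(np.max(np.abs(res.Theta[mask] - th[mask])))
        )
    return {
        "n_pairs": n_pairs,
        "max_reconstruction_error": recon,
        "max_ratio_identity_error": ratio_err,
        "max_theta_identity_error": theta_err,
    }


def balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    sens = float((pred & truth).sum()) / max(int(truth.sum()), 1)
    specificity = float((~pred & ~truth).sum()) / max(int((~truth).sum()), 1)
    return 0.5 * (sens + specificity)


def blind_source_separation(seed: int = 1) -> dict[str, float]:
    """Run the full recovery study on the default synthetic cohort.

    One cohort at the default conditions (K = 600, L = 100, carrier
    fraction 0.2, pattern amplitude 1.0, noise 0.25, GC and batch artifacts
    on); returns the selected component's correlation with the planted
    pattern and with the GC covariate, the batch component's MWW P, the
    patient-classification balanced accuracies and the overlap of the two
    high sets."""
    cfg = SyntheticConfig(seed=seed)
    pair, truth = generate_matched_pair(cfg)
    res = gsvd_matrices(pair.tumor.values, pair.normal.values)
    ranking = rank_components(res)
    a = ranking.selected
    pattern = res.U1[:, a]
    pattern_corr = float(np.corrcoef(pattern, truth.pattern_tumor)[0, 1])
    gc_corr = float(np.corrcoef(pattern, truth.gc_tumor)[0, 1])

    # the most tumor-exclusive component apart from the selected pattern is
    # the sequencer-batch component (batches are unmatched between datasets)
    others = [i for i in np.argsort(-res.theta) if i != a]
    batch_idx = int(others[0])
    assoc = covariate_association(
        res.Vt[batch_idx, :], truth.batch_tumor.astype(str),
        vector_id=f"component_{batch_idx + 1}", covariate_name="tumor_batch",
    )

    correlations = correlate_patients(pattern, pair.tumor)
    coefficients, correlations, _ = orient_component(res.Vt[a, :], correlations)
    cls = classify_patients(correlations, coefficients, patients=pair.patients)
    return {
        "n_patients": cfg.l,
        "selected_theta": float(res.theta[a]),
        "pattern_abs_correlation": abs(pattern_corr),
        "gc_abs_correlation": abs(gc_corr),
        "batch_theta": float(res.theta[batch_idx]),
        "batch_mww_p": float(assoc.mww_p),
        "balanced_accuracy_by_correlation": balanced_accuracy(
            cls.high_by_correlation, truth.carriers
        ),
        "balanced_accuracy_by_coefficient": balanced_accuracy(
            cls.high_by_coefficient, truth.carriers
        ),
        "high_set_overlap": float(cls.overlap_fraction),
    }


def _survival_truth(carriers: np.ndarray, cfg: SyntheticConfig) -> GroundTruth:
    z = np.zeros(1)
    n = len(carriers)
    return GroundTruth(z, z, carriers, z, z, np.zeros(n), np.zeros(n),
                       cfg.baseline_hazard, cfg.hazard_ratio, cfg.censoring_rate)


def cox_coverage(
    hazard_ratio: float, n: int = 500, n_reps: int = 200, seed: int = 0
) -> dict[str, float]:
    """Fraction of replicate Cox fits whose 95% CI covers the true hazard
    ratio, under the exponential proportional-hazards generator."""
    rng = np.random.default_rng(seed)
    covered = 0
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SyntheticConfig(k1=2 * n, k2=2 * n, l=n, m=1,
                              hazard_ratio=hazard_ratio, seed=rep_seed)
        rep_rng = np.random.default_rng(rep_seed)
        carriers = np.zeros(n, dtype=bool)
        carriers[rep_rng.choice(n, int(round(0.2 * n)), replace=False)] = True
        recs = generate_survival(_survival_truth(carriers, cfg), cfg)
        fit = cox_fit(
            recs,
            {"pattern_high": {r.patient_id: float(carriers[i])
                              for i, r in enumerate(recs)}},
        )
        lo, hi = fit.ci_lower["pattern_high"], fit.ci_upper["pattern_high"]
        covered += int(lo <= hazard_ratio <= hi)
    return {"n_reps": n_reps, "n": n, "coverage": covered / n_reps}


def planted_logrank(seed: int = 5, n: int = 200) -> dict[str, float]:
    """Two-group log-rank on the planted carrier split, HR = 3, with the
    censoring level implying >= 60% events."""
    cfg = SyntheticConfig(k1=2 * n, k2=2 * n, l=n, m=1, hazard_ratio=3.0,
                          censoring_rate=0.3, seed=seed)
    rng = np.random.default_rng(seed)
    carriers = np.zeros(n, dtype=bool)
    carriers[rng.choice(n, int(round(0.2 * n)), replace=False)] = True
    recs = generate_survival(_survival_truth(carriers, cfg), cfg)
    event_rate = float(np.mean([r.os_event for r in recs]))
    groups = {r.patient_id: ("carrier" if carriers[i] else "noncarrier")
              for i, r in enumerate(recs)}
    res = logrank(recs, groups)
    return {"n": n, "event_rate": event_rate, "p_value": float(res["p_value"])}
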