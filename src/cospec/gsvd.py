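"""Exact generalized singular value decomposition of a matched matrix pair.

The GSVD simultaneously factorizes two column-matched, row-independent
matrices D1 (K1 x L) and D2 (K2 x L), both of full column rank L <= K_i, as

    D_i = U_i @ Sigma_i @ V.T,    i = 1, 2,

with dataset-specific column-wise orthonormal U_i, positive diagonal cores
Sigma_i = diag(sigma_{i,a}) and one shared invertible factor V whose
transpose is row-normalized.  Components are ordered by decreasing ratio
sigma_{1,a} / sigma_{2,a}, so the leading components are the ones most
exclusive to the first (tumor) dataset and the trailing ones most exclusive
to the second (normal) dataset.  The angular distance

    theta_a = arctan(sigma_{1,a} / sigma_{2,a}) - pi/4    in (-pi/4, pi/4)

maps that ratio onto a symmetric scale: theta near +pi/4 means the component
is approximately exclusive to dataset 1, theta near 0 means it is equally
present in both, theta near -pi/4 exclusive to dataset 2.

Algorithm
---------
The stacked matrix [D1; D2] is factored by a thin QR; the partitioned
orthonormal factor [Q1; Q2] is then split by the cosine-sine construction:
an SVD Q1 = P1 C Z^T yields the cosines, and Q2 Z has orthogonal columns
whose norms are the sines S = sqrt(I - C^2).  Row norms of Z^T R are
absorbed symmetrically into both diagonal cores so that V^T is
row-normalized; the absorbed scale is shared per component, which leaves
every ratio and every angular distance unchanged.

The decomposition is unique up to a shared +-1 per component triplet
(u_{1,a}, u_{2,a}, v_a), except inside degenerate subspaces of equal ratio;
the sign convention here (largest-magnitude entry of each v_a made
positive) resolves the phase, and degenerate index groups are reported on
the result for downstream interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .io import MatchedPair

_QUARTER_PI = np.pi / 4.0


class RankError(ValueError):
    """A dataset fails the full-column-rank requirement."""


@dataclass
class GSVDResult:
    """Factors and derived quantities of one GSVD.

    Attributes
    ----------
    U1, U2 : (K_i, L) column-wise orthonormal dataset-specific basis.
    sigma1, sigma2 : (L,) positive generalized singular values.
    V : (L, L) shared invertible factor; ``V.T`` is row-normalized.
    theta : (L,) angular distances in (-pi/4, pi/4).
    ratios : (L,) sigma1/sigma2, nonincreasing.
    significance1, significance2 : (L,) fraction of each dataset's squared
        information captured by each component (sums to 1).
    degenerate_groups : index groups with numerically equal ratios, where
        the decomposition is unique only up to rotation within the group.
    """

    U1: np.ndarray
    U2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    V: np.ndarray
    theta: np.ndarray
    ratios: np.ndarray
    significance1: np.ndarray
    significance2: np.ndarray
    degenerate_groups: list[list[int]] = field(default_factory=list)
    scale_convention: str = "shared row norm absorbed equally into Sigma1 and Sigma2"

    @property
    def n_components(self) -> int:
        return self.sigma1.shape[0]

    @property
    def Vt(self) -> np.ndarray:
        return self.V.T


def angular_distance(sigma1_a: float, sigma2_a: float) -> float:
    """Angular distance arctan(sigma1/sigma2) - pi/4 of one component.

    Antisymmetric under swapping the two datasets and strictly inside
    (-pi/4, pi/4) for positive inputs.
    """
    if sigma1_a <= 0 or sigma2_a <= 0:
        raise ValueError("generalized singular values must be strictly positive")
    return float(np.arctan2(sigma1_a, sigma2_a) - _QUARTER_PI)


def _check_full_rank(values: np.ndarray, rank_tol: float, name: str) -> None:
    k, l = values.shape
    if l > k:
        raise RankError(f"{name}: L={l} patients exceed K={k} bins (need L <= K)")
    sv = linalg.svdvals(values)
    if sv[0] == 0 or sv[-1] <= rank_tol * sv[0]:
        raise RankError(
            f"{name}: rank-deficient (smallest/largest singular value "
            f"{0.0 if sv[0] == 0 else sv[-1] / sv[0]:.3e} <= rank_tol {rank_tol:.1e})"
        )


def compute_gsvd(pair: MatchedPair, rank_tol: float = 1e-10) -> GSVDResult:
    """Compute the exact GSVD of a patient-matched tumor/normal pair.

    Deterministic for fixed input: components are sorted by decreasing
    sigma1/sigma2 (ties broken by decreasing sigma1, then pre-sort index)
    and signs fixed so the largest-magnitude entry of every v_a is positive.
    """
    return gsvd_matrices(pair.tumor.values, pair.normal.values, rank_tol=rank_tol)


def gsvd_matrices(
    d1: np.ndarray, d2: np.ndarray, rank_tol: float = 1e-10
) -> GSVDResult:
    """GSVD of two raw arrays sharing a column axis (see :func:`compute_gsvd`)."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape[1] != d2.shape[1]:
        raise ValueError("the two matrices must share the patient (column) axis")
    _check_full_rank(d1, rank_tol, "dataset 1 (tumor)")
    _check_full_rank(d2, rank_tol, "dataset 2 (normal)")
    k1, l = d1.shape

    q, r = linalg.qr(np.vstack([d1, d2]), mode="economic")
    q1, q2 = q[:k1], q[k1:]

    # CS construction: cosines from the SVD of the top block, sines as the
    # column norms of Q2 @ Z (orthogonal because Q1^T Q1 + Q2^T Q2 = I).
    p1, c, zt = linalg.svd(q1, full_matrices=False)
    c = np.clip(c, 0.0, 1.0)
    b = q2 @ zt.T
    s = np.linalg.norm(b, axis=0)
    if np.any(c == 0):
        raise RankError("dataset 1 (tumor): zero cosine — rank-deficient pair")
    if np.any(s == 0):
        raise RankError("dataset 2 (normal): zero sine — rank-deficient pair")
    u1 = p1
    u2 = b / s

    xt = zt @ r  # L x L invertible shared factor, rows not yet normalized
    row_norms = np.linalg.norm(xt, axis=1)
    vt = xt / row_norms[:, None]
    sigma1 = c * row_norms
    sigma2 = s * row_norms

    # Order by decreasing ratio; SVD already sorts c descending, but make the
    # tie-break (decreasing sigma1, then pre-sort index) explicit.
    ratios = sigma1 / sigma2
    order = sorted(range(l), key=lambda a: (-ratios[a], -sigma1[a], a))
    u1, u2 = u1[:, order], u2[:, order]
    sigma1, sigma2, ratios = sigma1[order], sigma2[order], ratios[order]
    vt = vt[order, :]

    # Sign convention: flip each triplet so the largest-|.| entry of v_a > 0.
    for a in range(l):
        j = int(np.argmax(np.abs(vt[a])))
        if vt[a, j] < 0:
            vt[a] *= -1.0
            u1[:, a] *= -1.0
            u2[:, a] *= -1.0

    theta = np.arctan2(sigma1, sigma2) - _QUARTER_PI
    sig1 = sigma1**2 / np.sum(sigma1**2)
    sig2 = sigma2**2 / np.sum(sigma2**2)

    return GSVDResult(
        U1=u1,
        U2=u2,
        sigma1=sigma1,
        sigma2=sigma2,
        V=vt.T,
        theta=theta,
        ratios=ratios,
        significance1=sig1,
        significance2=sig2,
        degenerate_groups=_degenerate_groups(ratios),
    )


def _degenerate_groups(ratios: np.ndarray, rel_tol: float = 1e-8) -> list[list[int]]:
    """Chain consecutive components whose ratios agree within rel_tol*max."""
    tol = rel_tol * float(np.max(ratios))
    groups: list[list[int]] = []
    current = [0]
    for a in range(1, len(ratios)):
        if abs(ratios[a] - ratios[a - 1]) < tol:
            current.append(a)
        else:
            if len(current) > 1:
                groups.append(current)
            current = [a]
    if len(current) > 1:
        groups.append(current)
    return groups


def reconstruct(
    result: GSVDResult,
    dataset_index: int,
    component_subset: "list[int] | None" = None,
) -> np.ndarray:
    """Sum of rank-1 terms sigma_{i,a} (u_{i,a} outer v_a) over a subset.

    ``component_subset`` uses 0-based component indices; None means all
    components (which reproduces D_i to working precision); the empty subset
    returns the zero matrix of the right shape.
    """
    if dataset_index not in (1, 2):
        raise ValueError("dataset_index must be 1 or 2")
    u = result.U1 if dataset_index == 1 else result.U2
    sigma = result.sigma1 if dataset_index == 1 else result.sigma2
    if component_subset is None:
        idx = np.arange(result.n_components)
    else:
        idx = np.asarray(sorted(component_subset), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= result.n_components):
            raise ValueError("component_subset outside valid range")
    if idx.size == 0:
        return np.zeros((u.shape[0], result.V.shape[0]))
    return (u[:, idx] * sigma[idx]) @ result.Vt[idx, :]


def gsvd_factors_dict(result: GSVDResult, prefix: str = "") -> dict[str, np.ndarray]:
    """Flatten a result into named arrays for archiving/TSV export."""
    return {
        f"{prefix}U1": result.U1,
        f"{prefix}U2": result.U2,
        f"{prefix}sigma1": result.sigma1,
        f"{prefix}sigma2": result.sigma2,
        f"{prefix}V": result.V,
        f"{prefix}theta": result.theta,
        f"{prefix}ratios": result.ratios,
        f"{prefix}significance1": result.significance1,
        f"{prefix}significance2": result.significance2,
    }
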