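"""Tensor GSVD of a matched pair of third-order tensors.

Two tensors D_i (K_i x L x M) sharing the patient (x) and platform (y) axes
but with independent row (bin) axes are factorized simultaneously as

    D_i = R_i x_a U_i x_b V_x x_c V_y
        = sum_{a,b,c} r_{i,abc} (u_{i,a} o v_{x,b} o v_{y,c}),

where x_a/x_b/x_c denote mode products, U_i (K_i x LM) are dataset-specific
column-wise orthonormal factors, V_x (L x L) and V_y (M x M) are shared
invertible factors with row-normalized transposes, and the core tensors R_i
(LM x L x M) hold the tensor generalized singular values r_{i,abc}.

The factors come from the GSVDs of three pairs of unfoldings: the row-mode
unfolding (K_i x LM) supplies U_i, Sigma_i and the row-mode shared factor
V^T; the x- and y-mode unfoldings supply V_x and V_y.  The cores follow by
contraction,

    R_i(unfolded) = Sigma_i V^T (V_y^{-T} kron V_x^{-T}),

so every defined ratio |r_{1,abc} / r_{2,abc}| collapses to the row-mode
ratio sigma_{1,a} / sigma_{2,a} > 0, and the tensor angular distance
Theta_abc = arctan(|r1/r2|) - pi/4 equals the row-mode theta_a.  Those two
identities are what make the tensor GSVD a comparative decomposition: the
exclusivity of a (u_{1,a}, v_{x,b}, v_{y,c}) combination is read off the
row-mode angle alone.

Index conventions (the algebra fixes the shapes, not the orders): the
row-mode unfolding puts the x index fastest, column (l, m) -> m*L + l,
which is exactly the order the Kronecker product V_y kron V_x expects, so
the core formula applies without any permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gsvd import GSVDResult, RankError, gsvd_matrices
from .io import MatchedTensorPair

_QUARTER_PI = np.pi / 4.0

_MODES = ("row", "x", "y")


def unfold(tensor: np.ndarray, mode: str) -> np.ndarray:
    """Unfold a K x L x M tensor along one mode.

    row : K x LM matrix, column (l, m) at index m*L + l (x varies fastest)
    x   : MK x L matrix (its transpose is L x MK, column (k, m) at m*K + k)
    y   : KL x M matrix (its transpose is M x KL, column (k, l) at l*K + k)
    """
    t = np.asarray(tensor, dtype=float)
    if t.ndim != 3:
        raise ValueError("expected a third-order tensor")
    k, l, m = t.shape
    if mode == "row":
        return t.transpose(0, 2, 1).reshape(k, m * l)
    if mode == "x":
        return t.transpose(1, 2, 0).reshape(l, m * k).T
    if mode == "y":
        return t.transpose(2, 1, 0).reshape(m, l * k).T
    raise ValueError(f"invalid mode {mode!r}; expected one of {_MODES}")


def refold(matrix: np.ndarray, mode: str, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given (K, L, M) shape."""
    a = np.asarray(matrix, dtype=float)
    k, l, m = shape
    if mode == "row":
        return a.reshape(k, m, l).transpose(0, 2, 1)
    if mode == "x":
        return a.T.reshape(l, m, k).transpose(2, 0, 1)
    if mode == "y":
        return a.T.reshape(m, l, k).transpose(2, 1, 0)
    raise ValueError(f"invalid mode {mode!r}; expected one of {_MODES}")


@dataclass
class TensorGSVDResult:
    """Factors of one tensor GSVD.

    ``row_mode`` is the embedded GSVD of the row unfoldings and carries the
    sigma's and theta's that the tensor identities refer back to.  ``Theta``
    entries where r_{2,abc} is numerically zero are NaN (undefined), never
    +-pi/4.  ``x_mode`` and ``y_mode`` are the intermediate GSVDs of the x/y
    unfoldings, exposed for verification.
    """

    U1: np.ndarray
    U2: np.ndarray
    Vx: np.ndarray
    Vy: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    Theta: np.ndarray
    row_mode: GSVDResult
    x_mode: GSVDResult
    y_mode: GSVDResult
    shape1: tuple[int, int, int] = (0, 0, 0)
    shape2: tuple[int, int, int] = (0, 0, 0)
    warnings: list[str] = field(default_factory=list)

    @property
    def r1(self) -> np.ndarray:
        return self.R1

    @property
    def r2(self) -> np.ndarray:
        return self.R2


def tensor_angular_distance(r1_abc: float, r2_abc: float) -> float:
    """Theta = arctan(|r1/r2|) - pi/4; NaN when the denominator vanishes."""
    if r2_abc == 0:
        return float("nan")
    return float(np.arctan(abs(r1_abc / r2_abc)) - _QUARTER_PI)


def _inv_transpose(vt: np.ndarray, label: str, notes: list[str]) -> np.ndarray:
    """(V^T)^{-1} by solving linear systems; warn on bad conditioning."""
    cond = np.linalg.cond(vt)
    if cond > 1e8:
        msg = f"{label}: shared factor condition number {cond:.2e} > 1e8"
        notes.append(msg)
        warnings.warn(msg, stacklevel=3)
    return np.linalg.solve(vt, np.eye(vt.shape[0]))


def compute_tensor_gsvd(
    tpair: MatchedTensorPair, rank_tol: float = 1e-10
) -> TensorGSVDResult:
    """Tensor GSVD of a matched tensor pair via its three unfolding GSVDs."""
    t1, t2 = tpair.tumor, tpair.normal
    k1, l, m = t1.shape
    k2 = t2.shape[0]

    def _gsvd(mode: str) -> GSVDResult:
        a1, a2 = unfold(t1, mode), unfold(t2, mode)
        try:
            return gsvd_matrices(a1, a2, rank_tol=rank_tol)
        except RankError as exc:
            raise RankError(f"{mode}-mode unfolding: {exc}") from exc

    row = _gsvd("row")
    x = _gsvd("x")
    y = _gsvd("y")

    notes: list[str] = []
    vxt_inv = _inv_transpose(x.Vt, "x-mode", notes)  # = Vx^{-T}
    vyt_inv = _inv_transpose(y.Vt, "y-mode", notes)  # = Vy^{-T}
    w = np.kron(vyt_inv, vxt_inv)

    def _core(sigma: np.ndarray) -> np.ndarray:
        rmat = (sigma[:, None] * row.Vt) @ w  # LM x LM
        return rmat.reshape(l * m, m, l).transpose(0, 2, 1)  # -> LM x L x M

    r1 = _core(row.sigma1)
    r2 = _core(row.sigma2)

    theta = np.full(r1.shape, np.nan)
    defined = np.abs(r2) > 1e-12 * np.max(np.abs(r2))
    theta[defined] = np.arctan(np.abs(r1[defined] / r2[defined])) - _QUARTER_PI

    return TensorGSVDResult(
        U1=row.U1,
        U2=row.U2,
        Vx=x.V,
        Vy=y.V,
        R1=r1,
        R2=r2,
        Theta=theta,
        row_mode=row,
        x_mode=x,
        y_mode=y,
        shape1=(k1, l, m),
        shape2=(k2, l, m),
        warnings=notes,
    )


def reconstruct_tensor(result: TensorGSVDResult, dataset_index: int) -> np.ndarray:
    """Multiply the factors back: R_i x_a U_i x_b V_x x_c V_y."""
    if dataset_index not in (1, 2):
        raise ValueError("dataset_index must be 1 or 2")
    u = result.U1 if dataset_index == 1 else result.U2
    r = result.R1 if dataset_index == 1 else result.R2
    shape = result.shape1 if dataset_index == 1 else result.shape2
    k, l, m = shape
    r_unf = unfold(r, "row")  # LM x LM, columns (b, c) at c*L + b
    d_unf = u @ r_unf @ np.kron(result.Vy, result.Vx).T
    return refold(d_unf, "row", (k, l, m))
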