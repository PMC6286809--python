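"""Exact algebra linking Jacobian, covariance, and fluctuation matrices.

The stationary covariance C of a linear Langevin system dX = JX dt + √(2D) dW
with Hurwitz-stable J satisfies the Lyapunov equation

    J C + C Jᵀ = -2 D.                                          (forward)

For inference the equation is vectorized: with the column-major (Fortran)
``vec`` convention used package-wide,

    vec(J C + C Jᵀ) = [ (C ⊗ I) + (I ⊗ C) K_n ] vec(J) =: A j,

so the Lyapunov equation becomes the linear system  A j + 2 d = 0  with
d = vec(D). A candidate sparsity pattern (a bitstring over the n² Jacobian
entries) reduces the system to the supported columns of A, which is then fit
by least squares; the residual ‖A_r j_r + 2d‖₂ enters the GA fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.linalg

__all__ = [
    "forward_solve_covariance",
    "vectorize_lyapunov",
    "reduce_system",
    "solve_reduced",
    "VectorizedSystem",
    "ReducedSystem",
    "vec",
    "unvec",
    "check_symmetric",
]

#: relative tolerance for accepting an input covariance as symmetric
SYMMETRY_RTOL = 1e-8
#: relative rank tolerance of the least-squares solver
LSTSQ_RCOND = 1e-10
#: residuals are clamped below at this value before taking log10
RESIDUAL_FLOOR = 1e-300


@dataclass
class VectorizedSystem:
    """The linear system ``A j + 2 d = 0`` equivalent to the Lyapunov equation.

    Attributes
    ----------
    A : (n², n²) ndarray
        Coefficient matrix built from the covariance.
    d : (n²,) ndarray
        Column-major vectorization of the diagonal fluctuation matrix D.
    n : int
        Number of metabolites.
    """

    A: np.ndarray
    d: np.ndarray
    n: int

    # Because C is symmetric, equations (i,k) and (k,i) are identical: only
    # n(n+1)/2 rows are distinct. The √2-weighted deduplicated system has
    # exactly the same least-squares minimizer and residual norm and costs
    # roughly half as much per solve — it is what the fitness evaluation
    # uses internally.
    def _compressed(self) -> tuple[np.ndarray, np.ndarray]:
        if not hasattr(self, "_compressed_cache"):
            n = self.n
            rows, weights = [], []
            for k in range(n):
                for i in range(k + 1):
                    rows.append(i + k * n)
                    weights.append(1.0 if i == k else math.sqrt(2.0))
            w = np.asarray(weights)
            A_c = self.A[rows] * w[:, None]
            b_c = -2.0 * self.d[rows] * w
            self._compressed_cache = (A_c, b_c)
        return self._compressed_cache

    def solve_support(self, support: np.ndarray) -> tuple[np.ndarray, float]:
        """Least-squares fit restricted to the given support positions.

        Equivalent to ``solve_reduced(reduce_system(self, structure))`` (same
        minimizer, same residual norm) but computed on the deduplicated
        equation set for speed.
        """
        A_c, b_c = self._compressed()
        return _lstsq_gelsy(A_c[:, support], b_c)


class ReducedSystem(NamedTuple):
    """Columns of A retained by a sparsity pattern, plus the full d."""

    A_r: np.ndarray
    support: np.ndarray  # sorted positions of the 1-bits
    d: np.ndarray


def vec(M: np.ndarray) -> np.ndarray:
    """Column-major (Fortran) vectorization; the package-wide convention."""
    return np.asarray(M).reshape(-1, order="F")


def unvec(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vec`."""
    return np.asarray(v).reshape((n, n), order="F")


def _as_fluctuation_diag(D, n: int | None = None) -> np.ndarray:
    """Accept a vector of diagonal intensities or a diagonal matrix."""
    D = np.asarray(D, dtype=float)
    if D.ndim == 2:
        off = D - np.diag(np.diag(D))
        if np.any(off != 0):
            raise ValueError("fluctuation matrix must be diagonal")
        D = np.diag(D)
    if D.ndim != 1:
        raise ValueError("fluctuation must be a vector or a diagonal matrix")
    if n is not None and D.shape[0] != n:
        raise ValueError(f"fluctuation has length {D.shape[0]}, expected {n}")
    if np.any(D < 0):
        raise ValueError("fluctuation intensities must be nonnegative")
    return D


def check_symmetric(C: np.ndarray, rtol: float = SYMMETRY_RTOL) -> np.ndarray:
    """Validate symmetry of a covariance matrix and symmetrize by averaging.

    Raises ``ValueError`` when max|C - Cᵀ| exceeds ``rtol`` · max|C|.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"covariance must be square, got shape {C.shape}")
    scale = np.abs(C).max()
    asym = np.abs(C - C.T).max()
    if scale > 0 and asym > rtol * scale:
        raise ValueError(
            f"covariance is not symmetric: max|C - C^T| = {asym:.3e} "
            f"exceeds {rtol:g} * max|C| = {rtol * scale:.3e}"
        )
    return 0.5 * (C + C.T)


def forward_solve_covariance(J: np.ndarray, D) -> np.ndarray:
    """Solve the Lyapunov equation J C + C Jᵀ = -2D for the covariance C.

    Parameters
    ----------
    J : (n, n) ndarray
        Jacobian of the system at steady state; must be Hurwitz-stable
        (all eigenvalue real parts negative), otherwise no stationary
        covariance exists.
    D : (n,) vector or (n, n) diagonal matrix
        Nonnegative fluctuation intensities.

    Returns
    -------
    C : (n, n) ndarray, symmetric.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"Jacobian must be square, got shape {J.shape}")
    n = J.shape[0]
    Ddiag = _as_fluctuation_diag(D, n)
    eigs = np.linalg.eigvals(J)
    worst = eigs[np.argmax(eigs.real)]
    if worst.real >= 0:
        raise ValueError(
            f"Jacobian is not Hurwitz-stable: eigenvalue {worst:.6g} has "
            "nonnegative real part; no stationary covariance exists"
        )
    C = scipy.linalg.solve_continuous_lyapunov(J, -2.0 * np.diag(Ddiag))
    return 0.5 * (C + C.T)


def vectorize_lyapunov(C: np.ndarray, D) -> VectorizedSystem:
    """Rewrite the Lyapunov equation as the linear system A j + 2 d = 0.

    With the column-major convention, vec(J C) = (Cᵀ ⊗ I) vec(J) and
    vec(C Jᵀ) = (I ⊗ C) K_n vec(J) where K_n is the commutation matrix;
    symmetry of C gives  A = (C ⊗ I) + (I ⊗ C) K_n.
    """
    C = check_symmetric(C)
    n = C.shape[0]
    if n < 1:
        raise ValueError("need at least one metabolite")
    Ddiag = _as_fluctuation_diag(D, n)
    I = np.eye(n)
    # commutation matrix: K vec(J) = vec(J^T)
    K = np.zeros((n * n, n * n))
    idx = np.arange(n * n).reshape((n, n), order="F")
    K[idx.T.reshape(-1, order="F"), np.arange(n * n)] = 1.0
    A = np.kron(C, I) + np.kron(I, C) @ K
    d = vec(np.diag(Ddiag))
    return VectorizedSystem(A=A, d=d, n=n)


def reduce_system(sys: VectorizedSystem, structure: np.ndarray) -> ReducedSystem:
    """Keep only the columns of A supported by a sparsity bitstring.

    ``structure`` marks the Jacobian entries allowed to be nonzero; zero
    entries of j and their columns of A drop out of A j + 2 d = 0.
    """
    structure = np.asarray(structure).astype(bool).ravel()
    if structure.shape[0] != sys.A.shape[1]:
        raise ValueError(
            f"structure length {structure.shape[0]} does not match "
            f"system size {sys.A.shape[1]}"
        )
    support = np.flatnonzero(structure)
    if support.size == 0:
        raise ValueError("all-zero structure: no Jacobian entries to fit")
    return ReducedSystem(A_r=sys.A[:, support], support=support, d=sys.d)


_GELSY, _GELSY_LWORK = scipy.linalg.get_lapack_funcs(
    ("gelsy", "gelsy_lwork"), (np.empty(0, np.float64),)
)


def solve_reduced(red: ReducedSystem) -> tuple[np.ndarray, float]:
    """Least-squares fit of the reduced system; returns (j_r, residual).

    Minimizes ‖A_r j_r + 2 d‖₂ with a QR-based (complete orthogonal) solver
    (LAPACK gelsy, called directly — this sits in the GA's innermost loop);
    rank-deficient systems return the minimum-norm solution. The residual is
    the Euclidean norm at the minimizer.
    """
    return _lstsq_gelsy(red.A_r, -2.0 * red.d)


_LWORK_CACHE: dict[tuple[int, int], int] = {}


def _lstsq_gelsy(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    m, r = A.shape
    lwork = _LWORK_CACHE.get((m, r))
    if lwork is None:
        work, info = _GELSY_LWORK(m, r, 1, LSTSQ_RCOND)
        lwork = _LWORK_CACHE[(m, r)] = int(np.real(work))
    if r > m:  # underdetermined: LAPACK wants the rhs padded to length r
        b_in = np.zeros(r)
        b_in[:m] = b
    else:
        b_in = b
    v, x, _, rank, info = _GELSY(
        A, b_in[:, None], np.zeros(r, np.int32), LSTSQ_RCOND, lwork, False, False
    )
    if info != 0:  # pragma: no cover - LAPACK failure is exceptional
        raise np.linalg.LinAlgError(f"gelsy failed with info={info}")
    j_r = x[:r, 0]
    residual = float(np.linalg.norm(A @ j_r - b))
    return j_r, residual


def embed_solution(j_r: np.ndarray, support: np.ndarray, n: int) -> np.ndarray:
    """Scatter fitted values back into a full n×n Jacobian (zeros elsewhere)."""
    j = np.zeros(n * n)
    j[support] = j_r
    return unvec(j, n)
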