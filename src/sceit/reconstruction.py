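"""Time-difference inverse problem: damped least squares and spectral constraints.

Two reconstruction routes are provided.

* ``dls_reconstruct`` — the single-frequency damped-least-squares baseline:
  one (or two) Gauss-Newton steps of the Tikhonov-regularized linearized
  problem with regularization matrix ``R = diag(J^T J)``.

* ``sc_reconstruct`` — the spectrally constrained multi-frequency route: the
  per-frequency linearized systems ``J(w_i) A(w_i) dF = dv(w_i)`` are stacked
  vertically into one system for the frequency-independent fraction change
  ``dF``; the unit-sum constraint is folded in by eliminating the reference
  tissue, the Tikhonov solution is clamped element-wise to the feasible
  fraction set, and (optionally) the background is re-linearized for a second
  step.

Both routes select the regularization weight by the maximum-curvature corner
of the L-curve over a fixed logarithmic grid, and both report the numerical
rank and effective condition number (via SVD) of the matrix being inverted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import scipy.linalg

from .fraction_model import (
    FractionField,
    TissueSpectra,
    clamp_fractions,
    coefficient_matrix,
    fractions_to_conductivity,
)
from .mesh_fem import (
    ConductivityField,
    Mesh2D,
    Protocol,
    VoltageFrame,
    compute_jacobian,
    solve_forward,
)

__all__ = [
    "StackedSystem",
    "ReconstructionResult",
    "MatrixDiagnostics",
    "SolvabilityError",
    "assemble_stacked",
    "select_lambda_lcurve",
    "tikhonov_solve",
    "dls_reconstruct",
    "sc_reconstruct",
    "matrix_diagnostics",
    "default_lambda_grid",
]


class SolvabilityError(ValueError):
    """Stacked system has fewer equations than unknowns (M*K < (T-1)*N)."""


class MatrixDiagnostics(NamedTuple):
    rank: int
    condition_number: float


@dataclass
class StackedSystem:
    """Vertically stacked multi-frequency system.

    ``blocks[i] = J(w_i) @ A(w_i)`` has shape (K, T*N); ``S`` stacks them to
    (M*K, T*N) and ``S_reduced`` folds the reference-tissue columns via the
    substitution ``f_n1 = 1 - sum_{j>=2} f_nj``, leaving (M*K, (T-1)*N).
    ``reg_diag`` is the diagonal of ``S_reduced^T S_reduced`` (the standard
    Tikhonov weight).
    """

    blocks: list
    S: np.ndarray
    S_reduced: np.ndarray
    reg_diag: np.ndarray
    n_tissues: int
    n_elements: int
    lam: Optional[float] = None


@dataclass
class ReconstructionResult:
    """Output of one reconstruction run.

    ``delta_sigma`` has one row per frequency for the spectral-constraints
    route (the fraction change mapped through the coefficient matrices) and a
    single row for DLS.  Histories hold the cumulative image after each
    Gauss-Newton step.
    """

    algorithm: str
    delta_sigma: np.ndarray
    delta_fractions: Optional[np.ndarray]
    lambdas: list
    iterations_run: int
    diagnostics: list
    delta_sigma_history: list = field(default_factory=list)
    delta_fraction_history: list = field(default_factory=list)


def default_lambda_grid(n: int = 30) -> np.ndarray:
    """Log-spaced candidate regularization weights.

    The weights are dimensionless because the regularization matrix
    ``R = diag(normal matrix)`` already carries the scale of the problem.
    """
    return np.logspace(-8.0, 0.0, n)


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

def assemble_stacked(
    jacobians: Sequence[np.ndarray],
    coeff_matrices: Sequence,
) -> StackedSystem:
    """Stack per-frequency products ``J(w_i) A(w_i)`` into one system."""
    if len(jacobians) != len(coeff_matrices):
        raise ValueError("need one coefficient matrix per Jacobian")
    if not jacobians:
        raise ValueError("at least one frequency is required")
    blocks = []
    n_elements = jacobians[0].shape[1]
    n_tissues = None
    for J, A in zip(jacobians, coeff_matrices):
        K, N = J.shape
        if N != n_elements:
            raise ValueError("Jacobians disagree on element count")
        TN = A.shape[1]
        if A.shape[0] != N or TN % N:
            raise ValueError("coefficient matrix shape incompatible with J")
        T = TN // N
        if n_tissues is None:
            n_tissues = T
        elif T != n_tissues:
            raise ValueError("coefficient matrices disagree on tissue count")
        blocks.append(np.asarray(J @ A.toarray() if hasattr(A, "toarray") else J @ A))
    S = np.vstack(blocks)
    S3 = S.reshape(S.shape[0], n_elements, n_tissues)
    S_reduced = (S3[:, :, 1:] - S3[:, :, :1]).reshape(
        S.shape[0], n_elements * (n_tissues - 1)
    )
    return StackedSystem(
        blocks=blocks,
        S=S,
        S_reduced=S_reduced,
        reg_diag=np.einsum("ij,ij->j", S_reduced, S_reduced),
        n_tissues=n_tissues,
        n_elements=n_elements,
    )


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

def _scaled_svd(matrix: np.ndarray, reg_diag: np.ndarray):
    """SVD of the column-scaled matrix so lambda*R becomes lambda*I."""
    d = np.sqrt(np.maximum(reg_diag, 1e-300))
    U, s, Vt = scipy.linalg.svd(matrix / d, full_matrices=False)
    return U, s, Vt, d


def select_lambda_lcurve(
    matrix: np.ndarray,
    rhs: np.ndarray,
    grid: Optional[np.ndarray] = None,
    reg_diag: Optional[np.ndarray] = None,
) -> float:
    """Maximum-curvature corner of the L-curve over a fixed lambda grid.

    The curve is (log residual norm, log solution seminorm ``||R^1/2 x||``)
    parameterized by lambda; curvature is evaluated by finite differences in
    log-lambda and the interior grid point of maximum curvature is returned.
    Deterministic for fixed inputs.
    """
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if not np.any(rhs):
        warnings.warn("all-zero data vector; returning mid-grid lambda")
        return float(grid[len(grid) // 2])
    if grid.size < 3:  # curvature needs interior points; be conservative
        return float(grid[-1])
    if reg_diag is None:
        reg_diag = np.einsum("ij,ij->j", matrix, matrix)
    U, s, _, _ = _scaled_svd(matrix, reg_diag)
    beta = U.T @ rhs
    # residual component orthogonal to the column space
    res_perp2 = max(float(rhs @ rhs - beta @ beta), 0.0)
    rho = np.empty(grid.size)
    eta = np.empty(grid.size)
    for i, lam in enumerate(grid):
        f = s ** 2 / (s ** 2 + lam)
        rho[i] = np.sqrt(res_perp2 + float(((1 - f) ** 2 * beta ** 2).sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(s > 0, f * beta / s, 0.0)
        eta[i] = np.sqrt(float((y ** 2).sum()))
    floor = 1e-15 * float(np.linalg.norm(rhs))
    lr = np.log(np.maximum(rho, floor))
    le = np.log(np.maximum(eta, floor))
    t = np.log(grid)
    dr, de = np.gradient(lr, t), np.gradient(le, t)
    d2r, d2e = np.gradient(dr, t), np.gradient(de, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dr * d2e - d2r * de) / (dr ** 2 + de ** 2) ** 1.5
    kappa[~np.isfinite(kappa)] = -np.inf
    interior = kappa[1:-1]
    return float(grid[1 + int(np.argmax(interior))])


def tikhonov_solve(
    system,
    rhs: np.ndarray,
    lam: Optional[float] = None,
    reg_diag: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Standard-Tikhonov normal-equation solve.

    ``x = (M^T M + lam * diag(M^T M))^-1 M^T rhs`` where ``M`` is either the
    reduced stacked matrix of a :class:`StackedSystem` or a plain array.
    """
    if isinstance(system, StackedSystem):
        matrix = system.S_reduced
        reg_diag = system.reg_diag if reg_diag is None else reg_diag
        lam = system.lam if lam is None else lam
    else:
        matrix = np.asarray(system)
        if reg_diag is None:
            reg_diag = np.einsum("ij,ij->j", matrix, matrix)
    if lam is None or lam <= 0:
        raise ValueError("a positive regularization weight is required")
    G = matrix.T @ matrix
    G[np.diag_indices_from(G)] += lam * np.maximum(reg_diag, 1e-300)
    return scipy.linalg.solve(G, matrix.T @ rhs, assume_a="pos")


def matrix_diagnostics(matrix: np.ndarray, tol: Optional[float] = None) -> MatrixDiagnostics:
    """Numerical rank and effective condition number via SVD.

    Rank counts singular values above ``max(shape) * eps * s_max`` (or an
    explicit tolerance); the condition number is the ratio of the largest to
    the smallest above-tolerance singular value, so rank-deficient matrices
    get a finite "effective" value.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("matrix must be nonempty")
    s = scipy.linalg.svdvals(matrix)
    if s[0] == 0.0:
        warnings.warn("all-zero matrix: rank 0, condition number undefined")
        return MatrixDiagnostics(0, float("nan"))
    if tol is None:
        tol = max(matrix.shape) * np.finfo(float).eps * s[0]
    above = s[s > tol]
    return MatrixDiagnostics(int(above.size), float(above[0] / above[-1]))


# ---------------------------------------------------------------------------
# reconstruction drivers
# ---------------------------------------------------------------------------

def _restrict_grid(lambda_grid, previous_lambdas) -> np.ndarray:
    """Candidate weights for the next Gauss-Newton step.

    Later steps fit residuals that may sit at the noise floor, where the
    L-curve has no corner and an unconstrained search can collapse the
    damping and fit pure noise.  Restricting the search to weights at least
    as large as the previous step's selection is a trust-region-style
    safeguard: damping never decreases across iterations.
    """
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(
        lambda_grid, dtype=float
    )
    if not previous_lambdas:
        return grid
    lo = max(previous_lambdas)
    hi = float(grid.max())
    if lo >= hi:
        return np.array([lo])
    return np.logspace(np.log10(lo), np.log10(hi), grid.size)


def _as_array(frames, n_frequencies: int) -> np.ndarray:
    if isinstance(frames, np.ndarray):
        out = np.atleast_2d(frames)
    else:
        seq = list(frames)
        if seq and isinstance(seq[0], VoltageFrame):
            out = np.vstack([f.values for f in seq])
        else:
            out = np.atleast_2d(np.asarray(seq, dtype=float))
    if out.shape[0] != n_frequencies:
        raise ValueError("expected one frame per frequency")
    return out


def dls_reconstruct(
    delta_v: np.ndarray,
    mesh: Mesh2D,
    protocol: Protocol,
    sigma_background: float,
    lam: Optional[float] = None,
    num_steps: int = 1,
    lambda_grid: Optional[np.ndarray] = None,
    residual_update: str = "linear",
) -> ReconstructionResult:
    """Damped-least-squares time-difference reconstruction (one frequency).

    Step one solves ``(J^T J + lam diag(J^T J))^-1 J^T dv`` at the
    homogeneous background.  Further steps update the background
    conductivity, re-linearize the Jacobian there, and solve for the
    remaining residual.  With ``residual_update="linear"`` (the default,
    matching the limited-step *linear* iteration scheme) the residual is the
    measured difference minus the linear prediction of the accepted
    increments; with ``"simulated"`` the forward problem is re-solved on the
    reconstruction mesh and the residual referenced to the simulated
    baseline.
    """
    if residual_update not in ("linear", "simulated"):
        raise ValueError("residual_update must be 'linear' or 'simulated'")
    delta_v = np.asarray(delta_v, dtype=float).ravel()
    if delta_v.size != protocol.n_measurements:
        raise ValueError("delta_v length must equal the measurement count")
    sigma0 = np.full(mesh.n_elements, float(sigma_background))
    floor = 1e-3 * float(sigma_background)
    v_sim0 = None
    if residual_update == "simulated":
        v_sim0 = solve_forward(
            mesh, ConductivityField(sigma0), protocol
        ).values

    sigma_prev = sigma0
    rhs = delta_v.copy()
    lambdas, diagnostics, history = [], [], []
    for k in range(num_steps):
        J = compute_jacobian(mesh, ConductivityField(sigma_prev), protocol)
        if k > 0 and residual_update == "simulated":
            v_sim = solve_forward(
                mesh, ConductivityField(sigma_prev), protocol
            ).values
            rhs = delta_v - (v_sim - v_sim0)
        reg = np.einsum("ij,ij->j", J, J)
        if lam is not None:
            lam_k = lam
        else:
            grid_k = _restrict_grid(lambda_grid, lambdas)
            lam_k = select_lambda_lcurve(J, rhs, grid=grid_k, reg_diag=reg)
        step = tikhonov_solve(J, rhs, lam=lam_k, reg_diag=reg)
        sigma_new = sigma_prev + step
        if np.any(sigma_new <= 0):
            warnings.warn("nonpositive conductivity after update; flooring")
            sigma_new = np.maximum(sigma_new, floor)
        if residual_update == "linear":
            rhs = rhs - J @ (sigma_new - sigma_prev)
        diagnostics.append(matrix_diagnostics(J))
        lambdas.append(lam_k)
        history.append(sigma_new - sigma0)
        sigma_prev = sigma_new

    return ReconstructionResult(
        algorithm="dls",
        delta_sigma=history[-1],
        delta_fractions=None,
        lambdas=lambdas,
        iterations_run=num_steps,
        diagnostics=diagnostics,
        delta_sigma_history=history,
    )


def sc_reconstruct(
    v_background,
    v_foreground,
    spectra: TissueSpectra,
    mesh: Mesh2D,
    protocol: Protocol,
    num_steps: int = 2,
    lam: Optional[float] = None,
    lambda_grid: Optional[np.ndarray] = None,
    residual_update: str = "linear",
) -> ReconstructionResult:
    """Spectrally constrained multi-frequency time-difference reconstruction.

    Implements the limited-step loop: starting from the pure-background
    fraction field, each step (i) linearizes every frequency's forward map at
    the current fractions, (ii) stacks ``J(w_i) A(w_i)`` over frequencies,
    (iii) solves the reduced Tikhonov problem for the non-reference fraction
    change, (iv) clamps the updated fractions to [0, 1] with unit element
    sums, and (v) updates the data residual.  The default *linear* update
    subtracts the stacked-system prediction of the accepted (clamped)
    fraction increment from the running residual; ``"simulated"`` re-solves
    the forward problem at the current fractions and references the residual
    to the simulated baseline.  The final fraction change is mapped to a
    conductivity-change image per frequency through the coefficient
    matrices.
    """
    if residual_update not in ("linear", "simulated"):
        raise ValueError("residual_update must be 'linear' or 'simulated'")
    M = spectra.n_frequencies
    T = spectra.n_tissues
    N = mesh.n_elements
    K = protocol.n_measurements
    if M * K < (T - 1) * N:
        raise SolvabilityError(
            f"M*K = {M * K} < (T-1)*N = {(T - 1) * N}: "
            "stacked system is underdetermined; add frequencies or coarsen "
            "the reconstruction mesh"
        )
    v_bg = _as_array(v_background, M)
    v_fg = _as_array(v_foreground, M)
    dv_meas = v_fg - v_bg

    coeffs = [coefficient_matrix(spectra, i, N) for i in range(M)]
    F0 = FractionField.homogeneous(T, N)
    F_prev = F0
    rhs_parts = [dv_meas[i].copy() for i in range(M)]
    v_sim0 = None
    lambdas, diagnostics = [], []
    dsig_history, dfrac_history = [], []
    for k in range(num_steps):
        sigmas = [
            fractions_to_conductivity(F_prev, spectra, i) for i in range(M)
        ]
        if residual_update == "simulated":
            if k == 0:
                v_sim0 = [
                    solve_forward(mesh, sigmas[i], protocol).values
                    for i in range(M)
                ]
            else:
                rhs_parts = [
                    dv_meas[i]
                    - (
                        solve_forward(mesh, sigmas[i], protocol).values
                        - v_sim0[i]
                    )
                    for i in range(M)
                ]
        rhs = np.concatenate(rhs_parts)
        jacobians = [
            compute_jacobian(mesh, sigmas[i], protocol) for i in range(M)
        ]
        system = assemble_stacked(jacobians, coeffs)
        if lam is not None:
            lam_k = lam
        else:
            grid_k = _restrict_grid(lambda_grid, lambdas)
            lam_k = select_lambda_lcurve(
                system.S_reduced, rhs, grid=grid_k,
                reg_diag=system.reg_diag,
            )
        dfr = tikhonov_solve(system, rhs, lam=lam_k)
        # element-major vector -> (T-1, N)
        dfr = dfr.reshape(N, T - 1).T
        F_tilde = F_prev.matrix.copy()
        F_tilde[1:] += dfr
        F_new = clamp_fractions(F_tilde)
        if residual_update == "linear":
            inc = (F_new.matrix - F_prev.matrix).ravel(order="F")
            rhs_parts = [
                rhs_parts[i] - system.blocks[i] @ inc for i in range(M)
            ]
        lambdas.append(lam_k)
        diagnostics.append(matrix_diagnostics(system.S_reduced))
        dF = F_new.matrix - F0.matrix
        dfrac_history.append(dF)
        dsig_history.append(
            np.vstack([spectra.at_frequency(i) @ dF for i in range(M)])
        )
        F_prev = F_new

    return ReconstructionResult(
        algorithm="sc",
        delta_sigma=dsig_history[-1],
        delta_fractions=dfrac_history[-1],
        lambdas=lambdas,
        iterations_run=num_steps,
        diagnostics=diagnostics,
        delta_sigma_history=dsig_history,
        delta_fraction_history=dfrac_history,
    )
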