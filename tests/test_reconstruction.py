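"""Stacked-system assembly, regularization, and the two reconstruction routes."""

import numpy as np
import pytest

from sceit import (
    ConductivityField,
    FractionField,
    SolvabilityError,
    TissueSpectra,
    assemble_stacked,
    brain_spectra,
    coefficient_matrix,
    compute_jacobian,
    compute_metrics,
    default_lambda_grid,
    dls_reconstruct,
    make_two_tissue_scene,
    matrix_diagnostics,
    sc_reconstruct,
    select_lambda_lcurve,
    simulate_clean_frames,
    simulate_noisy_frames,
    tikhonov_solve,
)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_assemble_single_frequency_degenerates(spectra, rng):
    J = rng.normal(size=(10, 4))
    A = coefficient_matrix(spectra, 0, 4)
    system = assemble_stacked([J], [A])
    assert system.S.shape == (10, 8)
    assert system.S_reduced.shape == (10, 4)


def test_assemble_reduced_columns_are_contrast_columns(spectra, rng):
    """For T=2 the reduced column is (tissue-2 column) - (tissue-1 column)."""
    J = rng.normal(size=(6, 3))
    A = coefficient_matrix(spectra, 1, 3)
    system = assemble_stacked([J, J], [A, A])
    for n in range(3):
        expected = system.S[:, 2 * n + 1] - system.S[:, 2 * n]
        assert np.allclose(system.S_reduced[:, n], expected)
    # symbolic check: substituting f1 = 1 - f2 into S F must reproduce
    # S_reduced f2 up to the constant S @ (pure tissue-1) term
    f2 = rng.random(3)
    full = np.empty(6)
    full[0::2] = 1 - f2
    full[1::2] = f2
    base = np.zeros(6)
    base[0::2] = 1.0
    assert np.allclose(
        system.S @ full - system.S @ base, system.S_reduced @ f2
    )


def test_assemble_repeated_blocks_keep_rank(spectra, rng):
    J = rng.normal(size=(8, 5))
    A = coefficient_matrix(spectra, 0, 5)
    one = assemble_stacked([J], [A])
    two = assemble_stacked([J, J], [A, A])
    assert np.linalg.matrix_rank(two.S) == np.linalg.matrix_rank(one.S)


def test_assemble_shape_mismatch(spectra, rng):
    with pytest.raises(ValueError):
        assemble_stacked([rng.normal(size=(4, 3))], [coefficient_matrix(spectra, 0, 5)])


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

def _ill_posed_problem(n=32, noise=0.01, seed=3):
    """Discretized 1-D image-restoration integral operator (severely
    ill-posed; singular values decay exponentially), 1% additive noise."""
    h = np.pi / n
    s = -np.pi / 2 + (np.arange(n) + 0.5) * h
    u = np.pi * (np.sin(s[:, None]) + np.sin(s[None, :]))
    with np.errstate(divide="ignore", invalid="ignore"):
        sinc = np.where(u == 0, 1.0, np.sin(u) / u)
    A = h * ((np.cos(s[:, None]) + np.cos(s[None, :])) ** 2) * sinc ** 2
    x_true = 2 * np.exp(-6 * (s - 0.8) ** 2) + np.exp(-2 * (s + 0.5) ** 2)
    b = A @ x_true
    rng = np.random.default_rng(seed)
    b_noisy = b + noise * np.linalg.norm(b) / np.sqrt(n) * rng.normal(size=n)
    return A, b_noisy, x_true


def test_lcurve_monotonicity_and_determinism(rng):
    A, b, _ = _ill_posed_problem()
    grid = default_lambda_grid()
    reg = np.einsum("ij,ij->j", A, A)
    res_norms, sol_norms = [], []
    for lam in grid:
        x = tikhonov_solve(A, b, lam=lam, reg_diag=reg)
        res_norms.append(np.linalg.norm(A @ x - b))
        sol_norms.append(np.linalg.norm(np.sqrt(reg) * x))
    assert np.all(np.diff(res_norms) >= -1e-12)
    assert np.all(np.diff(sol_norms) <= 1e-12)
    assert select_lambda_lcurve(A, b) == select_lambda_lcurve(A, b)


def test_lcurve_near_error_optimal_on_classic_problem():
    """Corner within a factor 10 of the error-minimizing weight."""
    A, b, x_true = _ill_posed_problem()
    grid = default_lambda_grid()
    reg = np.einsum("ij,ij->j", A, A)
    errors = [
        np.linalg.norm(tikhonov_solve(A, b, lam=lam, reg_diag=reg) - x_true)
        for lam in grid
    ]
    lam_opt = grid[int(np.argmin(errors))]
    lam_sel = select_lambda_lcurve(A, b)
    assert grid[0] < lam_sel < grid[-1]  # strictly inside the grid
    assert 0.1 <= lam_sel / lam_opt <= 10.0


def test_lcurve_zero_rhs_warns_and_returns_mid_grid():
    A, _, _ = _ill_posed_problem()
    with pytest.warns(UserWarning):
        lam = select_lambda_lcurve(A, np.zeros(A.shape[0]))
    grid = default_lambda_grid()
    assert lam == grid[len(grid) // 2]


def test_tikhonov_identity_closed_form():
    x = tikhonov_solve(np.eye(2), np.array([1.0, 0.0]), lam=1.0, reg_diag=np.ones(2))
    assert np.allclose(x, [0.5, 0.0])


def test_tikhonov_large_lambda_shrinks(rng):
    A = rng.normal(size=(12, 6))
    b = rng.normal(size=12)
    x = tikhonov_solve(A, b, lam=1e12)
    assert np.linalg.norm(x) < 1e-6


def test_tikhonov_small_lambda_recovers_full_rank_solution(rng):
    """Noiseless full-column-rank system: recovery to 1e-6 relative error."""
    A = rng.normal(size=(20, 8))
    x0 = rng.normal(size=8)
    b = A @ x0
    x = tikhonov_solve(A, b, lam=1e-12)
    assert np.linalg.norm(x - x0) <= 1e-6 * np.linalg.norm(x0)
    # cross-check against the direct least-squares oracle
    x_ls, *_ = np.linalg.lstsq(A, b, rcond=None)
    assert np.allclose(x, x_ls, atol=1e-6)


def test_tikhonov_requires_positive_lambda(rng):
    with pytest.raises(ValueError):
        tikhonov_solve(rng.normal(size=(4, 2)), np.ones(4), lam=0.0)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_diagnostics_identity():
    assert matrix_diagnostics(np.eye(5)) == (5, pytest.approx(1.0))


def test_diagnostics_duplicated_rows_keep_rank(rng):
    J = rng.normal(size=(6, 4))
    assert matrix_diagnostics(np.vstack([J, J])).rank == matrix_diagnostics(J).rank


def test_diagnostics_known_rank_factors(rng):
    M = rng.normal(size=(10, 4)) @ rng.normal(size=(4, 6))
    assert matrix_diagnostics(M).rank == 4
    assert np.linalg.matrix_rank(M) == 4  # independent oracle


def test_diagnostics_zero_matrix_signaled():
    with pytest.warns(UserWarning):
        d = matrix_diagnostics(np.zeros((3, 3)))
    assert d.rank == 0 and np.isnan(d.condition_number)


# ---------------------------------------------------------------------------
# reconstruction drivers
# ---------------------------------------------------------------------------

def test_dls_zero_data_gives_zero_image(inverse_mesh, protocol):
    res = dls_reconstruct(
        np.zeros(192), inverse_mesh, protocol, sigma_background=0.155, lam=0.01
    )
    assert np.allclose(res.delta_sigma, 0.0)


def test_dls_localizes_single_target(inverse_mesh, protocol, spectra):
    """At 80 dB the reconstructed perturbation overlaps the truth (PE < 0.1)."""
    scene = make_two_tissue_scene(2, snr_db=80.0)
    cb, cf = simulate_clean_frames(scene, protocol)
    v_bg, v_fg = simulate_noisy_frames(cb, cf, 80.0, (0, 2, 800, 0))
    res = dls_reconstruct(
        v_fg[1] - v_bg[1],
        inverse_mesh,
        protocol,
        sigma_background=float(spectra.values[0, 1]),
        lam=0.0173,
    )
    m = compute_metrics(res.delta_sigma, inverse_mesh, scene.target)
    assert m.pe < 0.1


def test_sc_no_change_gives_zero_image(inverse_mesh, protocol, spectra):
    frames = np.tile(np.linspace(1, 2, 192), (3, 1)) * 1e-4
    res = sc_reconstruct(
        frames, frames, spectra, inverse_mesh, protocol, num_steps=2, lam=0.01
    )
    assert np.allclose(res.delta_fractions, 0.0)
    assert np.allclose(res.delta_sigma, 0.0)


def test_sc_fractions_feasible_every_iteration(inverse_mesh, protocol, spectra):
    scene = make_two_tissue_scene(1, snr_db=60.0)
    cb, cf = simulate_clean_frames(scene, protocol)
    v_bg, v_fg = simulate_noisy_frames(cb, cf, 60.0, (0, 1, 600, 0))
    res = sc_reconstruct(
        v_bg, v_fg, spectra, inverse_mesh, protocol, num_steps=2, lam=0.016
    )
    F0 = FractionField.homogeneous(2, inverse_mesh.n_elements).matrix
    for dF in res.delta_fraction_history:
        F = F0 + dF
        assert np.all(F >= -1e-12) and np.all(F <= 1 + 1e-12)
        assert np.allclose(F.sum(axis=0), 1.0)
    # final conductivity change equals the coefficient-matrix transform
    for i in range(3):
        A = coefficient_matrix(spectra, i, inverse_mesh.n_elements)
        assert np.allclose(
            res.delta_sigma[i], A @ res.delta_fractions.ravel(order="F")
        )


def test_sc_refuses_underdetermined_system(inverse_mesh, protocol):
    from sceit import brain_blood_spectra

    sp3 = brain_blood_spectra()  # (T-1)*N = 1024 > M*K = 576
    frames = np.zeros((3, 192))
    with pytest.raises(SolvabilityError):
        sc_reconstruct(frames, frames, sp3, inverse_mesh, protocol)


def test_sc_equals_dls_for_frequency_flat_spectra(inverse_mesh, protocol):
    """Identical spectra at all frequencies, noiseless data: the stacked
    solve collapses to the single-frequency damped solve (up to clamping of
    slightly negative ring values, which only zeroes elements)."""
    flat = TissueSpectra(
        ("bg", "tgt"),
        [1.0, 2.0, 3.0],
        np.array([[0.155, 0.155, 0.155], [0.120, 0.120, 0.120]]),
    )
    scene = make_two_tissue_scene(2, spectra=flat, snr_db=np.inf)
    cb, cf = simulate_clean_frames(scene, protocol)
    lam = 0.016
    sc = sc_reconstruct(
        cb, cf, flat, inverse_mesh, protocol, num_steps=1, lam=lam
    )
    dls = dls_reconstruct(
        cf[1] - cb[1],
        inverse_mesh,
        protocol,
        sigma_background=0.155,
        lam=lam,
        num_steps=1,
    )
    sc_img = sc.delta_sigma[1]
    dls_img = dls.delta_sigma
    scale = np.abs(dls_img).max()
    # where DLS's implied fraction change is feasible the images agree;
    # where it is negative, SC clamps to zero
    contrast = 0.120 - 0.155
    implied_f = dls_img / contrast
    feasible = implied_f >= 0
    assert np.allclose(sc_img[feasible], dls_img[feasible], atol=1e-8 * scale)
    assert np.allclose(sc_img[~feasible], 0.0)


def test_gn_lambda_never_decreases_with_lcurve(inverse_mesh, protocol, spectra):
    """Trust-region safeguard: later-step damping at least the first step's."""
    scene = make_two_tissue_scene(3, snr_db=60.0)
    cb, cf = simulate_clean_frames(scene, protocol)
    v_bg, v_fg = simulate_noisy_frames(cb, cf, 60.0, (0, 3, 600, 0))
    res = dls_reconstruct(
        v_fg[1] - v_bg[1],
        inverse_mesh,
        protocol,
        sigma_background=float(spectra.values[0, 1]),
        num_steps=2,
    )
    assert res.lambdas[1] >= res.lambdas[0]
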