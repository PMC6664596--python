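"""Mesh construction, FEM forward solve, Jacobian, and noise model."""

import numpy as np
import pytest

from sceit import (
    ConductivityField,
    VoltageFrame,
    add_gaussian_noise,
    build_circular_mesh,
    compute_jacobian,
    opposite_adjacent_protocol,
    solve_forward,
)
from sceit.mesh_fem import MeshConstructionError


@pytest.mark.parametrize(
    "target_elements, expect_elements, expect_nodes",
    [(800, 800, 441), (512, 512, 289)],
)
def test_mesh_matches_study_sizes(target_elements, expect_elements, expect_nodes):
    mesh = build_circular_mesh(300.0, 16, target_elements)
    assert mesh.n_elements == expect_elements
    assert mesh.n_nodes == expect_nodes


@pytest.mark.parametrize("target", [64, 512, 800])
def test_mesh_geometry_invariants(target):
    """Positive areas, closed boundary loop, Euler relation for a disk."""
    mesh = build_circular_mesh(
        300.0, 16, target, n_sectors=16 if target == 64 else 8
    )
    assert np.all(mesh.element_areas > 0)
    boundary = mesh.boundary_nodes
    n_interior = mesh.n_nodes - len(boundary)
    assert mesh.n_elements == 2 * n_interior + len(boundary) - 2
    assert set(mesh.electrode_nodes).issubset(set(boundary.tolist()))
    # electrodes evenly spaced: angular gaps all equal
    ang = np.sort(
        np.mod(
            np.arctan2(
                mesh.nodes[mesh.electrode_nodes, 1],
                mesh.nodes[mesh.electrode_nodes, 0],
            ),
            2 * np.pi,
        )
    )
    gaps = np.diff(np.append(ang, ang[0] + 2 * np.pi))
    assert np.allclose(gaps, 2 * np.pi / 16, atol=1e-9)


def test_unreachable_element_count_is_an_error():
    with pytest.raises(MeshConstructionError):
        build_circular_mesh(300.0, 16, 260)  # between 128 and 512


def test_protocol_structure(protocol):
    assert len(protocol.injection_pairs) == 16
    for k, (src, snk) in enumerate(protocol.injection_pairs):
        assert src == k and snk == (k + 8) % 16
        assert len(protocol.measurement_pairs[k]) == 12
    assert protocol.n_measurements == 192


def test_forward_scaling_and_current_linearity(tiny_mesh, protocol, rng):
    """v is (-1)-homogeneous in sigma and 1-homogeneous in current."""
    sigma = 1.0 + rng.random(tiny_mesh.n_elements)
    v1 = solve_forward(tiny_mesh, ConductivityField(sigma), protocol).values
    v2 = solve_forward(tiny_mesh, ConductivityField(3 * sigma), protocol).values
    assert np.allclose(v2, v1 / 3, rtol=1e-12)
    p2 = opposite_adjacent_protocol(16, protocol.current_amplitude * 5)
    v3 = solve_forward(tiny_mesh, ConductivityField(sigma), p2).values
    assert np.allclose(v3, 5 * v1, rtol=1e-12)


def test_forward_reciprocity(tiny_mesh, rng):
    """Swapping drive and measurement pairs leaves the value unchanged."""
    from sceit.mesh_fem import Protocol

    sigma = ConductivityField(1.0 + rng.random(tiny_mesh.n_elements))
    # drive (0, 8), measure (3, 4)  vs  drive (3, 4), measure (0, 8)
    p_a = Protocol(((0, 8),), (((3, 4),),), 1e-3)
    p_b = Protocol(((3, 4),), (((0, 8),),), 1e-3)
    va = solve_forward(tiny_mesh, sigma, p_a).values[0]
    vb = solve_forward(tiny_mesh, sigma, p_b).values[0]
    assert va == pytest.approx(vb, rel=1e-10)


def test_forward_matches_analytic_disk_solution(forward_mesh, protocol):
    """Point sources on a homogeneous disk: logarithmic potential.

    For unit conductivity and boundary point electrodes the potential is
    u(z) = I/(pi*sigma) * (ln|z - z_sink| - ln|z - z_source|) up to a
    constant, which cancels in voltage differences.
    """
    sigma = ConductivityField(np.ones(forward_mesh.n_elements))
    v = solve_forward(forward_mesh, sigma, protocol).values
    z = forward_mesh.nodes[forward_mesh.electrode_nodes] @ np.array([1, 1j])
    amp = protocol.current_amplitude
    expected = []
    for d, (s, k) in enumerate(protocol.injection_pairs):
        with np.errstate(divide="ignore"):  # infinite at the driven electrodes
            u = amp / np.pi * (
                np.log(np.abs(z - z[k])) - np.log(np.abs(z - z[s]))
            )
        for (a, b) in protocol.measurement_pairs[d]:
            expected.append(u[a] - u[b])
    expected = np.array(expected)
    rel = np.linalg.norm(v - expected) / np.linalg.norm(expected)
    assert rel < 0.01


def test_jacobian_matches_finite_differences(tiny_mesh, protocol, rng):
    """Adjoint Jacobian vs central differences, 5 random fields, tol 1e-3."""
    for _ in range(5):
        sigma = 0.5 + rng.random(tiny_mesh.n_elements)
        J = compute_jacobian(tiny_mesh, ConductivityField(sigma), protocol)
        for n in rng.choice(tiny_mesh.n_elements, 3, replace=False):
            h = 1e-6 * sigma[n]
            up, dn = sigma.copy(), sigma.copy()
            up[n] += h
            dn[n] -= h
            fd = (
                solve_forward(tiny_mesh, ConductivityField(up), protocol).values
                - solve_forward(tiny_mesh, ConductivityField(dn), protocol).values
            ) / (2 * h)
            assert np.abs(J[:, n] - fd).max() <= 1e-3 * np.abs(fd).max()


def test_jacobian_row_sum_identity(tiny_mesh, protocol):
    """At sigma = 1 the row sums equal minus the measured voltages."""
    sigma = ConductivityField(np.ones(tiny_mesh.n_elements))
    J = compute_jacobian(tiny_mesh, sigma, protocol)
    v = solve_forward(tiny_mesh, sigma, protocol).values
    assert np.allclose(J.sum(axis=1), -v, rtol=1e-10, atol=1e-18)
    assert np.allclose(J @ np.zeros(tiny_mesh.n_elements), 0.0)


def test_noise_determinism_and_infinite_snr(rng):
    frame = VoltageFrame(rng.normal(size=192))
    assert add_gaussian_noise(frame, np.inf, 1).values is frame.values
    a = add_gaussian_noise(frame, 60.0, seed=7).values
    b = add_gaussian_noise(frame, 60.0, seed=7).values
    assert np.array_equal(a, b)
    c = add_gaussian_noise(frame, 60.0, seed=8).values
    assert not np.array_equal(a, c)


def test_noise_achieves_requested_snr(rng):
    """Monte-Carlo recomputation of the achieved SNR at 60 dB."""
    frame = VoltageFrame(rng.normal(size=192))
    sig_rms = np.sqrt(np.mean(frame.values ** 2))
    ratios = []
    for seed in range(10_000):
        noisy = add_gaussian_noise(frame, 60.0, seed=seed).values
        noise_rms = np.sqrt(np.mean((noisy - frame.values) ** 2))
        ratios.append(noise_rms ** 2)
    achieved = 20 * np.log10(sig_rms / np.sqrt(np.mean(ratios)))
    assert achieved == pytest.approx(60.0, abs=0.2)
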