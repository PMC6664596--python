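"""Circular 2-D finite-element meshes and the EIT forward problem.

The forward model is the standard piecewise-constant-conductivity Laplace
problem on a disk: current is injected through point electrodes on the
boundary, the interior potential solves div(sigma grad u) = 0 with insulating
(natural) boundary conditions away from the electrodes, and the potential is
grounded (u = 0) at the node nearest the disk center.  First-order (linear)
triangular elements are used throughout, so each element carries one
conductivity value and the potential gradient is constant per element.

Meshes are built by a deterministic ring construction (concentric rings of
nodes, 8 angular sectors) so that node and element counts — and therefore
every downstream matrix — are exactly reproducible.  A disk with ``n_rings``
rings has ``8 * n_rings**2`` elements and ``1 + 4 * n_rings * (n_rings + 1)``
nodes; ``n_rings = 10`` gives the 800-element / 441-node forward mesh and
``n_rings = 8`` the 512-element / 289-node inverse mesh used in the numerical
studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Mesh2D",
    "Protocol",
    "ConductivityField",
    "VoltageFrame",
    "build_circular_mesh",
    "opposite_adjacent_protocol",
    "solve_forward",
    "compute_jacobian",
    "add_gaussian_noise",
]

#: angular sectors of the ring construction; 8 makes the printed mesh sizes
#: (800/441, 512/289) reachable with 16 evenly spaced boundary electrodes.
N_SECTORS = 8


class MeshConstructionError(ValueError):
    """Raised when a requested triangulation would be degenerate."""


@dataclass(frozen=True)
class Mesh2D:
    """Triangulated disk.

    Attributes
    ----------
    nodes : (n_nodes, 2) float array
        Node coordinates in pixel units, origin at the disk center.
    elements : (n_elements, 3) int array
        Node-index triples, consistently counterclockwise.
    radius : float
        Disk radius in pixels.
    electrode_nodes : (n_electrodes,) int array
        Boundary node indices of the electrodes, counterclockwise.
    ground_node : int
        Node at which the potential is fixed to zero (nearest the center).
    """

    nodes: np.ndarray
    elements: np.ndarray
    radius: float
    electrode_nodes: np.ndarray
    ground_node: int

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def element_areas(self) -> np.ndarray:
        """Signed areas; positive for a valid mesh."""
        p = self.nodes[self.elements]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    @property
    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    @property
    def boundary_nodes(self) -> np.ndarray:
        """Nodes on the outer rim, in counterclockwise order."""
        r = np.hypot(self.nodes[:, 0], self.nodes[:, 1])
        idx = np.flatnonzero(r > self.radius * (1 - 1e-9))
        ang = np.arctan2(self.nodes[idx, 1], self.nodes[idx, 0])
        return idx[np.argsort(ang)]


@dataclass(frozen=True)
class Protocol:
    """Current-injection / voltage-measurement pattern.

    ``injection_pairs[d]`` is an ordered (source, sink) electrode-index pair;
    ``measurement_pairs[d]`` lists the adjacent electrode pairs measured while
    injection ``d`` is active (electrodes in the active pair are excluded).
    """

    injection_pairs: tuple
    measurement_pairs: tuple
    current_amplitude: float = 1e-3

    @property
    def n_measurements(self) -> int:
        return sum(len(m) for m in self.measurement_pairs)


@dataclass(frozen=True)
class ConductivityField:
    """Per-element conductivity (S/m) at one frequency."""

    values: np.ndarray
    frequency_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values <= 0):
            raise ValueError("conductivity must be strictly positive")


@dataclass(frozen=True)
class VoltageFrame:
    """K voltage differences (V) for one frequency and one frame role."""

    values: np.ndarray
    frequency_index: int = 0
    role: str = "background"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _ring_nodes(
    radius: float, n_rings: int, phase: float, n_sectors: int = N_SECTORS
) -> np.ndarray:
    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        n_k = n_sectors * k
        ang = phase + 2.0 * np.pi * np.arange(n_k) / n_k
        r = radius * k / n_rings
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.asarray(pts)


def _stitch_rings(inner: np.ndarray, outer: np.ndarray) -> list:
    """Triangulate the annulus between two concentric node rings.

    Advances two angular pointers, emitting one triangle per step; yields
    ``len(inner) + len(outer)`` triangles with consistent orientation.
    """
    n1, n2 = len(inner), len(outer)
    tris = []
    i = j = 0
    for _ in range(n1 + n2):
        if (j + 1) * n1 <= (i + 1) * n2:  # advance outer pointer
            tris.append((inner[i % n1], outer[j % n2], outer[(j + 1) % n2]))
            j += 1
        else:  # advance inner pointer
            tris.append((inner[i % n1], outer[j % n2], inner[(i + 1) % n1]))
            i += 1
    return tris


def build_circular_mesh(
    radius: float,
    n_electrodes: int = 16,
    target_elements: int = 800,
    n_sectors: int = N_SECTORS,
) -> Mesh2D:
    """Build a ring-structured triangulated disk.

    The ring count is chosen so the element count ``n_sectors * n_rings**2``
    is as close as possible to ``target_elements`` (and within ±10% of it).
    Electrodes are snapped to the nearest of the evenly spaced boundary
    nodes; the whole mesh is rotated by half an electrode spacing so the +x
    axis points midway between two electrodes.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    candidates = [
        max(1, int(np.floor(np.sqrt(target_elements / n_sectors)))),
        max(1, int(np.ceil(np.sqrt(target_elements / n_sectors)))),
    ]
    n_rings = min(
        candidates, key=lambda n: abs(n_sectors * n ** 2 - target_elements)
    )
    n_elem = n_sectors * n_rings ** 2
    if abs(n_elem - target_elements) > 0.1 * target_elements:
        raise MeshConstructionError(
            f"ring construction reaches {n_elem} elements, "
            f"not within 10% of target {target_elements}"
        )
    phase = np.pi / n_electrodes
    nodes = _ring_nodes(radius, n_rings, phase, n_sectors)

    elements = []
    # innermost fan around the center node
    ring1 = np.arange(1, 1 + n_sectors)
    for m in range(n_sectors):
        elements.append((0, ring1[m], ring1[(m + 1) % n_sectors]))
    start = 1
    for k in range(2, n_rings + 1):
        inner = np.arange(start, start + n_sectors * (k - 1))
        start += n_sectors * (k - 1)
        outer = np.arange(start, start + n_sectors * k)
        elements.extend(_stitch_rings(inner, outer))
    elements = np.asarray(elements, dtype=np.int64)

    mesh = Mesh2D(
        nodes=nodes,
        elements=elements,
        radius=float(radius),
        electrode_nodes=np.zeros(n_electrodes, dtype=np.int64),
        ground_node=0,
    )
    areas = mesh.element_areas
    neg = areas < 0
    if np.any(neg):
        elements[neg] = elements[neg][:, [0, 2, 1]]
    if np.any(np.isclose(np.abs(areas), 0.0)):
        raise MeshConstructionError("degenerate (zero-area) element produced")

    # electrodes: nearest boundary node to each target angle
    boundary = np.arange(len(nodes) - n_sectors * n_rings, len(nodes))
    b_ang = np.mod(np.arctan2(nodes[boundary, 1], nodes[boundary, 0]), 2 * np.pi)
    order = np.argsort(b_ang)
    boundary, b_ang = boundary[order], b_ang[order]
    elec = []
    for e in range(n_electrodes):
        want = np.mod(phase + 2 * np.pi * e / n_electrodes, 2 * np.pi)
        d = np.abs(np.angle(np.exp(1j * (b_ang - want))))
        elec.append(boundary[int(np.argmin(d))])
    electrode_nodes = np.asarray(elec, dtype=np.int64)
    if len(set(electrode_nodes.tolist())) != n_electrodes:
        raise MeshConstructionError("electrodes collapsed onto shared nodes")

    return Mesh2D(
        nodes=nodes,
        elements=elements,
        radius=float(radius),
        electrode_nodes=electrode_nodes,
        ground_node=int(np.argmin(np.hypot(nodes[:, 0], nodes[:, 1]))),
    )


def opposite_adjacent_protocol(
    n_electrodes: int = 16, current_amplitude: float = 1e-3
) -> Protocol:
    """Opposite (polar) drive with adjacent measurement.

    Source ``k`` pairs with sink ``k + n/2 (mod n)`` for every ``k``; voltage
    is measured on every adjacent pair ``(j, j+1 mod n)`` whose electrodes are
    both passive.  For 16 electrodes this yields 16 injections x 12
    measurements = 192 values per frame.
    """
    half = n_electrodes // 2
    injections, measurements = [], []
    for k in range(n_electrodes):
        src, snk = k, (k + half) % n_electrodes
        injections.append((src, snk))
        active = {src, snk}
        pairs = [
            (j, (j + 1) % n_electrodes)
            for j in range(n_electrodes)
            if j not in active and (j + 1) % n_electrodes not in active
        ]
        measurements.append(tuple(pairs))
    return Protocol(
        injection_pairs=tuple(injections),
        measurement_pairs=tuple(measurements),
        current_amplitude=float(current_amplitude),
    )


# ---------------------------------------------------------------------------
# FEM assembly and forward solve
# ---------------------------------------------------------------------------

def _element_gradients(mesh: Mesh2D):
    """Per-element shape-function gradient coefficients.

    Returns ``(bmat, cmat, areas)`` where for element ``e`` with nodes
    ``(i, j, k)`` the potential gradient is
    ``grad u = (bmat[e] . u[nodes], cmat[e] . u[nodes]) / (2 areas[e])``.
    """
    p = mesh.nodes[mesh.elements]
    x, y = p[..., 0], p[..., 1]
    b = np.stack(
        [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
    )
    c = np.stack(
        [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
    )
    return b, c, mesh.element_areas


def _stiffness(mesh: Mesh2D, sigma: np.ndarray) -> sp.csc_matrix:
    b, c, areas = _element_gradients(mesh)
    coeff = sigma / (4.0 * areas)  # sigma_e / (4 A_e)
    local = coeff[:, None, None] * (
        b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]
    )
    rows = np.repeat(mesh.elements, 3, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 3)).ravel()
    K = sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    # symmetric Dirichlet elimination at the ground node
    g = mesh.ground_node
    K = K.tolil()
    K[g, :] = 0.0
    K[:, g] = 0.0
    K[g, g] = 1.0
    return K.tocsc()


def _node_potentials(mesh: Mesh2D, sigma: np.ndarray, protocol: Protocol):
    """Solve the grounded system for every injection; returns (D, n_nodes)."""
    K = _stiffness(mesh, sigma)
    lu = spla.splu(K)
    amp = protocol.current_amplitude
    rhs = np.zeros((mesh.n_nodes, len(protocol.injection_pairs)))
    for d, (src, snk) in enumerate(protocol.injection_pairs):
        rhs[mesh.electrode_nodes[src], d] += amp
        rhs[mesh.electrode_nodes[snk], d] -= amp
    rhs[mesh.ground_node, :] = 0.0
    return lu.solve(rhs).T, lu


def _measure(u_all: np.ndarray, mesh: Mesh2D, protocol: Protocol) -> np.ndarray:
    vals = []
    for d, pairs in enumerate(protocol.measurement_pairs):
        u = u_all[d]
        for (a, b) in pairs:
            vals.append(
                u[mesh.electrode_nodes[a]] - u[mesh.electrode_nodes[b]]
            )
    return np.asarray(vals)


def solve_forward(
    mesh: Mesh2D, sigma: ConductivityField, protocol: Protocol
) -> VoltageFrame:
    """Boundary voltage differences for a piecewise-constant conductivity."""
    s = np.asarray(sigma.values, dtype=float)
    if s.ndim == 0:
        s = np.full(mesh.n_elements, float(s))
    if s.shape[0] != mesh.n_elements:
        raise ValueError("sigma length must equal the element count")
    u_all, _ = _node_potentials(mesh, s, protocol)
    return VoltageFrame(
        values=_measure(u_all, mesh, protocol),
        frequency_index=sigma.frequency_index,
    )


def compute_jacobian(
    mesh: Mesh2D, sigma: ConductivityField, protocol: Protocol
) -> np.ndarray:
    """Sensitivity of every measurement to every element conductivity.

    Uses the adjoint (compensation-theorem) identity: the derivative of
    measurement ``(d, m)`` with respect to ``sigma_e`` is
    ``-integral_e grad(u_drive) . grad(u_meas)`` where ``u_meas`` is the
    potential generated by a unit current through the measurement pair.
    Returns a dense (K, N) array ordered like the protocol.
    """
    s = np.asarray(sigma.values, dtype=float)
    if s.ndim == 0:
        s = np.full(mesh.n_elements, float(s))
    if s.shape[0] != mesh.n_elements:
        raise ValueError("sigma length must equal the element count")
    u_all, lu = _node_potentials(mesh, s, protocol)

    # adjoint fields: unit current at each single electrode (return via ground)
    n_el = len(mesh.electrode_nodes)
    rhs = np.zeros((mesh.n_nodes, n_el))
    rhs[mesh.electrode_nodes, np.arange(n_el)] = 1.0
    rhs[mesh.ground_node, :] = 0.0
    w_all = lu.solve(rhs).T  # (n_el, n_nodes)

    b, c, areas = _element_gradients(mesh)
    inv2a = 1.0 / (2.0 * areas)

    def grads(u):
        ue = u[mesh.elements]
        return (b * ue).sum(axis=1) * inv2a, (c * ue).sum(axis=1) * inv2a

    wx = np.empty((n_el, mesh.n_elements))
    wy = np.empty((n_el, mesh.n_elements))
    for e in range(n_el):
        wx[e], wy[e] = grads(w_all[e])

    rows = []
    for d, pairs in enumerate(protocol.measurement_pairs):
        gx_d, gy_d = grads(u_all[d])
        for (a, bb) in pairs:
            gx_m = wx[a] - wx[bb]
            gy_m = wy[a] - wy[bb]
            rows.append(-areas * (gx_d * gx_m + gy_d * gy_m))
    return np.asarray(rows)


def add_gaussian_noise(
    frame: VoltageFrame, snr_db: float, seed: int
) -> VoltageFrame:
    """Additive white Gaussian noise scaled to an RMS signal-to-noise ratio.

    The noise standard deviation is ``RMS(frame) * 10**(-snr_db / 20)``; an
    infinite SNR returns the frame unchanged.  Identical seeds give identical
    noise.
    """
    if np.isinf(snr_db):
        return frame
    rms = np.sqrt(np.mean(frame.values ** 2))
    std = rms * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = frame.values + rng.normal(0.0, std, size=frame.values.shape)
    return VoltageFrame(
        values=noisy, frequency_index=frame.frequency_index, role=frame.role
    )
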