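"""Image-quality metrics for reconstructed conductivity/fraction images.

An image is a per-element value array on the reconstruction mesh.  The
region of perturbation (RP) is the largest edge-connected cluster of
elements whose absolute deviation from the image mean exceeds half the
maximum absolute deviation.  Four figures of merit are computed against a
known elliptical target:

* PE — position error: difference between the center distances of the RP
  centroid and the true target center, normalized by the mesh diameter.
* SD — shape deformation: mean difference of the axis-aligned bounding-box
  extents of the RP and the true target, normalized by the mesh diameter.
* IN — image noise: inverse contrast-to-noise ratio, i.e. the standard
  deviation of the image over the background divided by the absolute
  contrast between the mean target change and the mean background change.
* TE = PE + SD + IN.

All three components are invariant to adding a constant to the image and to
multiplying it by a positive scalar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .fraction_model import TissueSpectra
from .mesh_fem import Mesh2D

__all__ = [
    "EllipseTarget",
    "ImageMetrics",
    "FlatImageError",
    "region_of_perturbation",
    "true_target_elements",
    "compute_metrics",
    "mean_relative_contrast",
]


class FlatImageError(ValueError):
    """Constant image: the region of perturbation is undefined."""


@dataclass(frozen=True)
class EllipseTarget:
    """Axis-aligned elliptical perturbation (pixel units)."""

    center: tuple
    semi_axes: tuple
    tissue_index: int = 1

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        a, b = self.semi_axes
        return ((p[:, 0] - self.center[0]) / a) ** 2 + (
            (p[:, 1] - self.center[1]) / b
        ) ** 2 <= 1.0

    @property
    def center_distance(self) -> float:
        return float(np.hypot(*self.center))

    @property
    def extents(self) -> tuple:
        return (2.0 * self.semi_axes[0], 2.0 * self.semi_axes[1])


@dataclass(frozen=True)
class ImageMetrics:
    pe: float
    sd: float
    in_: float
    rp_elements: np.ndarray

    @property
    def te(self) -> float:
        return self.pe + self.sd + self.in_


def element_adjacency(mesh: Mesh2D) -> sp.csr_matrix:
    """Element adjacency through shared edges (not shared vertices)."""
    edges = {}
    rows, cols = [], []
    for e, tri in enumerate(mesh.elements):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            other = edges.get(key)
            if other is None:
                edges[key] = e
            else:
                rows += [other, e]
                cols += [e, other]
    n = mesh.n_elements
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )


def region_of_perturbation(image: np.ndarray, mesh: Mesh2D) -> np.ndarray:
    """Largest edge-connected cluster of strongly deviating elements.

    Elements with ``|x_n - mean(x)| > 0.5 * max|x_n - mean(x)|`` are
    thresholded, then reduced to the largest connected cluster (ties broken
    by the smallest contained element index).  A constant image raises
    :class:`FlatImageError`.
    """
    image = np.asarray(image, dtype=float).ravel()
    if image.size != mesh.n_elements:
        raise ValueError("image length must equal the element count")
    dev = np.abs(image - image.mean())
    peak = dev.max()
    if peak == 0.0:
        raise FlatImageError("constant image: region of perturbation empty")
    mask = dev > 0.5 * peak
    idx = np.flatnonzero(mask)
    adj = element_adjacency(mesh)[np.ix_(idx, idx)]
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = np.flatnonzero(sizes == sizes.max())
    if best.size > 1:  # deterministic tie-break
        best = [min(best, key=lambda c: idx[labels == c].min())]
    return idx[labels == best[0]]


def true_target_elements(mesh: Mesh2D, target: EllipseTarget) -> np.ndarray:
    """Elements whose centroid falls inside the true ellipse."""
    return np.flatnonzero(target.contains(mesh.element_centroids))


def compute_metrics(
    image: np.ndarray, mesh: Mesh2D, target: EllipseTarget
) -> ImageMetrics:
    """Score one change image against the true elliptical target."""
    image = np.asarray(image, dtype=float).ravel()
    rp = region_of_perturbation(image, mesh)
    d_mesh = 2.0 * mesh.radius

    areas = mesh.element_areas[rp]
    centroid = np.average(mesh.element_centroids[rp], axis=0, weights=areas)
    d_rp = float(np.hypot(*centroid))
    pe = abs(d_rp - target.center_distance) / d_mesh

    rp_nodes = mesh.nodes[np.unique(mesh.elements[rp])]
    lx_rp = float(rp_nodes[:, 0].max() - rp_nodes[:, 0].min())
    ly_rp = float(rp_nodes[:, 1].max() - rp_nodes[:, 1].min())
    lx_real, ly_real = target.extents
    sd = 0.5 * (abs(lx_rp - lx_real) + abs(ly_rp - ly_real)) / d_mesh

    tgt = true_target_elements(mesh, target)
    if tgt.size == 0:
        raise ValueError("true target contains no element centroid")
    bg = np.setdiff1d(np.arange(mesh.n_elements), tgt)
    contrast = abs(image[tgt].mean() - image[bg].mean())
    noise = image[bg].std(ddof=1)
    if contrast == 0.0:
        warnings.warn("zero target/background contrast; image noise infinite")
        in_ = float("inf")
    else:
        in_ = noise / contrast

    return ImageMetrics(pe=float(pe), sd=float(sd), in_=float(in_), rp_elements=rp)


def mean_relative_contrast(
    spectra: TissueSpectra, tissue_a: int = 0, tissue_b: int = 1
) -> float:
    """Mean relative conductivity contrast between two tissues, in percent.

    Averages ``(eps_ib - eps_ia) / eps_ia`` over the measurement frequencies
    and reports the magnitude as a percentage.
    """
    ea = spectra.values[tissue_a]
    eb = spectra.values[tissue_b]
    return float(abs(np.mean((eb - ea) / ea)) * 100.0)
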