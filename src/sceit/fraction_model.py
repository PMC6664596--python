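"""Tissue volume-fraction model of the conductivity distribution.

Each mesh element is a convex combination of a small set of tissues with
known conductivity spectra: the conductivity of element ``n`` at angular
frequency ``w_i`` is ``sigma_n(w_i) = sum_j f_nj * sigma_ij`` where ``f_nj``
is the volume fraction of tissue ``j`` in element ``n``, ``0 <= f_nj <= 1``
and the fractions of every element sum to one.  The fractions are independent
of frequency, which is what lets multi-frequency measurements be stacked into
a single linear system.

Vectorization convention: the T x N fraction matrix (tissue rows, element
columns) is flattened column-major, so the T fractions of element ``n``
occupy the contiguous slots ``n*T ... n*T + T - 1`` — matching the block
layout of the spectral coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mesh_fem import ConductivityField

__all__ = [
    "TissueSpectra",
    "FractionField",
    "coefficient_matrix",
    "fractions_to_conductivity",
    "clamp_fractions",
    "eliminate_reference_tissue",
    "expand_reference_tissue",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TissueSpectra:
    """Conductivity of each tissue at each measurement frequency.

    ``values[j, i]`` is the conductivity (S/m) of tissue ``j`` at frequency
    ``frequencies[i]``.  Tissue 0 is conventionally the background
    (reference) tissue.
    """

    tissue_names: tuple
    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "frequencies", np.asarray(self.frequencies, dtype=float)
        )
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.tissue_names), len(self.frequencies)):
            raise ValueError("values must have shape (n_tissues, n_frequencies)")
        if np.any(self.values <= 0):
            raise ValueError("conductivities must be strictly positive")
        if self.n_tissues < 2:
            raise ValueError("at least two tissues are required")

    @property
    def n_tissues(self) -> int:
        return self.values.shape[0]

    @property
    def n_frequencies(self) -> int:
        return self.values.shape[1]

    def at_frequency(self, i: int) -> np.ndarray:
        """Conductivities of all tissues at frequency index ``i``."""
        return self.values[:, i]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.tissue_names), columns=self.frequencies
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TissueSpectra":
        """Build from a tissue-by-frequency table (rows tissues)."""
        return cls(
            tissue_names=tuple(str(t) for t in table.index),
            frequencies=np.asarray(table.columns, dtype=float),
            values=table.to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path) -> "TissueSpectra":
        return cls.from_table(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path)


@dataclass(frozen=True)
class FractionField:
    """Per-element tissue fractions, shape (T, N)."""

    matrix: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        if self.matrix.ndim != 2:
            raise ValueError("fraction matrix must be 2-D (tissues x elements)")
        self.validate()

    def validate(self) -> None:
        f = self.matrix
        if np.any(f < -_SUM_TOL) or np.any(f > 1 + _SUM_TOL):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.abs(f.sum(axis=0) - 1.0) > 1e-6):
            raise ValueError("fractions of every element must sum to 1")

    @property
    def n_tissues(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_elements(self) -> int:
        return self.matrix.shape[1]

    @property
    def vector(self) -> np.ndarray:
        """Column-major flattening: element n's T fractions contiguous."""
        return self.matrix.ravel(order="F")

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_tissues: int) -> "FractionField":
        vec = np.asarray(vec, dtype=float)
        return cls(vec.reshape((n_tissues, -1), order="F"))

    @classmethod
    def homogeneous(cls, n_tissues: int, n_elements: int) -> "FractionField":
        """Pure background tissue everywhere (tissue 0 fraction = 1)."""
        m = np.zeros((n_tissues, n_elements))
        m[0] = 1.0
        return cls(m)


def coefficient_matrix(
    spectra: TissueSpectra, frequency_index: int, n_elements: int
) -> sp.csr_matrix:
    """Spectral coefficient matrix A(w_i), shape (N, T*N).

    Row ``n`` carries the T tissue conductivities at frequency ``w_i`` in the
    columns belonging to element ``n``, so ``A @ F.vector`` maps fractions to
    the per-element conductivity.
    """
    if not 0 <= frequency_index < spectra.n_frequencies:
        raise IndexError(
            f"frequency_index {frequency_index} out of range "
            f"[0, {spectra.n_frequencies})"
        )
    eps = spectra.at_frequency(frequency_index)
    T = spectra.n_tissues
    rows = np.repeat(np.arange(n_elements), T)
    cols = np.arange(n_elements * T)
    data = np.tile(eps, n_elements)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(n_elements, T * n_elements)
    )


def fractions_to_conductivity(
    F: FractionField, spectra: TissueSpectra, frequency_index: int
) -> ConductivityField:
    """Per-element conductivity implied by the fractions at one frequency."""
    if F.n_tissues != spectra.n_tissues:
        raise ValueError("fraction field and spectra disagree on tissue count")
    eps = spectra.at_frequency(frequency_index)
    return ConductivityField(
        values=eps @ F.matrix, frequency_index=frequency_index
    )


def clamp_fractions(F_tilde: np.ndarray) -> FractionField:
    """Project unconstrained fractions back onto the feasible set.

    The non-reference tissues (rows 1..T-1) are clipped to [0, 1]; if their
    sum in an element exceeds one they are rescaled proportionally to sum to
    one; the reference-tissue fraction is then set to the complement.  The
    operation is idempotent and preserves fields that are already feasible.
    """
    F_tilde = np.asarray(F_tilde, dtype=float)
    rest = np.clip(F_tilde[1:], 0.0, 1.0)
    s = rest.sum(axis=0)
    over = s > 1.0
    if np.any(over):
        rest[:, over] /= s[over]
    out = np.empty_like(F_tilde)
    out[1:] = rest
    out[0] = 1.0 - rest.sum(axis=0)
    # guard against negative zeros from rounding
    np.clip(out[0], 0.0, 1.0, out=out[0])
    return FractionField(out)


def eliminate_reference_tissue(F: FractionField) -> np.ndarray:
    """Drop the reference-tissue row (recoverable as 1 - sum of the rest)."""
    return F.matrix[1:].copy()


def expand_reference_tissue(reduced: np.ndarray) -> FractionField:
    """Inverse of :func:`eliminate_reference_tissue`."""
    reduced = np.atleast_2d(np.asarray(reduced, dtype=float))
    full = np.empty((reduced.shape[0] + 1, reduced.shape[1]))
    full[1:] = reduced
    full[0] = 1.0 - reduced.sum(axis=0)
    return FractionField(full)


# ---------------------------------------------------------------------------
# spectra presets (conductivities in S/m)
# ---------------------------------------------------------------------------

def brain_spectra() -> TissueSpectra:
    """Normal vs ischemic human brain tissue at three frequencies.

    Literature conductivities in the 10 Hz - 100 kHz band; the background
    (normal) tissue is tissue 0 and the ischemic perturbation tissue 1.
    """
    return TissueSpectra(
        tissue_names=("normal_brain", "ischemia_brain"),
        frequencies=np.array([1e3, 1e4, 1e5]),
        values=np.array([[0.151, 0.155, 0.175], [0.115, 0.120, 0.130]]),
    )


def phantom_spectra() -> TissueSpectra:
    """Saline-pomelo background vs cucumber perturbation (tank phantom)."""
    return TissueSpectra(
        tissue_names=("pomelo", "cucumber"),
        frequencies=np.array([20e3, 50e3, 100e3]),
        values=np.array([[0.083, 0.105, 0.129], [0.047, 0.065, 0.093]]),
    )


def brain_blood_spectra() -> TissueSpectra:
    """Three-tissue variant: blood is flat at 0.7 S/m across the band."""
    base = brain_spectra()
    return TissueSpectra(
        tissue_names=base.tissue_names + ("blood",),
        frequencies=base.frequencies,
        values=np.vstack([base.values, np.full(base.n_frequencies, 0.7)]),
    )
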