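"""The 25-dimensional interface descriptor.

Each structure is summarised by five feature families, concatenated in
a fixed order: 20 residue-type percentages over the interface atoms,
the TM-score of the alignment that produced the modelled complex, a
curvature index (convex and concave components from the per-atom
kappa = cos(Omega/4)), the mean alpha-shape connectivity of the
interface atoms, and the interface-atom fraction of the whole complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alpha import AlphaShape, curvature_from_solid_angle, solid_angle, vertex_degree
from .interface import InterfaceSet
from .structure import Structure

__all__ = [
    "RESIDUE_ORDER",
    "FEATURE_NAMES",
    "FeatureVector",
    "residue_index",
    "curvature_index",
    "mean_connectivity",
    "interface_atom_index",
    "assemble",
    "write_feature_table",
    "read_feature_table",
]

#: Residue order of the 20 percentage slots (GLU precedes GLN).
RESIDUE_ORDER = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLU", "GLN", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

FEATURE_NAMES = tuple(f"pct_{r}" for r in RESIDUE_ORDER) + (
    "tm_score",
    "convex_index",
    "concave_index",
    "mean_connectivity",
    "interface_atom_index",
)


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 25-dimensional descriptor of one structure."""

    residue_index: tuple[float, ...]
    tm_score: float
    convex_index: float
    concave_index: float
    mean_connectivity: float
    interface_atom_index: float

    def __post_init__(self) -> None:
        if len(self.residue_index) != 20:
            raise ValueError("residue_index must have 20 entries")

    def to_array(self) -> np.ndarray:
        return np.array(
            list(self.residue_index)
            + [
                self.tm_score,
                self.convex_index,
                self.concave_index,
                self.mean_connectivity,
                self.interface_atom_index,
            ]
        )

    @classmethod
    def from_array(cls, arr) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (25,):
            raise ValueError(f"expected 25 components, got {arr.shape}")
        return cls(
            residue_index=tuple(arr[:20]),
            tm_score=float(arr[20]),
            convex_index=float(arr[21]),
            concave_index=float(arr[22]),
            mean_connectivity=float(arr[23]),
            interface_atom_index=float(arr[24]),
        )


def residue_index(
    interface: InterfaceSet,
    protein_structure: Structure | None = None,
    on_nonstandard: str = "error",
) -> np.ndarray:
    """Percentage of each residue type among the interface atoms.

    Counts atoms (each interface atom contributes its residue's type)
    and normalises by the interface size, so non-zero entries sum
    to 100.  An empty interface yields the all-zero vector.

    ``on_nonstandard`` controls atoms with a residue name outside the
    20 standard types: ``"error"`` (default) raises, ``"skip"`` drops
    them and renormalises over the remainder.
    """
    protein = protein_structure or interface.protein_structure
    if not interface.atom_indices:
        return np.zeros(20)
    counts = dict.fromkeys(RESIDUE_ORDER, 0)
    n_used = 0
    for i in sorted(interface.atom_indices):
        name = protein.atoms[i].residue_name
        if name not in counts:
            if on_nonstandard == "skip":
                continue
            raise ValueError(f"non-standard residue name {name!r} in interface")
        counts[name] += 1
        n_used += 1
    if n_used == 0:
        return np.zeros(20)
    return np.array([100.0 * counts[r] / n_used for r in RESIDUE_ORDER])


def curvature_index(
    interface: InterfaceSet,
    protein_shape: AlphaShape | None = None,
    signed: bool = True,
) -> tuple[float, float]:
    """(convex, concave) curvature indices of the interface.

    Per atom kappa = cos(Omega/4) on the protein-alone shape; the
    convex index averages the positive kappa over all interface atoms,
    the concave index the negative kappa (kept signed unless
    ``signed=False``, which returns its magnitude).
    """
    shape = protein_shape or interface.protein_shape
    if not interface.atom_indices:
        return (0.0, 0.0)
    n = len(interface.atom_indices)
    convex = concave = 0.0
    for i in interface.atom_indices:
        kappa = curvature_from_solid_angle(solid_angle(shape, i))
        if kappa > 0:
            convex += kappa
        elif kappa < 0:
            concave += kappa
    convex /= n
    concave /= n
    return (convex, concave if signed else abs(concave))


def mean_connectivity(interface: InterfaceSet, protein_shape: AlphaShape | None = None) -> float:
    """Mean number of boundary edges per interface atom; 0 when empty."""
    shape = protein_shape or interface.protein_shape
    if not interface.atom_indices:
        return 0.0
    return float(
        np.mean([vertex_degree(shape, i) for i in interface.atom_indices])
    )


def interface_atom_index(interface: InterfaceSet) -> float:
    """Interface size relative to the whole complex: |interface| / n_atoms."""
    if interface.n_complex_atoms <= 0:
        raise ValueError("complex has no atoms")
    return len(interface.atom_indices) / interface.n_complex_atoms


def assemble(
    residue_index,
    tm_score: float,
    curvature_index: tuple[float, float],
    mean_connectivity: float,
    interface_atom_index: float,
) -> FeatureVector:
    """Concatenate the five feature families into the 25-dim vector."""
    residue_index = tuple(float(x) for x in np.asarray(residue_index).ravel())
    if len(residue_index) != 20:
        raise ValueError("residue_index must have 20 entries")
    convex, concave = (float(x) for x in curvature_index)
    return FeatureVector(
        residue_index=residue_index,
        tm_score=float(tm_score),
        convex_index=convex,
        concave_index=concave,
        mean_connectivity=float(mean_connectivity),
        interface_atom_index=float(interface_atom_index),
    )


def write_feature_table(path, ids, vectors, labels=None) -> None:
    """Write features as CSV: an id column, the 25 named columns, optional label."""
    rows = np.vstack([v.to_array() for v in vectors])
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "id", list(ids))
    if labels is not None:
        df["label"] = list(labels)
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV, validating the 25-column layout."""
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df
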