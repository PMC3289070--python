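"""Protein–DNA interface extraction by alpha-shape surface comparison.

An interface atom is a protein atom that is on the surface of the
protein taken alone but *not* on the surface of the full protein–DNA
complex — i.e. an atom buried by DNA binding.  Atoms are matched
across the two surface computations by identity (chain, residue id,
atom name), never by coordinates.

Both surfaces are evaluated at one shared roughness.  A common alpha
is what makes the set difference meaningful — comparing surfaces
computed at different roughness scales reports the roughness mismatch,
not DNA burial.  The shared value is the complex's automatically
selected alpha (the smallest making the complex one solid covering all
atoms, the quantity the alpha-shape library's optimal-alpha query
answers), capped at twice the protein's own automatic alpha so that a
barely- or non-contacting partner cannot drive the roughness far
beyond the protein's intrinsic scale.  The cap rarely binds for true
complexes; for well-separated partners it keeps alpha at the protein
scale, no mixed simplex enters the complex shape, the two surfaces
coincide on the protein, and the interface is empty, as it must be.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alpha import AlphaShape, alpha_complex, delaunay_3d, select_alpha, surface_atoms
from .structure import Structure, strip_dna

__all__ = ["InterfaceSet", "extract_interface"]


@dataclass
class InterfaceSet:
    """Interface atoms, indexed into the protein-only structure."""

    atom_indices: frozenset[int]
    n_complex_atoms: int
    provenance: dict[str, float]
    protein_structure: Structure = field(repr=False)
    protein_shape: AlphaShape | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.atom_indices)


def extract_interface(complex_structure: Structure) -> InterfaceSet:
    """Interface atom set {Protein} \\ {Complex} of a protein–DNA complex.

    Builds the alpha-shape surface of the protein alone and of the full
    complex at the shared alpha and returns the protein atoms that are
    surface in the former but absent from the latter.  A structure with
    no DNA atoms follows the degenerate path: the interface is empty.

    Raises
    ------
    ValueError
        If the protein part is too small to triangulate, or two protein
        atoms share the same (chain, residue id, atom name) identity.
    """
    protein = strip_dna(complex_structure)
    if len(protein) < 4:
        raise ValueError("protein part too small for a 3-D alpha shape")

    identities = [a.identity for a in protein.atoms]
    if len(set(identities)) != len(identities):
        raise ValueError("identity collision among protein atoms")

    tri_protein = delaunay_3d(protein.coords())
    alpha_protein = select_alpha(tri_protein)

    if not complex_structure.dna_atoms:
        shape_p = alpha_complex(tri_protein, alpha_protein)
        return InterfaceSet(
            atom_indices=frozenset(),
            n_complex_atoms=len(complex_structure),
            provenance={
                "alpha_protein": alpha_protein,
                "alpha_complex": float("nan"),
                "alpha_shared": alpha_protein,
            },
            protein_structure=protein,
            protein_shape=shape_p,
        )

    tri_complex = delaunay_3d(complex_structure.coords())
    alpha_cplx = select_alpha(tri_complex)
    alpha = min(alpha_cplx, 2.0 * alpha_protein)

    shape_p = alpha_complex(tri_protein, alpha)
    protein_surface = surface_atoms(shape_p)
    complex_surface_ids = {
        complex_structure.atoms[i].identity
        for i in surface_atoms(alpha_complex(tri_complex, alpha))
    }

    interface = frozenset(
        i for i in protein_surface if identities[i] not in complex_surface_ids
    )
    return InterfaceSet(
        atom_indices=interface,
        n_complex_atoms=len(complex_structure),
        provenance={
            "alpha_protein": alpha_protein,
            "alpha_complex": alpha_cplx,
            "alpha_shared": alpha,
        },
        protein_structure=protein,
        protein_shape=shape_p,
    )
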