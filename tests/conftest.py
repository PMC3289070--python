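import numpy as np
import pytest

from alphadna import Atom, Structure
from alphadna.fixtures import ToyComplexSpec, make_toy_complex


def regular_tetrahedron(edge: float = 1.0) -> np.ndarray:
    """Vertices of a regular tetrahedron with the given edge length."""
    pts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return pts * (edge / np.sqrt(8.0))


def simple_structure(n_protein: int = 30, n_dna: int = 12, n_hydrogens: int = 0) -> Structure:
    """Hand-built structure: chains A/B protein, chain C DNA, optional hydrogens."""
    rng = np.random.default_rng(42)
    atoms = []
    serial = 0
    residues = ["ALA", "ARG", "GLY", "LYS", "SER"]
    for i in range(n_protein):
        chain = "A" if i < n_protein // 2 else "B"
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name="CA",
                element="C",
                residue_name=residues[i % len(residues)],
                residue_id=(chain, i + 1, ""),
                coord=tuple(np.round(rng.normal(size=3) * 8, 3)),
            )
        )
    for i in range(n_dna):
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name="C1'",
                element="C",
                residue_name=["DA", "DT", "DG", "DC"][i % 4],
                residue_id=("C", i + 1, ""),
                coord=tuple(np.round(rng.normal(size=3) * 8 + 30, 3)),
            )
        )
    for i in range(n_hydrogens):
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name="H",
                element="H",
                residue_name="ALA",
                residue_id=("A", 1, ""),
                coord=(float(i), 0.0, 0.0),
            )
        )
    return Structure(atoms=atoms)


@pytest.fixture(scope="session")
def toy_complex():
    """One deterministic toy complex with its contact ground truth."""
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_interface(toy_complex):
    from alphadna import extract_interface

    complex_structure, _ = toy_complex
    return extract_interface(complex_structure)
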