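"""Deterministic synthetic structures and feature sets.

These generators emulate what the pipeline consumes — a compact,
close-packed globular protein, a B-DNA-like double helix at
heavy-atom resolution, complexes with a known contact patch, and
labelled Gaussian feature sets for classifier tests — with no external
structure downloads.  All generators are pure functions of their
arguments, including the seed.

Design notes
------------
The protein is a jittered FCC packing clipped to a ball (folded cores
are close-packed at near-constant density) with a small accessory lobe
behind an unresolved disordered linker, as crystal structures commonly
show.  Atoms are grouped eight-per-residue with the first atom of each
residue named CA.

The DNA is two antiparallel strands with 13 pseudo-heavy-atoms per
nucleotide (phosphate, sugar and base positions filling the duplex
body), 3.4 A rise and 36 deg twist per base step, and slightly frayed
terminal base pairs.  Atom densities on both sides of the interface are
finer than the contact gap, which is what lets an alpha-shape surface
resolve burial — the same resolution regime as real crystal structures.

A toy complex nestles the helix into the protein: the protein is
carved back to a contact clearance of 4 A from every DNA atom, forming
a wrapping groove.  The contact ground truth is the 5 A heavy-atom
cutoff: deliberately a different criterion from the alpha-shape
interface it is used to judge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .features import FEATURE_NAMES, RESIDUE_ORDER
from .structure import Atom, Structure, merge

__all__ = [
    "ToyComplexSpec",
    "make_protein_blob",
    "make_dna_helix",
    "make_toy_complex",
    "make_feature_dataset",
    "CONTACT_CUTOFF",
    "CONTACT_CLEARANCE",
]

#: Ground-truth contact distance for toy complexes (A).
CONTACT_CUTOFF = 5.0

#: Heavy-atom contact clearance carved between protein and DNA (A).
CONTACT_CLEARANCE = 4.0

_DNA_NAMES = ("DA", "DT", "DG", "DC")

# nucleotide pseudo-atoms as (cylinder radius A, extra azimuth deg, extra z A):
# five backbone, three sugar, five base positions filling the duplex body
_NUCLEOTIDE_SITES = (
    ("P", 10.0, -14.0, 0.0), ("OP1", 9.9, -7.0, 0.35), ("O5'", 9.8, 0.0, 0.7),
    ("C5'", 9.7, 7.0, 1.05), ("O3'", 9.6, 14.0, 1.4),
    ("C4'", 8.6, 2.0, 0.2), ("C1'", 7.8, -6.0, 0.6), ("O4'", 7.0, 4.0, 1.0),
    ("N9", 6.0, 0.0, 0.5), ("C8", 4.9, 8.0, 0.5), ("N7", 3.8, -4.0, 0.5),
    ("C5", 2.7, 6.0, 0.5), ("C4", 1.5, 20.0, 0.5),
)

_PROTEIN_ATOM_NAMES = ("CA", "CB", "CG", "CD", "CE", "CZ", "N", "O")
_ATOMS_PER_RESIDUE = len(_PROTEIN_ATOM_NAMES)

#: terminal-base axial displacement (A); DNA ends fray
_FRAY = 2.2


def _ball_jitter(rng: np.random.Generator, n: int, rmax: float) -> np.ndarray:
    """Bounded thermal displacement: uniform in a ball of radius rmax."""
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d * (rmax * rng.random((n, 1)) ** (1.0 / 3.0))


def _fcc_ball(radius: float, rng: np.random.Generator, nn: float, jitter: float) -> np.ndarray:
    """Jittered FCC packing (nearest-neighbour distance nn) in a ball."""
    a = nn * np.sqrt(2.0)
    m = int(np.ceil(radius / a)) + 1
    basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    cells = np.array(
        [(i, j, k) for i in range(-m, m + 1) for j in range(-m, m + 1) for k in range(-m, m + 1)]
    )
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    pts += rng.uniform(-0.5, 0.5, 3) * a  # random lattice phase
    pts = pts[np.linalg.norm(pts, axis=1) <= radius - jitter]
    return pts + _ball_jitter(rng, len(pts), jitter)


def _protein_atoms(coords: np.ndarray, first_serial: int = 1, first_residue: int = 1) -> list[Atom]:
    atoms = []
    for i, c in enumerate(coords):
        res = first_residue + i // _ATOMS_PER_RESIDUE
        atoms.append(
            Atom(
                serial=first_serial + i,
                name=_PROTEIN_ATOM_NAMES[i % _ATOMS_PER_RESIDUE],
                element="C",
                residue_name=RESIDUE_ORDER[(res - 1) % 20],
                residue_id=("A", res, ""),
                coord=tuple(float(x) for x in c),
            )
        )
    return atoms


def make_protein_blob(n: int, radius: float, seed: int) -> Structure:
    """Close-packed globular pseudo-protein of ``n`` heavy atoms.

    Atoms sit on a jittered FCC lattice clipped to a ball of the given
    radius, with the lattice constant chosen to fit ``n`` atoms at
    near-constant density.  Atoms are grouped eight per residue (first
    atom CA), residue types cycle through the 20 standard amino acids,
    all on chain A.
    """
    if n < 20:
        raise ValueError("need at least 20 atoms for a protein blob")
    volume = 4.0 / 3.0 * np.pi * radius**3
    # overfill the lattice, then trim the outermost atoms to exactly n
    overfill = 1.25
    for attempt in range(6):
        rng = np.random.default_rng([seed, attempt])
        nn = (4.0 * volume / (overfill * n)) ** (1.0 / 3.0) / np.sqrt(2.0)
        jitter = min(0.3, 0.15 * nn)
        pts = _fcc_ball(radius, rng, nn, jitter)
        if len(pts) >= n:
            order = np.argsort(np.linalg.norm(pts, axis=1))
            pts = pts[np.sort(order[:n])]
            return Structure(atoms=_protein_atoms(pts), chain_class={"A": "protein"})
        overfill *= 1.2
    raise RuntimeError("could not pack the requested atom count")  # pragma: no cover


def make_dna_helix(
    n_bases: int,
    seed: int,
    rise: float = 3.4,
    twist: float = 36.0,
    radius: float = 10.0,
    jitter: float = 0.15,
    fray: float = _FRAY,
) -> Structure:
    """Two antiparallel strands at heavy-atom resolution.

    Each base carries 13 pseudo-atoms (backbone, sugar, base) placed on
    the duplex body; base i of a strand is ``rise`` A above and
    ``twist`` degrees around from base i-1.  Terminal base pairs are
    frayed by ``fray`` A along the axis.  Base identities are drawn
    from the seeded generator.
    """
    if n_bases < 4:
        raise ValueError("need at least 4 bases per strand")
    rng = np.random.default_rng(seed)
    names = rng.choice(_DNA_NAMES, size=2 * n_bases)
    scale = radius / 10.0
    raw = []
    meta = []
    for s, (chain, phase) in enumerate((("D", 0.0), ("E", 150.0))):
        for i in range(n_bases):
            fz = -fray if i == 0 else (fray if i == n_bases - 1 else 0.0)
            res_num = i + 1 if s == 0 else n_bases - i  # antiparallel numbering
            res_name = str(names[s * n_bases + i])
            for atom_name, r, da, dz in _NUCLEOTIDE_SITES:
                ang = np.deg2rad(twist * i + phase + da)
                raw.append(
                    (r * scale * np.cos(ang), r * scale * np.sin(ang), rise * i + dz + fz)
                )
                meta.append((chain, res_num, res_name, atom_name))
    coords = np.asarray(raw) + _ball_jitter(rng, len(raw), jitter)
    atoms = [
        Atom(
            serial=k + 1,
            name=m[3],
            element="P" if m[3].startswith("P") else ("O" if m[3].startswith("O") else ("N" if m[3].startswith("N") else "C")),
            residue_name=m[2],
            residue_id=(m[0], m[1], ""),
            coord=tuple(float(x) for x in coords[k]),
        )
        for k, m in enumerate(meta)
    ]
    return Structure(atoms=atoms, chain_class={"D": "dna", "E": "dna"})


@dataclass(frozen=True)
class ToyComplexSpec:
    """Conditions for one synthetic protein–DNA complex.

    ``contact_offset`` is the signed gap between the protein ball
    surface and the helix cylinder surface; negative values nestle the
    DNA into the protein, and protein atoms closer than the 4 A
    contact clearance to any DNA atom are carved away, leaving a
    wrapping groove.  The accessory lobe (``satellite_radius`` across a
    ``satellite_gap`` disordered-linker gap) is part of the protein.
    """

    n_protein_atoms: int = 1280
    protein_radius: float = 12.0     # A
    helix_rise: float = 3.4          # A per base step
    helix_twist: float = 36.0        # degrees per base step
    helix_radius: float = 10.0       # A
    n_bases: int = 10
    contact_offset: float = -9.0     # A
    satellite_radius: float = 4.0    # A
    satellite_gap: float = 5.8       # A
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_protein_atoms, self.n_bases) <= 0:
            raise ValueError("counts must be positive")
        if min(self.protein_radius, self.helix_rise, self.helix_radius) <= 0:
            raise ValueError("lengths must be positive")


def _two_lobe_coords(spec: ToyComplexSpec, rng: np.random.Generator) -> np.ndarray:
    """Main lobe with a flat face plus the satellite lobe across the linker gap."""
    volume = 4.0 / 3.0 * np.pi * spec.protein_radius**3
    nn = (4.0 * volume / spec.n_protein_atoms) ** (1.0 / 3.0) / np.sqrt(2.0)
    face = spec.protein_radius - 1.5
    main = _fcc_ball(spec.protein_radius, rng, nn, min(0.3, 0.15 * nn))
    main = main[main[:, 0] >= -face]
    sat = _fcc_ball(spec.satellite_radius, rng, nn=0.85 * nn, jitter=0.25)
    sat = sat[sat[:, 0] <= 1.5]
    sat[:, 0] += -face - spec.satellite_gap - 1.5
    return np.vstack([main, sat])


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, frozenset[int]]:
    """A groove-wrapped protein–DNA complex plus its contact ground truth.

    The helix (centred on its own centroid) is placed with its axis at
    ``protein_radius + helix_radius + contact_offset`` from the protein
    centre; protein atoms within the 4 A contact clearance of any DNA
    atom are removed.  Ground truth is the set of remaining protein
    atom indices (into the protein-only structure) within 5 A of any
    DNA atom.
    """
    rng = np.random.default_rng(spec.seed)
    pcoords = _two_lobe_coords(spec, rng)
    helix = make_dna_helix(
        spec.n_bases, spec.seed + 1, spec.helix_rise, spec.helix_twist, spec.helix_radius
    )
    hx = helix.coords()
    hx -= hx.mean(axis=0)
    hx[:, 0] += spec.protein_radius + spec.helix_radius + spec.contact_offset
    helix_moved = Structure(
        atoms=[replace(a, coord=tuple(hx[i])) for i, a in enumerate(helix.atoms)],
        chain_class=dict(helix.chain_class),
    )

    tree = cKDTree(hx)
    d, _ = tree.query(pcoords)
    pcoords = pcoords[d > CONTACT_CLEARANCE]
    d = d[d > CONTACT_CLEARANCE]
    ground_truth = frozenset(int(i) for i in np.nonzero(d <= CONTACT_CUTOFF)[0])

    protein = Structure(atoms=_protein_atoms(pcoords), chain_class={"A": "protein"})
    return merge([protein, helix_moved]), ground_truth


def make_feature_dataset(
    n_per_class: int, separation: float, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two labelled Gaussian classes in 25 dimensions.

    Class means are ``separation`` apart along the uniform direction,
    each class has unit isotropic variance; labels are +1 / -1.
    """
    if n_per_class < 10:
        raise ValueError("need at least 10 samples per class")
    rng = np.random.default_rng(seed)
    direction = np.ones(25) / 5.0  # unit vector
    shift = 0.5 * separation * direction
    x_pos = rng.normal(size=(n_per_class, 25)) + shift
    x_neg = rng.normal(size=(n_per_class, 25)) - shift
    x = np.vstack([x_pos, x_neg])
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=int), -np.ones(n_per_class, dtype=int)]
    )
    return pd.DataFrame(x, columns=list(FEATURE_NAMES)), labels
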