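"""Structural alignment and template-based complex construction.

A target protein is superposed onto each template protein with an
iterative heuristic — gapless-threading seeds, Kabsch superposition,
a TM-score-weighted residue score matrix, semi-global dynamic
programming, and re-superposition until the TM-score converges.  The
best-scoring template lends its DNA to the target: the target is
transformed into the template frame and combined with the template DNA
to form the hybrid complex whose interface is then featurised.

The TM-score is normalised by the target length L with distance scale
d0 = 1.24 (L - 15)^(1/3) - 1.8 A, clamped to >= 0.5 A for short chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .structure import Structure, merge, read_pdb

__all__ = [
    "AlignmentResult",
    "TemplateLibrary",
    "AlignConfig",
    "kabsch",
    "tm_score",
    "align",
    "align_coords",
    "scan_library",
    "build_complex",
    "representative_atoms",
]


@dataclass(frozen=True)
class AlignConfig:
    gap_penalty: float = 0.6        # per unaligned step, score units
    tol: float = 1e-4               # TM convergence tolerance
    max_iter: int = 20
    n_seed_refine: int = 3          # seeds kept for DP refinement
    min_seed_overlap: int = 4


@dataclass
class AlignmentResult:
    """Rigid transform, residue pairing and scores of one alignment."""

    rotation: np.ndarray            # (3, 3) proper orthogonal
    translation: np.ndarray         # (3,) A; maps x -> R x + t
    pairs: list[tuple[int, int]]    # (target_idx, template_idx), increasing
    tm_score: float
    seq_identity: float
    rmsd: float


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rigid transform mapping ``coords_a`` onto ``coords_b``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) enforced, so mirror images are never produced.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if len(a) < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:
        raise ValueError("rank-deficient configuration (collinear points)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((a @ rot.T + trans - b) ** 2, axis=1))))
    return rot, trans, rmsd


def tm_d0(l_target: int) -> float:
    """TM-score distance scale d0 = 1.24 (L-15)^(1/3) - 1.8 A.

    Chains of 15 residues or fewer take d0 = 0.5 A; for slightly longer
    chains, where the formula would be non-positive, d0 is floored at
    0.15 A so the score stays defined.
    """
    if l_target <= 15:
        return 0.5
    return max(0.15, 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8)


def tm_score(distances, l_target: int) -> float:
    """TM = (1/L) sum 1 / (1 + (d_i/d0)^2) over aligned residue pairs."""
    d = np.asarray(distances, dtype=float)
    if len(d) == 0:
        return 0.0
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    d0 = tm_d0(l_target)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)


def representative_atoms(structure: Structure) -> tuple[np.ndarray, list[str]]:
    """Calpha trace of the largest protein chain: (coords, residue names)."""
    per_chain: dict[str, list] = {}
    for a in structure.protein_atoms:
        if a.name == "CA":
            per_chain.setdefault(a.chain_id, []).append(a)
    if not per_chain:
        raise ValueError("no representative (CA) protein atoms")
    atoms = max(per_chain.values(), key=len)
    coords = np.array([a.coord for a in atoms])
    return coords, [a.residue_name for a in atoms]


def _semi_global_dp(score: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Semi-global alignment (free end gaps, linear gap penalty).

    Returns the strictly increasing list of aligned (i, j) index pairs.
    """
    la, lb = score.shape
    f = np.zeros((la + 1, lb + 1))
    j_idx = np.arange(lb + 1, dtype=float)
    for i in range(1, la + 1):
        # best of diagonal (match) and up (gap in target) entering column j
        cand = np.maximum(f[i - 1, :-1] + score[i - 1], f[i - 1, 1:] - gap)
        # fold in left moves with a running max:
        # f[i,j] = max_{k<=j} A[k] - gap*(j-k), A[0] = 0, A[j] = cand[j-1]
        shifted = np.empty(lb + 1)
        shifted[0] = 0.0
        shifted[1:] = cand
        f[i] = np.maximum.accumulate(shifted + gap * j_idx) - gap * j_idx
        f[i, 0] = 0.0
    # free tail: start traceback from the best cell on the last row/column
    bi, bj = la, int(np.argmax(f[la]))
    if f[int(np.argmax(f[:, lb])), lb] > f[bi, bj]:
        bi, bj = int(np.argmax(f[:, lb])), lb
    pairs: list[tuple[int, int]] = []
    i, j = bi, bj
    tie = 1e-9
    while i > 0 and j > 0:
        diag = f[i - 1, j - 1] + score[i - 1, j - 1]
        left = f[i, j - 1] - gap
        up = f[i - 1, j] - gap
        if diag >= max(left, up) - tie:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif left >= up:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return pairs


def _pair_result(xa, xb, seqs, pairs, l_target) -> AlignmentResult:
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    rot, trans, rmsd = kabsch(xa[ia], xb[ib])
    d = np.linalg.norm(xa[ia] @ rot.T + trans - xb[ib], axis=1)
    tm = tm_score(d, l_target)
    sa, sb = seqs
    ident = float(np.mean([sa[i] == sb[j] for i, j in pairs])) if pairs else 0.0
    return AlignmentResult(rot, trans, list(pairs), tm, ident, rmsd)


def align_coords(
    target_coords: np.ndarray,
    target_seq: list[str],
    template_coords: np.ndarray,
    template_seq: list[str],
    config: AlignConfig = AlignConfig(),
) -> AlignmentResult:
    """Align a target Calpha trace onto a template trace.

    Gapless-threading seeds are scored with Kabsch + TM; the best few
    are refined by iterating superposition -> TM-weighted score matrix
    -> semi-global DP until the TM-score converges.  The returned
    TM-score never falls below the best seed's.
    """
    xa = np.asarray(target_coords, dtype=float)
    xb = np.asarray(template_coords, dtype=float)
    la, lb = len(xa), len(xb)
    if la < 4 or lb < 4:
        raise ValueError("need at least 4 representative atoms on each side")
    d0 = tm_d0(la)
    seqs = (list(target_seq), list(template_seq))

    min_ov = max(config.min_seed_overlap, min(la, lb) // 2)
    seeds = []
    for off in range(-(la - min_ov), lb - min_ov + 1):
        i0, j0 = max(0, -off), max(0, off)
        n = min(la - i0, lb - j0)
        if n < min_ov:
            continue
        pairs = [(i0 + k, j0 + k) for k in range(n)]
        try:
            seeds.append(_pair_result(xa, xb, seqs, pairs, la))
        except ValueError:
            continue
    if not seeds:
        raise ValueError("no gapless seed achieves a finite score")
    seeds.sort(key=lambda r: -r.tm_score)
    best = seeds[0]

    for seed in seeds[: config.n_seed_refine]:
        current = seed
        prev_tm = current.tm_score
        for _ in range(config.max_iter):
            moved = xa @ current.rotation.T + current.translation
            dist = np.linalg.norm(moved[:, None, :] - xb[None, :, :], axis=2)
            score = 1.0 / (1.0 + (dist / d0) ** 2)
            pairs = _semi_global_dp(score, config.gap_penalty)
            if len(pairs) < 3:
                break
            result = _pair_result(xa, xb, seqs, pairs, la)
            if result.tm_score > best.tm_score:
                best = result
            if abs(result.tm_score - prev_tm) < config.tol:
                break
            prev_tm = result.tm_score
            current = result
    return best


def align(target: Structure, template: Structure, config: AlignConfig = AlignConfig()) -> AlignmentResult:
    """Align the target's protein onto a template structure's protein."""
    xa, sa = representative_atoms(target)
    xb, sb = representative_atoms(template)
    return align_coords(xa, sa, xb, sb, config)


@dataclass
class TemplateLibrary:
    """Protein–DNA complexes available as templates."""

    entries: list[tuple[str, Structure]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for eid, st in self.entries:
            if not st.dna_atoms:
                raise ValueError(f"template {eid} contains no DNA atoms")
            if not st.protein_atoms:
                raise ValueError(f"template {eid} contains no protein atoms")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_dir(cls, directory, manifest=None) -> "TemplateLibrary":
        """Load templates from a directory of PDB files.

        A TSV manifest (columns: id, path, ...) fixes the order;
        without one, ``*.pdb`` files are taken in sorted name order.
        """
        directory = Path(directory)
        entries = []
        if manifest is not None:
            for line in Path(manifest).read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("id\t"):
                    continue
                fields = line.split("\t")
                eid, rel = fields[0], fields[1]
                entries.append((eid, read_pdb(directory / rel)))
        else:
            for p in sorted(directory.glob("*.pdb")):
                entries.append((p.stem, read_pdb(p)))
        return cls(entries=entries)

    def deduplicate(self, identity_cutoff: float = 0.35, config: AlignConfig = AlignConfig()) -> "TemplateLibrary":
        """Drop templates sharing > cutoff sequence identity with an
        earlier (kept) template — the template-vs-template redundancy
        filter."""
        kept: list[tuple[str, Structure]] = []
        for eid, st in self.entries:
            redundant = False
            for _, ref in kept:
                if align(st, ref, config).seq_identity > identity_cutoff:
                    redundant = True
                    break
            if not redundant:
                kept.append((eid, st))
        return TemplateLibrary(entries=kept)


def scan_library(
    target: Structure,
    library: TemplateLibrary,
    redundancy_filter: bool = False,
    identity_cutoff: float = 0.35,
    config: AlignConfig = AlignConfig(),
) -> tuple[tuple[str, Structure], AlignmentResult]:
    """Align the target against every template; return the highest TM-score.

    With ``redundancy_filter`` set, templates whose aligned sequence
    identity with the target exceeds ``identity_cutoff`` are excluded
    (guarding against self-templates).  Ties break to earlier library
    order, so the scan is deterministic.
    """
    if len(library) == 0:
        raise ValueError("empty template library")
    best: tuple[tuple[str, Structure], AlignmentResult] | None = None
    for entry in library.entries:
        result = align(target, entry[1], config)
        if redundancy_filter and result.seq_identity > identity_cutoff:
            continue
        if best is None or result.tm_score > best[1].tm_score:
            best = (entry, result)
    if best is None:
        raise RuntimeError(
            f"all templates filtered at identity cutoff {identity_cutoff}"
        )
    return best


def build_complex(
    target: Structure,
    template_entry: Structure,
    alignment: AlignmentResult,
) -> Structure:
    """Hybrid complex: transformed target protein + template DNA.

    The target's atoms are moved into the template frame by the
    alignment's rigid transform; the template's DNA chains are copied
    with their coordinates bitwise unchanged and the template protein
    is discarded.  Colliding chain ids are re-lettered.
    """
    dna_atoms = template_entry.dna_atoms
    if not dna_atoms:
        raise ValueError("template has no DNA chains")
    rot, trans = alignment.rotation, alignment.translation
    moved = [
        replace(a, coord=tuple(rot @ np.asarray(a.coord) + trans))
        for a in target.atoms
    ]
    target_moved = Structure(
        atoms=moved, chain_class=dict(target.chain_class)
    )
    dna_chains = {a.chain_id for a in dna_atoms}
    dna_only = Structure(
        atoms=list(dna_atoms),
        chain_class={c: "dna" for c in dna_chains},
    )
    return merge([target_moved, dna_only])
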