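# alphadna

Predicting whether a protein structure binds DNA — including *unbound*
structures solved without their DNA partner — from the geometry and
composition of its (real or modelled) protein–DNA interface.

Most structure-based predictors of DNA binding work on bound complexes.
This package implements the complementary route for unbound proteins: a
target structure is scanned against a library of known protein–DNA
complexes with a TM-score structural alignment, docked onto the best
template's DNA, and the resulting interface is characterised with an
alpha-shape (Delaunay-filtration) surface model.  Each structure is
summarised by a 25-dimensional descriptor

```
x = (residue index [20], TM-score, convex index, concave index,
     mean connectivity, interface atom index)
```

where the residue index is the percentage of each amino-acid type among
interface atoms, the curvature indices average the per-atom
κ = cos(Ω/4) ∈ [−1 (cleft), +1 (knob)] of the interface solid angles Ω,
mean connectivity counts alpha-shape boundary edges per interface atom,
and the interface atom index is |interface| / |complex atoms|.  A
radial-kernel SVM (C = 0.1, γ = 0.01) separates DNA-binding (+1) from
non-binding (−1) structures.

The interface itself follows the buried-surface rule: an interface atom
is surface in the alpha shape of the protein alone but absent from the
surface of the full complex — i.e. buried by the DNA.  The alpha value
is selected automatically as the smallest making the complex one solid
component covering every atom (capped at twice the protein's own
scale), and Ω is computed per vertex by summing Van Oosterom–Strackee
solid angles of incident alpha-complex tetrahedra.

Everything is testable offline: a synthetic-structure module generates
close-packed globular pseudo-proteins, B-DNA-like double helices at
heavy-atom resolution, groove-wrapped complexes with a known contact
patch, and labelled feature sets.

## Worked example

```python
import alphadna as ad

# a synthetic protein–DNA complex with a known contact patch
complex_structure, contacts = ad.make_toy_complex(ad.ToyComplexSpec(seed=0))

iface = ad.extract_interface(complex_structure)
print(len(iface), sorted(iface.provenance.items()))
# 75 [('alpha_complex', 12.76...), ('alpha_protein', 12.76...), ('alpha_shared', 12.76...)]

from alphadna.pipeline import featurize_bound
fv = featurize_bound(complex_structure)
print(fv.tm_score, round(fv.convex_index, 3), round(fv.concave_index, 3),
      round(fv.mean_connectivity, 2), round(fv.interface_atom_index, 4))
# 1.0 0.082 -0.329 5.93 0.0645
```

75 of the protein's atoms are buried by the DNA; the shared alpha of
12.76 Å² is the complex's automatic one-component value (here equal to
the protein's own, since the same accessory-lobe linker gap sets both).  The feature
tail says the interface is mildly concave overall (concave index
−0.33), each interface atom touches about six other surface atoms, and
the interface is 6.5 % of the complex.  For an unbound target the same
vector is produced by `featurize_unbound(target, library)`, with the
TM-score slot taken from the winning template alignment.

A thin CLI covers the same operations
(`alphadna featurize | scan | build-complex | train | predict |
evaluate | make-fixtures`).

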