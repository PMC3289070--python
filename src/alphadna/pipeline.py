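"""End-to-end orchestration: featurise, train, predict, evaluate.

Bound complexes are featurised directly from their own interface and
carry TM-score 1.0 (they are their own template).  Unbound targets are
scanned against the template library, docked onto the best template's
DNA, and featurised from the hybrid complex with the alignment's
TM-score.  Batch runs skip-and-record individual failures rather than
aborting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .align import AlignConfig, TemplateLibrary, build_complex, scan_library
from .interface import extract_interface
from .metrics import ConfusionMatrix, confusion_from_predictions, report_table
from .structure import Structure, read_pdb
from .svm import SvmConfig, TrainedModel, save_model, train

__all__ = [
    "RunConfig",
    "featurize_bound",
    "featurize_unbound",
    "run_train",
    "run_evaluate",
]

logger = logging.getLogger("alphadna")


@dataclass
class RunConfig:
    """Settings shared by the pipeline commands."""

    svm: SvmConfig = field(default_factory=SvmConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    redundancy_filter: bool = False
    identity_cutoff: float = 0.35
    bound_tm_score: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_cutoff < 1.0):
            raise ValueError("identity_cutoff must be in (0, 1)")


def featurize_bound(
    complex_structure: Structure, tm_score: float = 1.0
) -> feat.FeatureVector:
    """25-dim descriptor of a bound protein–DNA complex.

    The interface comes straight from the complex; the TM-score slot
    defaults to 1.0 (the structure is its own template).
    """
    interface = extract_interface(complex_structure)
    return feat.assemble(
        feat.residue_index(interface),
        tm_score,
        feat.curvature_index(interface),
        feat.mean_connectivity(interface),
        feat.interface_atom_index(interface),
    )


def featurize_unbound(
    target: Structure,
    library: TemplateLibrary,
    config: RunConfig = RunConfig(),
) -> feat.FeatureVector:
    """25-dim descriptor of an unbound target via template docking.

    Scans the library, builds the hybrid complex with the best
    template's DNA, and featurises its interface; the TM-score slot is
    the winning alignment's score.
    """
    (entry_id, template), alignment = scan_library(
        target,
        library,
        redundancy_filter=config.redundancy_filter,
        identity_cutoff=config.identity_cutoff,
        config=config.align,
    )
    logger.info("best template %s: TM=%.4f", entry_id, alignment.tm_score)
    hybrid = build_complex(target, template, alignment)
    return featurize_bound(hybrid, tm_score=alignment.tm_score)


def _load_structures(source) -> list[tuple[str, Structure]]:
    if isinstance(source, (str, Path)):
        return [(p.stem, read_pdb(p)) for p in sorted(Path(source).glob("*.pdb"))]
    out = []
    for i, item in enumerate(source):
        if isinstance(item, tuple):
            out.append((str(item[0]), item[1]))
        else:
            out.append((f"structure_{i}", item))
    return out


def _featurize_any(
    name: str, st: Structure, library: TemplateLibrary | None, config: RunConfig
) -> feat.FeatureVector:
    if st.dna_atoms:
        return featurize_bound(st, tm_score=config.bound_tm_score)
    if library is None:
        raise ValueError(f"{name}: unbound structure but no template library given")
    return featurize_unbound(st, library, config)


def run_train(
    positives,
    negatives,
    library: TemplateLibrary | None,
    config: RunConfig = RunConfig(),
    model_path=None,
    feature_csv=None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Featurise both classes, fit the SVM, report the training confusion.

    ``positives`` / ``negatives`` are directories of PDB files or
    sequences of (id, Structure).  Returns the model and a report with
    per-structure features, labels and training predictions.
    """
    rows: list[dict] = []
    for label, source in ((1, positives), (-1, negatives)):
        items = _load_structures(source)
        if not items:
            raise ValueError("each class needs at least one structure")
        for name, st in items:
            try:
                fv = _featurize_any(name, st, library, config)
            except Exception as exc:
                logger.warning("skipping %s: %s", name, exc)
                continue
            rows.append({"id": name, "label": label, "vector": fv})
    if not rows:
        raise ValueError("no structure could be featurised")
    x = np.vstack([r["vector"].to_array() for r in rows])
    y = np.array([r["label"] for r in rows])
    model = train(x, y, config.svm)
    pred, decision = model.predict(x)
    report = pd.DataFrame(x, columns=list(feat.FEATURE_NAMES))
    report.insert(0, "id", [r["id"] for r in rows])
    report["label"] = y
    report["prediction"] = pred
    report["decision_value"] = decision
    if feature_csv is not None:
        report.to_csv(feature_csv, index=False)
    if model_path is not None:
        save_model(model, model_path)
    cm = confusion_from_predictions(y, pred)
    logger.info("training confusion: %s", cm)
    return model, report


def run_evaluate(predictions: dict, truth: dict, method: str = "SC") -> pd.DataFrame:
    """Benchmark-style report row from id-aligned +1/-1 label maps."""
    if not predictions:
        raise ValueError("no predictions to evaluate")
    if set(predictions) != set(truth):
        raise ValueError("prediction and truth ids do not match")
    ids = sorted(predictions)
    cm = confusion_from_predictions(
        [truth[i] for i in ids], [predictions[i] for i in ids]
    )
    return report_table({method: cm})


def evaluate_counts(tp: int, fp: int, tn: int, fn: int, method: str = "SC") -> pd.DataFrame:
    """Report row directly from confusion counts."""
    return report_table({method: ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)})
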