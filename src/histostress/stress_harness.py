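"""The stress test: baseline filtering, severity sweeps, metrics, overlap analysis.

A plug-in classifier scores patches into three classes (benign glandular,
benign nonglandular, tumor).  The harness first restricts the test set to
patches the classifier gets right on clean input ("baseline filtering"), so
the pre-artifact F1 is exactly 1.0 and any later drop is attributable to the
artifact.  It then sweeps one artifact family over its severity ladder,
applying the artifact to every patch (with per-patch seeded randomness),
re-classifying, and recording tumor-vs-rest confusion counts, precision,
recall and F1 per level, along with the set of misclassified patch ids for
cross-artifact overlap (Venn) analysis.

Metrics use tumor as the positive class: precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R); a metric whose denominator is zero is
defined as 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import laplace
from skimage.measure import label as cc_label

from .degradation_artifacts import apply_focus, apply_jpeg
from .errors import ClassifierContractError
from .geometric_artifacts import ElasticSpec, apply_elastic, apply_flip, apply_rotation
from .image_core import RGBPatch
from .overlay_artifacts import (
    TemplateBank,
    apply_dark_spots,
    apply_fingerprint,
    apply_squamous,
    apply_thread,
)
from .photometric_artifacts import adjust_brightness, adjust_contrast
from .stain_normalization import StainProfile, stain_transfer, standardize_brightness
from .synthetic_data import (
    REFERENCE_STAIN_MATRIX,
    TISSUE_CLASSES,
    LabeledPatch,
    generate_patch,
)

__all__ = [
    "CLASS_ORDER",
    "PredictionRecord",
    "ConfusionSummary",
    "DegradationCurve",
    "PatchClassifier",
    "ToyClassifier",
    "classify",
    "compute_metrics",
    "filter_baseline",
    "apply_artifact",
    "run_stress_test",
    "breakdown_by_class",
    "misclassification_overlap",
    "report",
    "ARTIFACT_NAMES",
]

#: Fixed order of the per-class probability vector in the plug-in contract.
CLASS_ORDER = ("GLAND", "NONGLAND", "TUMOR")

#: Artifact families the sweep dispatcher understands.
ARTIFACT_NAMES = (
    "identity",
    "focus",
    "jpeg",
    "flip",
    "rotation",
    "elastic",
    "brightness",
    "contrast",
    "dark_spots",
    "thread",
    "squamous",
    "fingerprint",
    "staining",
)


class PatchClassifier(Protocol):
    """Plug-in contract: per-class probabilities in :data:`CLASS_ORDER`."""

    def predict_proba(self, patches: Sequence[RGBPatch]) -> np.ndarray:
        """Return an (n, 3) array of probabilities for (GLAND, NONGLAND, TUMOR)."""
        ...


@dataclass(frozen=True)
class PredictionRecord:
    """One classifier output: predicted class is the argmax probability."""

    patch_id: str
    true_class: str
    predicted_class: str
    probabilities: tuple[float, float, float]


@dataclass(frozen=True)
class ConfusionSummary:
    """Tumor-vs-rest confusion counts and derived metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class DegradationCurve:
    """Per-severity-level confusion summaries for one artifact family."""

    artifact: str
    levels: list[object] = field(default_factory=list)
    summaries: list[ConfusionSummary] = field(default_factory=list)
    misclassified: list[set[str]] = field(default_factory=list)

    def f1_values(self) -> list[float]:
        return [s.f1 for s in self.summaries]


# ---------------------------------------------------------------------------
# classification and metrics
# ---------------------------------------------------------------------------


def classify(
    classifier: PatchClassifier,
    patches: Sequence[RGBPatch],
    true_classes: Sequence[str] | None = None,
) -> list[PredictionRecord]:
    """Score patches and validate the plug-in contract.

    ``true_classes`` (parallel to ``patches``) fills the records'
    ground-truth field; when omitted it is left empty.
    """
    if len(patches) == 0:
        return []
    probs = np.asarray(classifier.predict_proba(list(patches)), dtype=np.float64)
    if probs.shape != (len(patches), 3):
        raise ClassifierContractError(
            f"expected probabilities of shape ({len(patches)}, 3), got {probs.shape}"
        )
    if probs.min() < 0 or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ClassifierContractError(
            "probabilities must be nonnegative and sum to 1 per patch"
        )
    records = []
    for i, patch in enumerate(patches):
        true = true_classes[i] if true_classes is not None else ""
        records.append(
            PredictionRecord(
                patch_id=patch.id,
                true_class=true,
                predicted_class=CLASS_ORDER[int(np.argmax(probs[i]))],
                probabilities=tuple(probs[i]),
            )
        )
    return records


def compute_metrics(records: Sequence[PredictionRecord]) -> ConfusionSummary:
    """Tumor-vs-rest confusion counts over a set of predictions."""
    if len(records) == 0:
        raise ValueError("cannot compute metrics on an empty record list")
    tp = fp = fn = tn = 0
    for r in records:
        if r.true_class == "TUMOR":
            if r.predicted_class == "TUMOR":
                tp += 1
            else:
                fn += 1
        else:
            if r.predicted_class == "TUMOR":
                fp += 1
            else:
                tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def filter_baseline(
    dataset: Sequence[LabeledPatch], classifier: PatchClassifier
) -> list[LabeledPatch]:
    """Retain only patches the classifier predicts correctly on clean input.

    On the retained set the baseline F1 is 1.0 by construction.
    """
    if len(dataset) == 0:
        return []
    records = classify(
        classifier, [lp.patch for lp in dataset], [lp.true_class for lp in dataset]
    )
    return [
        lp for lp, r in zip(dataset, records) if r.predicted_class == lp.true_class
    ]


def breakdown_by_class(records: Sequence[PredictionRecord]) -> dict[str, int]:
    """FP/FN sources by true tissue class.

    Returns counts of benign glandular and nonglandular patches predicted
    tumor (the FP sources) and tumor patches predicted benign (FN); the FP
    counts sum to :meth:`ConfusionSummary.fp` and ``fn_tumor`` equals
    :meth:`ConfusionSummary.fn`.
    """
    out = {"fp_gland": 0, "fp_nongland": 0, "fn_tumor": 0}
    for r in records:
        if r.true_class == "GLAND" and r.predicted_class == "TUMOR":
            out["fp_gland"] += 1
        elif r.true_class == "NONGLAND" and r.predicted_class == "TUMOR":
            out["fp_nongland"] += 1
        elif r.true_class == "TUMOR" and r.predicted_class != "TUMOR":
            out["fn_tumor"] += 1
    return out


def misclassification_overlap(
    sets: dict[str, set[str]],
) -> dict[tuple[str, ...], int]:
    """Counts of every region of the Venn partition of 2..5 named id sets.

    The key is the sorted tuple of set names a region belongs to exactly;
    region counts sum to the size of the union.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 5:
        raise ValueError("overlap analysis needs between 2 and 5 sets")
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for inside in combinations(names, k):
            ids = set.intersection(*(sets[n] for n in inside))
            for other in names:
                if other not in inside:
                    ids = ids - sets[other]
            regions[inside] = len(ids)
    return regions


# ---------------------------------------------------------------------------
# artifact dispatch and the severity sweep
# ---------------------------------------------------------------------------


def _stable_rng(seed: int, patch_id: str, level: object) -> np.random.Generator:
    """Per-(seed, patch, level) generator so sweeps are reproducible and
    patch-aligned across artifacts (needed for overlap analysis)."""
    return np.random.default_rng(
        [
            int(seed) % (2**31),
            zlib.crc32(patch_id.encode()) % (2**31),
            zlib.crc32(str(level).encode()) % (2**31),
        ]
    )


def apply_artifact(
    patch: RGBPatch,
    artifact: str,
    level: object,
    rng: np.random.Generator,
    templates: TemplateBank | None = None,
    schemes: dict[str, StainProfile] | None = None,
) -> RGBPatch:
    """Apply one severity rung of a named artifact family to a patch.

    The meaning of ``level`` depends on the family: focus level (int), JPEG
    quality (int), flip axis, rotation quarter-turns (or ``"random"``),
    elastic grid size (px), brightness/contrast delta (fraction), dark spots
    ``(spot_type, count)``, thread variant (or ``"random"``), squamous count,
    staining scheme id.  Overlay families need a :class:`TemplateBank`;
    ``staining`` needs the scheme-profile dict.
    """
    if artifact == "identity":
        return patch.with_pixels(patch.pixels.copy())
    if artifact == "focus":
        return apply_focus(patch, int(level))
    if artifact == "jpeg":
        return apply_jpeg(patch, int(level))
    if artifact == "flip":
        return apply_flip(patch, str(level))
    if artifact == "rotation":
        turns = None if level == "random" else int(level)
        return apply_rotation(patch, turns, rng=rng)
    if artifact == "elastic":
        spec = ElasticSpec(grid_size=int(level), seed=int(rng.integers(0, 2**31 - 1)))
        return apply_elastic(patch, spec)
    if artifact == "brightness":
        return adjust_brightness(patch, float(level))
    if artifact == "contrast":
        return adjust_contrast(patch, float(level))
    if artifact in {"dark_spots", "thread", "squamous", "fingerprint"}:
        if templates is None:
            raise ValueError(f"artifact {artifact!r} needs a template bank")
        if artifact == "dark_spots":
            spot_type, count = level  # type: ignore[misc]
            return apply_dark_spots(patch, templates, int(spot_type), int(count), rng)
        if artifact == "thread":
            variant = None if level == "random" else int(level)
            return apply_thread(patch, templates, variant, rng)
        if artifact == "squamous":
            return apply_squamous(patch, templates, int(level), rng)
        return apply_fingerprint(patch, templates, rng)
    if artifact == "staining":
        if schemes is None or str(level) not in schemes:
            raise ValueError(f"staining artifact needs a scheme profile for {level!r}")
        return stain_transfer(patch, schemes[str(level)])
    raise ValueError(f"unknown artifact {artifact!r}")


def run_stress_test(
    dataset: Sequence[LabeledPatch],
    classifier: PatchClassifier,
    artifact: str,
    ladder: Sequence[object],
    seed: int = 0,
    normalize_first: bool = False,
    templates: TemplateBank | None = None,
    schemes: dict[str, StainProfile] | None = None,
    reference_profile: StainProfile | None = None,
) -> DegradationCurve:
    """Sweep one artifact family over its severity ladder.

    ``dataset`` must already be baseline-filtered; the baseline level (F1 =
    1.0 by construction) is prepended to the curve.  With
    ``normalize_first`` every patch is brightness-standardized and, when a
    ``reference_profile`` is given, stain-transferred to it before the
    artifact is applied — the standard preprocessing of a stain-normalized
    classifier.  The staining sweep itself must run on unnormalized patches.
    """
    if artifact not in ARTIFACT_NAMES:
        raise ValueError(f"unknown artifact {artifact!r}")
    if len(ladder) == 0:
        raise ValueError("severity ladder must contain at least one level")
    if artifact == "staining" and normalize_first:
        raise ValueError("the staining sweep runs on unnormalized patches")

    patches = [lp.patch for lp in dataset]
    if normalize_first:
        normalized = []
        for p in patches:
            q = standardize_brightness(p)
            if reference_profile is not None:
                q = stain_transfer(q, reference_profile)
            normalized.append(q)
        patches = normalized
    true_classes = [lp.true_class for lp in dataset]
    n_tumor = sum(1 for t in true_classes if t == "TUMOR")

    curve = DegradationCurve(artifact=artifact)
    curve.levels.append("baseline")
    curve.summaries.append(
        ConfusionSummary(tp=n_tumor, fp=0, fn=0, tn=len(dataset) - n_tumor)
    )
    curve.misclassified.append(set())

    for level in ladder:
        perturbed = [
            apply_artifact(
                p, artifact, level, _stable_rng(seed, p.id, level), templates, schemes
            )
            for p in patches
        ]
        records = classify(classifier, perturbed, true_classes)
        curve.levels.append(level)
        curve.summaries.append(compute_metrics(records))
        curve.misclassified.append(
            {r.patch_id for r in records if r.predicted_class != r.true_class}
        )
    return curve


def report(curves: Sequence[DegradationCurve], out_dir: str | Path) -> list[Path]:
    """Write one CSV and one F1-vs-severity plot per curve; return the paths."""
    if len(curves) == 0:
        raise ValueError("need at least one degradation curve to report")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for curve in curves:
        rows = [
            {
                "level": str(lv),
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
                "tn": s.tn,
                "precision": s.precision,
                "recall": s.recall,
                "f1": s.f1,
            }
            for lv, s in zip(curve.levels, curve.summaries)
        ]
        csv_path = out_dir / f"{curve.artifact}.csv"
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        written.append(csv_path)

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(range(len(curve.levels)), curve.f1_values(), marker="o")
        ax.set_xticks(range(len(curve.levels)))
        ax.set_xticklabels([str(lv) for lv in curve.levels], rotation=45, ha="right")
        ax.set_xlabel("severity level")
        ax.set_ylabel("F1 score (tumor vs rest)")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(curve.artifact)
        fig.tight_layout()
        png_path = out_dir / f"{curve.artifact}.png"
        fig.savefig(png_path, dpi=110)
        plt.close(fig)
        written.append(png_path)
    return written


# ---------------------------------------------------------------------------
# bundled toy classifier
# ---------------------------------------------------------------------------

_LUMA = np.array([0.299, 0.587, 0.114])


def toy_features(patch: RGBPatch) -> np.ndarray:
    """Stain-deconvolved texture features the toy classifier scores.

    Four numbers per patch: nucleus-blob count (connected components of the
    hematoxylin concentration map above 0.5, minimum area 4 px), near-white
    area fraction (lumina / fat / background), edge energy (mean squared
    Laplacian of luma), and mean eosin concentration.  Blob count and edge
    energy are genuinely blur-sensitive, so defocus and compression move
    patches across class boundaries rather than leaving the features fixed.
    """
    from .stain_normalization import concentrations

    conc = concentrations(patch, REFERENCE_STAIN_MATRIX)
    h_map = conc[0].reshape(patch.height, patch.width)
    blobs = cc_label(h_map > 0.5, connectivity=2)
    counts = np.bincount(blobs.ravel())
    n_blobs = int(np.sum(counts[1:] >= 4))
    luma = patch.pixels.astype(np.float64) @ _LUMA
    white_fraction = float(np.mean(luma > 240))
    edge_energy = float(np.mean(laplace(luma / 255.0) ** 2))
    eosin_mean = float(conc[1].mean())
    return np.array([n_blobs, white_fraction, edge_energy, eosin_mean])


class ToyClassifier:
    """Nearest-centroid classifier on z-scored :func:`toy_features`.

    Centroids and feature scales are calibrated on a clean synthetic batch,
    which gives 100% accuracy on clean patches (the precondition for
    baseline filtering) while remaining honestly sensitive to blur,
    compression and stain distortion.  Probabilities are a softmax over
    negative squared centroid distances.
    """

    def __init__(self) -> None:
        self.centroids_: np.ndarray | None = None
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, calibration: Sequence[LabeledPatch]) -> "ToyClassifier":
        feats = np.array([toy_features(lp.patch) for lp in calibration])
        labels = np.array([lp.true_class for lp in calibration])
        self.mean_ = feats.mean(axis=0)
        self.scale_ = np.maximum(feats.std(axis=0), 1e-9)
        z = (feats - self.mean_) / self.scale_
        self.centroids_ = np.array(
            [z[labels == cls].mean(axis=0) for cls in CLASS_ORDER]
        )
        return self

    @classmethod
    def trained(cls, seed: int = 0, n_per_class: int = 16) -> "ToyClassifier":
        """Calibrate on a freshly generated clean batch (seeded)."""
        rng = np.random.default_rng([seed, 2654435769 % (2**31)])
        batch = [
            generate_patch(tissue, int(s))
            for tissue in TISSUE_CLASSES
            for s in rng.integers(0, 2**31 - 1, size=n_per_class)
        ]
        return cls().fit(batch)

    def predict_proba(self, patches: Sequence[RGBPatch]) -> np.ndarray:
        if self.centroids_ is None:
            raise RuntimeError("classifier is not fitted")
        feats = np.array([toy_features(p) for p in patches]).reshape(-1, 4)
        z = (feats - self.mean_) / self.scale_
        d2 = ((z[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        logits = -0.5 * d2
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)
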