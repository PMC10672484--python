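"""Two-stage landmark pipeline: segment, binarize, detect, measure.

The pipeline mirrors the structure of a segmentation-first landmark
detector: stage one produces per-bone instance masks, which are flattened
to a pure 0/255 binary image; stage two locates the four AcI landmarks
from that binary product only (never the raw radiograph); geometry then
turns the landmarks into per-side acetabular index angles and a
threshold-based DDH call.

Detector backends are pluggable behind a two-method contract
(``segment`` + ``detect``).  Shipped backends:

* ``classical`` — thresholding/morphology segmentation plus rule-based
  corner detection on the ilium masks; works on the synthetic phantoms
  and makes the whole pipeline testable without training.
* ``oracle`` — returns stored ground truth; used to validate pipeline
  plumbing (all error metrics must be exactly zero).
* ``neural`` — a declared interface for Mask R-CNN / Keypoint R-CNN
  style detectors.  The config schema carries the standard training
  hyperparameters, but no trained weights ship with the package, so
  instantiating it raises.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import (
    BackendError,
    EmptyInputError,
    MissingSideError,
    NoComponentsError,
    PipelineStageError,
)
from .geometry import (
    AcIMeasurement,
    DiagnosisResult,
    LandmarkSet,
    Point2D,
    classify_ddh,
    compute_aci,
)
from .masks import BONES, InstanceMasks, render_binary_mask
from .metrics import (
    ErrorTable,
    aggregate_errors,
    landmark_error_record,
    rmse,
)

__all__ = [
    "PipelineConfig",
    "CaseReport",
    "DetectorBackend",
    "ClassicalBackend",
    "OracleBackend",
    "NeuralBackend",
    "get_backend",
    "segment_classical",
    "detect_landmarks_classical",
    "run_pipeline",
    "evaluate_pipeline",
    "EvaluationReport",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline hyperparameters.

    The first six fields are the detector-training hyperparameters of a
    Keypoint R-CNN style backend (kept as configuration so a neural
    backend can consume them); ``backend`` and ``ddh_threshold_deg``
    control inference.
    """

    rpn_batch_size: int = 256
    roi_heads_batch_size: int = 128
    base_learning_rate: float = 0.00075
    max_iteration: int = 2500
    weight_decay: float = 0.0001
    batch_size: int = 4
    backend: str = "classical"
    ddh_threshold_deg: float = 30.0

    def __post_init__(self):
        for name in ("rpn_batch_size", "roi_heads_batch_size", "max_iteration", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("base_learning_rate", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat YAML (or JSON) mapping of the field names."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CaseReport:
    """Everything one pipeline run produced for one image."""

    landmarks: LandmarkSet
    masks: InstanceMasks
    binary_mask: np.ndarray
    angles: AcIMeasurement
    diagnosis: DiagnosisResult
    backend: str
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "landmarks": {n: list(p) for n, p in zip(("RU", "RD", "LU", "LD"), self.landmarks)},
                "angles": {
                    "right_deg": round(self.angles.right_deg, 3),
                    "left_deg": round(self.angles.left_deg, 3),
                },
                "diagnosis": {
                    "right": self.diagnosis.right_label,
                    "left": self.diagnosis.left_label,
                    "overall": self.diagnosis.overall_label,
                    "threshold_deg": self.diagnosis.threshold_deg,
                },
                "backend": self.backend,
                "timings": self.timings,
            },
            sort_keys=True,
        )


@runtime_checkable
class DetectorBackend(Protocol):
    """Contract every detector backend satisfies; backends are interchangeable."""

    name: str

    def segment(self, image: np.ndarray) -> InstanceMasks: ...

    def detect(self, masks: InstanceMasks) -> LandmarkSet: ...


def segment_classical(image: np.ndarray, min_area: int = 60) -> InstanceMasks:
    """Threshold + morphology instance segmentation for phantom images.

    Otsu global threshold, binary opening (radius-1 disk), small-object
    removal, connected components; components are split left/right of the
    foreground centroid and, per side, assigned top-to-bottom to ilium,
    middle bone, femur.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("segment_classical expects a single-channel image")
    # threshold on the native (integer) dtype: exact histogram bins keep the
    # Otsu cut on the correct side of the background mode's top value
    t = threshold_otsu(img)
    fg = img > t
    fg = morphology.opening(fg, morphology.disk(1))
    labels = measure.label(fg)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    if not props:
        raise NoComponentsError("no foreground components after thresholding")
    mid_x = float(np.mean([p.centroid[1] for p in props]))
    masks = InstanceMasks(shape=img.shape)
    for side, keep in (("right", lambda x: x < mid_x), ("left", lambda x: x >= mid_x)):
        comps = [p for p in props if keep(p.centroid[1])]
        comps = sorted(comps, key=lambda p: p.area, reverse=True)[:3]
        comps.sort(key=lambda p: p.centroid[0])  # top to bottom
        for bone, comp in zip(BONES, comps):
            masks.set(bone, side, labels == comp.label)
    return masks


def _extreme_column_point(mask: np.ndarray, lateral_sign: int) -> tuple[Point2D, Point2D]:
    """(U, D) from one ilium mask via extreme-column rules.

    D (triradiate proxy) is the mean pixel of the medial-most occupied
    column; U (acetabular roof proxy) the mean pixel of the lateral-most
    column.  For the right side (image left half) lateral is -x, medial
    +x; mirrored on the left.  Both rules are translation-equivariant and
    move by at most ~1 px under mask dilation by 1 px.
    """
    ys, xs = np.nonzero(mask)
    lateral_col = xs.min() if lateral_sign < 0 else xs.max()
    medial_col = xs.max() if lateral_sign < 0 else xs.min()
    u = Point2D(float(lateral_col), float(ys[xs == lateral_col].mean()))
    d = Point2D(float(medial_col), float(ys[xs == medial_col].mean()))
    return u, d


def detect_landmarks_classical(masks: InstanceMasks) -> LandmarkSet:
    """Rule-based landmark detection on the ilium masks.

    Per side, the triradiate proxy D is the medial extreme of the ilium
    mask and the roof proxy U its lateral extreme (the phantom ilium is
    built so its inferior edge is the roof line, with those corners at
    the true landmarks).
    """
    points = {}
    for side, lateral_sign, u_name, d_name in (
        ("right", -1, "RU", "RD"),
        ("left", +1, "LU", "LD"),
    ):
        ilium = masks.get("ilium", side)
        if ilium is None or not ilium.any():
            raise MissingSideError(f"no {side} ilium mask; cannot place landmarks")
        points[u_name], points[d_name] = _extreme_column_point(ilium, lateral_sign)
    return LandmarkSet(**points)


class ClassicalBackend:
    """Deterministic thresholding + rule-based detector backend."""

    name = "classical"

    def __init__(self, min_area: int = 60):
        self.min_area = min_area

    def segment(self, image: np.ndarray) -> InstanceMasks:
        return segment_classical(image, min_area=self.min_area)

    def detect(self, masks: InstanceMasks) -> LandmarkSet:
        return detect_landmarks_classical(masks)


class OracleBackend:
    """Returns stored ground truth; validates pipeline plumbing."""

    name = "oracle"

    def __init__(self, masks: InstanceMasks, landmarks: LandmarkSet):
        self._masks = masks
        self._landmarks = landmarks

    def segment(self, image: np.ndarray) -> InstanceMasks:
        return self._masks

    def detect(self, masks: InstanceMasks) -> LandmarkSet:
        return self._landmarks


class NeuralBackend:
    """Interface stub for Mask R-CNN / Keypoint R-CNN style detectors.

    Training and weights are outside the scope of this package; the
    class documents the contract a trained backend must satisfy and
    consumes the same :class:`PipelineConfig` hyperparameters.
    """

    name = "neural-external"

    def __init__(self, config: PipelineConfig):
        raise BackendError(
            "the neural backend requires externally trained weights; "
            "use 'classical' or 'oracle'"
        )


AVAILABLE_BACKENDS = ("classical", "oracle", "neural-external")


def get_backend(name: str, config: PipelineConfig | None = None, case=None) -> DetectorBackend:
    """Instantiate a backend by name ('oracle' needs a ground-truth case)."""
    if name == "classical":
        return ClassicalBackend()
    if name == "oracle":
        if case is None:
            raise BackendError("oracle backend needs a ground-truth case")
        return OracleBackend(case.masks, case.landmarks)
    if name == "neural-external":
        return NeuralBackend(config or PipelineConfig())
    raise BackendError(f"unknown backend {name!r}; available: {', '.join(AVAILABLE_BACKENDS)}")


def run_pipeline(
    image: np.ndarray,
    backend: DetectorBackend,
    config: PipelineConfig = PipelineConfig(),
) -> CaseReport:
    """Run segment -> binary mask -> detect -> angles -> diagnosis.

    The landmark detector only ever sees the segmentation product, never
    the raw image.  Stage failures are re-raised as
    :class:`PipelineStageError` carrying the stage name.
    """
    timings: dict[str, float] = {}

    def _stage(stage_name, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except Exception as exc:  # noqa: BLE001 - tagged and re-raised
            raise PipelineStageError(stage_name, exc) from exc
        timings[stage_name] = time.perf_counter() - t0
        return out

    masks = _stage("segment", backend.segment, image)
    binary = _stage("binary_mask", render_binary_mask, masks)
    landmarks = _stage("detect", backend.detect, masks)
    angles = _stage("geometry", compute_aci, landmarks)
    diagnosis = _stage("diagnose", classify_ddh, angles, config.ddh_threshold_deg)
    return CaseReport(
        landmarks=landmarks,
        masks=masks,
        binary_mask=binary,
        angles=angles,
        diagnosis=diagnosis,
        backend=backend.name,
        timings=timings,
    )


@dataclass
class EvaluationReport:
    """Whole-dataset evaluation: RMSE plus pixel/AcI tables and diagnoses."""

    rmse: float
    pixel_table: ErrorTable
    aci_table: ErrorTable
    confusion: dict[str, int]  # keys tp/fp/fn/tn; positive class = ddh
    n_cases: int
    backend: str
    per_case: list[dict] = field(default_factory=list)

    @property
    def diagnosis_accuracy(self) -> float:
        total = sum(self.confusion.values())
        return (self.confusion["tp"] + self.confusion["tn"]) / total if total else float("nan")

    def summary(self) -> dict:
        px, ac = self.pixel_table.row("Avg"), self.aci_table.row("Avg")
        return {
            "backend": self.backend,
            "n_cases": self.n_cases,
            "rmse": round(self.rmse, 3),
            "pixel_error_mean": round(px["mean"], 3),
            "pixel_error_std": round(px["std"], 3),
            "aci_error_mean": round(ac["mean"], 3),
            "aci_error_std": round(ac["std"], 3),
            "confusion": self.confusion,
            "diagnosis_accuracy": round(self.diagnosis_accuracy, 3),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pixel_table.to_csv(out / "pixel_error.csv")
        self.aci_table.to_csv(out / "aci_error.csv")
        (out / "summary.json").write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")
        (out / "per_case.json").write_text(json.dumps(self.per_case, indent=2, sort_keys=True) + "\n")


def evaluate_pipeline(
    cases,
    backend: str | DetectorBackend = "classical",
    config: PipelineConfig = PipelineConfig(),
) -> EvaluationReport:
    """Run the pipeline over ground-truthed cases and score it.

    ``cases`` is a sequence of objects exposing ``image``, ``masks``,
    ``landmarks``, ``truth`` and ``label`` (e.g. synthetic phantoms).
    ``backend`` may be a backend instance or one of the names in
    :data:`AVAILABLE_BACKENDS`; the oracle backend is re-bound to each
    case's ground truth.
    """
    cases = list(cases)
    if not cases:
        raise EmptyInputError("evaluate_pipeline requires at least one case")
    records, preds, truths, per_case = [], [], [], []
    confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    backend_name = backend if isinstance(backend, str) else backend.name
    for i, case in enumerate(cases):
        b = get_backend(backend, config, case=case) if isinstance(backend, str) else backend
        report = run_pipeline(case.image, b, config)
        case_id = getattr(case, "case_id", "") or f"case_{i:04d}"
        records.append(landmark_error_record(case_id, report.landmarks, case.landmarks))
        preds.append(report.landmarks)
        truths.append(case.landmarks)
        predicted_ddh = report.diagnosis.overall_label == "ddh"
        actual_ddh = case.label == "ddh"
        key = ("t" if predicted_ddh == actual_ddh else "f") + ("p" if predicted_ddh else "n")
        confusion[key] += 1
        per_case.append(
            {
                "case_id": case_id,
                "label": case.label,
                "predicted": report.diagnosis.overall_label,
                "right_deg": round(report.angles.right_deg, 3),
                "left_deg": round(report.angles.left_deg, 3),
                "true_right_deg": round(case.truth.right_deg, 3),
                "true_left_deg": round(case.truth.left_deg, 3),
            }
        )
    return EvaluationReport(
        rmse=rmse(preds, truths),
        pixel_table=aggregate_errors(records, keys="landmark"),
        aci_table=aggregate_errors(records, keys="side"),
        confusion=confusion,
        n_cases=len(cases),
        backend=backend_name,
        per_case=per_case,
    )
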