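"""COCO 1.0 keypoint + polygon annotation I/O and dataset splitting.

Annotation files follow the COCO 1.0 layout exported by CVAT: an
``images`` array, polygon ``annotations`` per bone instance, and one
keypoint annotation per image carrying the four AcI landmarks as
``[x, y, v]`` triples.  Keypoint names in incoming files may use the
CVAT position labels ("left up", "left down", "right up", "right down")
or the canonical short names (LU, LD, RU, RD); both map onto the
canonical (RU, RD, LU, LD) order on read.  Polygon categories are the
three bones — ilium (upper), middle bone (ischium-pubis), femur (lower) —
with the side (image left/right) stored as a per-annotation attribute
rather than doubling the category list.

Writing is deterministic: images sorted by id, keys sorted, no
timestamps, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyInputError, SchemaError
from .geometry import LANDMARK_NAMES, LandmarkSet, Point2D
from .masks import BONES, SIDES

__all__ = [
    "RegionPolygon",
    "AnnotatedCase",
    "SplitSpec",
    "read_coco",
    "write_coco",
    "split_dataset",
]

_KEYPOINT_NAME_MAP = {
    "left up": "LU",
    "left down": "LD",
    "right up": "RU",
    "right down": "RD",
    "LU": "LU",
    "LD": "LD",
    "RU": "RU",
    "RD": "RD",
}

_CATEGORY_NAME_MAP = {
    "ilium": "ilium",
    "middle": "middle",
    "middle bone": "middle",
    "ischium-pubis": "middle",
    "femur": "femur",
}

_KEYPOINT_CATEGORY = "pelvis_landmarks"


@dataclass(frozen=True)
class RegionPolygon:
    """One bone outline: polygon vertices with a bone class and side tag."""

    bone: str
    side: str
    vertices: list[tuple[float, float]]

    def __post_init__(self):
        if self.bone not in BONES:
            raise ValueError(f"unknown bone {self.bone!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 vertices")


@dataclass
class AnnotatedCase:
    """One image with its landmarks, bone polygons and optional class label."""

    image_id: int
    file_name: str
    width: int
    height: int
    landmarks: LandmarkSet | None = None
    polygons: list[RegionPolygon] = field(default_factory=list)
    label: str | None = None


def _shoelace_area(vertices) -> float:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(x @ np.roll(y, -1) - y @ np.roll(x, -1)) / 2.0)


def _bbox(points) -> list[float]:
    p = np.asarray(points, dtype=float)
    x0, y0 = p.min(axis=0)
    x1, y1 = p.max(axis=0)
    return [float(x0), float(y0), float(x1 - x0), float(y1 - y0)]


def write_coco(cases: list[AnnotatedCase], path: str | Path) -> None:
    """Write cases as deterministic COCO 1.0 JSON (sorted image ids)."""
    bone_cat_ids = {bone: i + 1 for i, bone in enumerate(BONES)}
    kp_cat_id = len(BONES) + 1
    categories = [
        {"id": cid, "name": bone, "supercategory": "bone"} for bone, cid in bone_cat_ids.items()
    ]
    categories.append(
        {
            "id": kp_cat_id,
            "name": _KEYPOINT_CATEGORY,
            "supercategory": "landmarks",
            "keypoints": list(LANDMARK_NAMES),
            "skeleton": [],
        }
    )
    images, annotations = [], []
    ann_id = 1
    for case in sorted(cases, key=lambda c: c.image_id):
        entry = {
            "id": case.image_id,
            "file_name": case.file_name,
            "width": case.width,
            "height": case.height,
        }
        if case.label is not None:
            entry["attributes"] = {"label": case.label}
        images.append(entry)
        if case.landmarks is not None:
            pts = case.landmarks.as_array()
            flat = []
            for x, y in pts:
                flat.extend([float(x), float(y), 2])  # v=2: labeled and visible
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": case.image_id,
                    "category_id": kp_cat_id,
                    "keypoints": flat,
                    "num_keypoints": 4,
                    "bbox": _bbox(pts),
                    "area": 0.0,
                    "iscrowd": 0,
                    "segmentation": [],
                }
            )
            ann_id += 1
        for poly in case.polygons:
            flat = [float(v) for xy in poly.vertices for v in xy]
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": case.image_id,
                    "category_id": bone_cat_ids[poly.bone],
                    "segmentation": [flat],
                    "bbox": _bbox(poly.vertices),
                    "area": _shoelace_area(poly.vertices),
                    "iscrowd": 0,
                    "attributes": {"side": poly.side},
                }
            )
            ann_id += 1
    doc = {
        "info": {"description": "pelvikit annotations", "version": "1.0"},
        "licenses": [],
        "categories": categories,
        "images": images,
        "annotations": annotations,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def read_coco(path: str | Path) -> list[AnnotatedCase]:
    """Read COCO 1.0 JSON into annotated cases (sorted by image id).

    Raises
    ------
    SchemaError
        On missing/unknown keypoint names or a keypoint count other than
        four; the offending image id is carried on the exception.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise SchemaError(f"missing top-level '{key}' array")

    kp_names_by_cat: dict[int, list[str]] = {}
    bone_by_cat: dict[int, str] = {}
    for cat in doc["categories"]:
        if cat.get("keypoints"):
            kp_names_by_cat[cat["id"]] = list(cat["keypoints"])
        else:
            name = _CATEGORY_NAME_MAP.get(str(cat["name"]).lower())
            if name is not None:
                bone_by_cat[cat["id"]] = name

    cases: dict[int, AnnotatedCase] = {}
    for img in doc["images"]:
        label = (img.get("attributes") or {}).get("label")
        cases[img["id"]] = AnnotatedCase(
            image_id=img["id"],
            file_name=img["file_name"],
            width=img["width"],
            height=img["height"],
            label=label,
        )

    for ann in doc["annotations"]:
        image_id = ann["image_id"]
        if image_id not in cases:
            raise SchemaError(f"annotation {ann.get('id')} references unknown image", image_id)
        case = cases[image_id]
        cat_id = ann["category_id"]
        if cat_id in kp_names_by_cat:
            raw_names = kp_names_by_cat[cat_id]
            kps = ann.get("keypoints", [])
            if len(kps) != 3 * len(raw_names) or len(raw_names) != 4:
                raise SchemaError(
                    f"image {image_id}: expected 4 keypoints, got {len(kps) // 3}", image_id
                )
            named: dict[str, Point2D] = {}
            for i, raw in enumerate(raw_names):
                canon = _KEYPOINT_NAME_MAP.get(raw)
                if canon is None:
                    raise SchemaError(f"image {image_id}: unknown keypoint name {raw!r}", image_id)
                named[canon] = Point2D(float(kps[3 * i]), float(kps[3 * i + 1]))
            if set(named) != set(LANDMARK_NAMES):
                raise SchemaError(
                    f"image {image_id}: keypoint names {sorted(named)} != expected", image_id
                )
            case.landmarks = LandmarkSet(**named)
        elif cat_id in bone_by_cat:
            seg = ann.get("segmentation") or []
            side = (ann.get("attributes") or {}).get("side", "right")
            for flat in seg:
                verts = [(float(flat[i]), float(flat[i + 1])) for i in range(0, len(flat), 2)]
                case.polygons.append(RegionPolygon(bone_by_cat[cat_id], side, verts))
    return [cases[k] for k in sorted(cases)]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/val/test split fractions plus a shuffling seed."""

    train: float = 0.7
    val: float = 0.1
    test: float = 0.2
    seed: int = 0

    def __post_init__(self):
        fr = (self.train, self.val, self.test)
        if any(f < 0 for f in fr):
            raise ValueError(f"fractions must be >= 0, got {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")


def split_dataset(case_ids, spec: SplitSpec = SplitSpec()) -> tuple[list, list, list]:
    """Shuffle ids with the seeded generator and partition them.

    Train receives round(train * n) ids and val round(val * n)
    (round-half-even); test takes the remainder.  The three partitions
    are disjoint and exhaustive, and identical for identical seeds.
    """
    ids = list(case_ids)
    n = len(ids)
    if n == 0:
        raise EmptyInputError("split_dataset requires at least one id")
    order = np.random.default_rng(spec.seed).permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = round(spec.train * n)
    n_val = round(spec.val * n)
    if n_train + n_val > n:
        n_val = n - n_train
    return shuffled[:n_train], shuffled[n_train : n_train + n_val], shuffled[n_train + n_val :]
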