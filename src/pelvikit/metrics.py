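"""Landmark-localization and angle-error metrics.

Three complementary error measures are used to evaluate landmark
predictions against ground truth:

* **RMSE** — root mean square over all per-coordinate residuals.  Each
  case contributes 8 residuals (x and y of 4 landmarks), pooled before
  the square root.
* **Pixel error** — per-landmark Euclidean distance between predicted and
  true point; summarized as a mean.
* **AcI error** — per-side absolute difference between the acetabular
  index computed from predicted landmarks and from true landmarks, in
  degrees.

Results tables carry mean / std / median per landmark (RU, RD, LU, LD)
or per side (Left, Right), plus an ``Avg`` row.  The ``Avg`` row is the
unweighted column-wise mean of the per-key statistics — not the pooled
statistic over all cases — because that is how summary rows of this kind
are conventionally tabulated; a pooled mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, LengthMismatchError
from .geometry import LANDMARK_NAMES, LandmarkSet, compute_aci

__all__ = [
    "SIDE_NAMES",
    "LandmarkErrorRecord",
    "ErrorTable",
    "FiveNumberSummary",
    "pixel_error",
    "mean_pixel_error",
    "rmse",
    "aci_error",
    "landmark_error_record",
    "aggregate_errors",
    "five_number_summary",
]

#: Row order of per-side tables.
SIDE_NAMES = ("Left", "Right")


@dataclass(frozen=True)
class LandmarkErrorRecord:
    """Per-case errors: pixel distance per landmark, |ΔAcI| per side."""

    case_id: str
    pixel: dict[str, float] = field(default_factory=dict)  # keyed RU/RD/LU/LD
    aci: dict[str, float] = field(default_factory=dict)  # keyed Left/Right

    def __post_init__(self):
        for v in list(self.pixel.values()) + list(self.aci.values()):
            if v < 0:
                raise ValueError("error entries must be >= 0")


def pixel_error(pred: LandmarkSet, truth: LandmarkSet) -> dict[str, float]:
    """Euclidean distance in pixels between each predicted and true landmark."""
    d = np.linalg.norm(pred.as_array() - truth.as_array(), axis=1)
    return dict(zip(LANDMARK_NAMES, d.tolist()))


def mean_pixel_error(pred: LandmarkSet, truth: LandmarkSet) -> float:
    """Scalar pixel error: mean distance over the four landmarks."""
    return float(np.mean(list(pixel_error(pred, truth).values())))


def rmse(preds: list[LandmarkSet], truths: list[LandmarkSet]) -> float:
    """Root mean square of all per-coordinate residuals (8 per case)."""
    if len(preds) != len(truths):
        raise LengthMismatchError(f"{len(preds)} predictions vs {len(truths)} truths")
    if not preds:
        raise EmptyInputError("rmse requires at least one case")
    resid = np.concatenate([(p.as_array() - t.as_array()).ravel() for p, t in zip(preds, truths)])
    return float(np.sqrt(np.mean(resid**2)))


def aci_error(pred: LandmarkSet, truth: LandmarkSet) -> dict[str, float]:
    """Absolute per-side AcI difference in degrees, keyed Left/Right."""
    a, b = compute_aci(pred), compute_aci(truth)
    return {"Left": abs(a.left_deg - b.left_deg), "Right": abs(a.right_deg - b.right_deg)}


def landmark_error_record(case_id: str, pred: LandmarkSet, truth: LandmarkSet) -> LandmarkErrorRecord:
    """Bundle pixel and AcI errors of one case into a record."""
    return LandmarkErrorRecord(case_id, pixel_error(pred, truth), aci_error(pred, truth))


@dataclass(frozen=True)
class ErrorTable:
    """Mean/std/median per key with an appended Avg row.

    ``data`` is a DataFrame indexed by key (landmark or side names, then
    "Avg") with columns mean, std, median.
    """

    data: pd.DataFrame
    key: str  # "landmark" or "side"

    def to_csv(self, path) -> None:
        self.data.to_csv(path, float_format="%.3f", index_label=self.key)

    def to_json(self) -> str:
        rounded = self.data.round(3)
        return rounded.to_json(orient="index")

    def row(self, name: str) -> dict[str, float]:
        return self.data.loc[name].to_dict()


def aggregate_errors(
    records: list[LandmarkErrorRecord],
    keys: str = "landmark",
    avg_mode: str = "avg_row",
) -> ErrorTable:
    """Aggregate per-case errors into a mean/std/median table.

    Parameters
    ----------
    records
        One record per evaluated case.
    keys
        "landmark" aggregates pixel errors per landmark (rows RU, RD,
        LU, LD); "side" aggregates AcI errors per side (rows Left, Right).
    avg_mode
        "avg_row" (default): the Avg row is the unweighted mean of the
        per-key statistics. "pooled": the Avg row is the statistic over
        all values pooled across keys.

    Std is the sample standard deviation (n - 1 denominator); it is 0
    when a key has a single case.
    """
    if not records:
        raise EmptyInputError("aggregate_errors requires at least one record")
    if keys == "landmark":
        names, getter = LANDMARK_NAMES, lambda r: r.pixel
    elif keys == "side":
        names, getter = SIDE_NAMES, lambda r: r.aci
    else:
        raise ValueError(f"keys must be 'landmark' or 'side', got {keys!r}")
    if avg_mode not in ("avg_row", "pooled"):
        raise ValueError(f"avg_mode must be 'avg_row' or 'pooled', got {avg_mode!r}")

    cols = {name: np.array([getter(r)[name] for r in records], dtype=float) for name in names}

    def stats(v: np.ndarray) -> dict[str, float]:
        std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return {"mean": float(np.mean(v)), "std": std, "median": float(np.median(v))}

    rows = {name: stats(v) for name, v in cols.items()}
    if avg_mode == "avg_row":
        rows["Avg"] = {
            c: float(np.mean([rows[name][c] for name in names])) for c in ("mean", "std", "median")
        }
    else:
        rows["Avg"] = stats(np.concatenate(list(cols.values())))
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["mean", "std", "median"])
    return ErrorTable(frame, key=keys)


@dataclass(frozen=True)
class FiveNumberSummary:
    """min, Q1, median, Q3, max and IQR = Q3 - Q1 (degrees)."""

    min: float
    q1: float
    median: float
    q3: float
    max: float
    iqr: float

    def __post_init__(self):
        chain = (self.min, self.q1, self.median, self.q3, self.max)
        if any(a > b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"five-number summary not ordered: {chain}")

    def to_dict(self) -> dict[str, float]:
        return {
            "min": self.min,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.max,
            "iqr": self.iqr,
        }

    def boxplot_stats(self) -> dict[str, float]:
        """Quantities a boxplot renderer consumes (whiskers at min/max)."""
        d = self.to_dict()
        d["whislo"], d["whishi"] = self.min, self.max
        return d


def five_number_summary(values) -> FiveNumberSummary:
    """Five-number summary with linear-interpolation quartiles.

    Quartiles follow the linear interpolation between closest ranks used
    by default in numeric software (numpy's "linear" percentile method).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise EmptyInputError("five_number_summary requires at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("five_number_summary requires finite values")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return FiveNumberSummary(
        min=float(v.min()), q1=float(q1), median=float(med), q3=float(q3), max=float(v.max()),
        iqr=float(q3 - q1),
    )
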