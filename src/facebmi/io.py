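"""Readers and writers for landmark templates, face images, subject tables and
cross-validation reports.

Conventions
-----------
* Landmark files use the Psychomorph-style ``.tem`` dialect: the first line is
  an integer point count, each following line one ``x y`` pair.  Comma- or
  tab-delimited coordinate lines are accepted as well.
* Image pixel coordinates are 0-based, x rightward, y downward; landmark
  coordinates share this frame.
* Images are H x W x 3 float arrays with RGB intensities in [0, 1].
* BMI is stored in kg/m^2, computed from cm/kg inputs without rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import FormatError, ValidationError

__all__ = [
    "SubjectRecord",
    "LandmarkSet",
    "compute_bmi",
    "validate_image",
    "read_landmark_template",
    "write_landmark_template",
    "read_subject_table",
    "write_subject_table",
    "load_image",
    "save_image",
    "write_report",
    "read_report",
]


def compute_bmi(height_cm: float, weight_kg: float) -> float:
    """Body mass index in kg/m^2 from height in cm and weight in kg."""
    if height_cm <= 0:
        raise ValidationError(f"height must be positive, got {height_cm}")
    if weight_kg <= 0:
        raise ValidationError(f"weight must be positive, got {weight_kg}")
    return weight_kg / (height_cm / 100.0) ** 2


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's identity and anthropometrics."""

    subject_id: str
    height_cm: float
    weight_kg: float
    bmi: float = field(default=None)  # type: ignore[assignment]
    age: Optional[float] = None

    def __post_init__(self):
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: nonpositive height or weight"
            )
        expected = compute_bmi(self.height_cm, self.weight_kg)
        if self.bmi is None:
            object.__setattr__(self, "bmi", expected)
        elif abs(self.bmi - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValidationError(
                f"subject {self.subject_id!r}: bmi {self.bmi} inconsistent with "
                f"height/weight (expected {expected})"
            )


@dataclass
class LandmarkSet:
    """An ordered 2D facial landmark configuration tied to one face image."""

    subject_id: str
    points: np.ndarray  # (p, 2) float, image-frame pixels
    image_size: Optional[tuple[int, int]] = None  # (width, height)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("points must be a (p, 2) array")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(
                f"subject {self.subject_id!r}: non-finite landmark coordinates"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Check an H x W x 3 RGB array with intensities in [0, 1]."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValidationError("image must be H x W x 3")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValidationError("image must be at least 1 x 1")
    if pixels.min() < -1e-9 or pixels.max() > 1 + 1e-9:
        raise ValidationError("image intensities must lie in [0, 1]")
    return np.clip(pixels, 0.0, 1.0)


# ---------------------------------------------------------------------------
# landmark templates

def read_landmark_template(
    path, subject_id: Optional[str] = None, expected_points: Optional[int] = None
) -> LandmarkSet:
    """Read a ``.tem`` landmark file: a point count line then one x/y pair per
    line.  ``expected_points`` additionally enforces a template size."""
    path = Path(path)
    raw = path.read_text().split("\n")
    lines = [ln.strip() for ln in raw if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty landmark file")
    try:
        count = int(lines[0])
    except ValueError as exc:
        raise FormatError(f"{path}: first line must be an integer point count") from exc
    coords = []
    for i, line in enumerate(lines[1 : 1 + count], start=2):
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected an x/y pair, got {line!r}")
        try:
            coords.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-numeric coordinate in {line!r}") from exc
    if len(coords) != count:
        raise FormatError(
            f"{path}: declared {count} points but found {len(coords)} coordinate lines"
        )
    if expected_points is not None and count != expected_points:
        raise FormatError(
            f"{path}: template declares {count} points, expected {expected_points}"
        )
    return LandmarkSet(subject_id or path.stem, np.array(coords, dtype=float))


def write_landmark_template(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{landmarks.n_points}\n")
        for x, y in landmarks.points:
            fh.write(f"{x:.10g} {y:.10g}\n")


# ---------------------------------------------------------------------------
# subject tables

def read_subject_table(path) -> list[SubjectRecord]:
    """Read a subject CSV with header ``subject_id,height_cm,weight_kg[,age]``.

    BMI is computed as weight / (height/100)^2; a missing age is recorded as
    absent.  Nonpositive height or weight raises a validation error naming the
    offending row.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "height_cm", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        h, w = float(row["height_cm"]), float(row["weight_kg"])
        if h <= 0 or w <= 0:
            raise ValidationError(
                f"{path}: row {i} (subject {row['subject_id']!r}) has nonpositive "
                "height or weight"
            )
        age = None
        if "age" in df.columns and pd.notna(row["age"]):
            age = float(row["age"])
        records.append(SubjectRecord(str(row["subject_id"]), h, w, age=age))
    return records


def write_subject_table(records: Sequence[SubjectRecord], path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "height_cm": [r.height_cm for r in records],
            "weight_kg": [r.weight_kg for r in records],
            "age": [r.age for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images

def load_image(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr


def save_image(pixels: np.ndarray, path) -> None:
    pixels = validate_image(pixels)
    arr = np.round(pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# reports

def write_report(runs, comparisons, path, provenance: Optional[dict] = None) -> dict:
    """Serialize cross-validation runs and model comparisons.

    Emits ``runs.csv`` (long format: model, repeat, mean_r2), ``fold_r2.csv``
    (model, repeat, fold, r2), ``comparisons.csv`` and ``summary.json`` under
    ``path``.  Returns the paths written.
    """
    if not runs:
        raise ValidationError("write_report requires at least one CVRun")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows, fold_rows = [], []
    for run in runs:
        for rep, mean_r2 in enumerate(run.repeat_means):
            rows.append({"model": run.model_id, "repeat": rep, "mean_r2": mean_r2})
        for rep in range(run.fold_r2.shape[0]):
            for fold in range(run.fold_r2.shape[1]):
                fold_rows.append(
                    {
                        "model": run.model_id,
                        "repeat": rep,
                        "fold": fold,
                        "r2": run.fold_r2[rep, fold],
                    }
                )
    runs_path = path / "runs.csv"
    pd.DataFrame(rows).to_csv(runs_path, index=False)
    folds_path = path / "fold_r2.csv"
    pd.DataFrame(fold_rows).to_csv(folds_path, index=False)

    comp_path = path / "comparisons.csv"
    comp_cols = ["model_a", "model_b", "mode", "t", "df", "p"]
    pd.DataFrame(
        [
            {
                "model_a": c.model_a,
                "model_b": c.model_b,
                "mode": c.mode,
                "t": c.t,
                "df": c.df,
                "p": c.p,
            }
            for c in comparisons
        ],
        columns=comp_cols,
    ).to_csv(comp_path, index=False)

    summary = {
        "models": {
            run.model_id: {
                "mean_r2": float(np.mean(run.repeat_means)),
                "sd_r2": float(np.std(run.repeat_means, ddof=1))
                if len(run.repeat_means) > 1
                else 0.0,
                "n_repeats": int(len(run.repeat_means)),
                "mean_excluded_per_fold": float(np.mean(run.exclusions)),
            }
            for run in runs
        },
        "provenance": provenance or {},
    }
    summary_path = path / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {
        "runs": runs_path,
        "fold_r2": folds_path,
        "comparisons": comp_path,
        "summary": summary_path,
    }


def read_report(path) -> dict:
    """Load a report directory back into DataFrames + the summary dict."""
    path = Path(path)
    out = {
        "runs": pd.read_csv(path / "runs.csv"),
        "fold_r2": pd.read_csv(path / "fold_r2.csv"),
        "comparisons": pd.read_csv(path / "comparisons.csv"),
        "summary": json.loads((path / "summary.json").read_text()),
    }
    return out
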