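"""File formats and cohort validation.

Label maps travel as lossless unsigned-integer single-channel PNG or TIFF;
RGB patches as 8-bit PNG/TIFF; cohorts as CSV/TSV with a typed schema;
gene sets as GMT (tab-separated: set name, description, genes).
Coordinates are (row, col), 0-based, with pixel centers at integer
coordinates.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "read_label_image",
    "write_label_image",
    "read_rgb_image",
    "write_rgb_image",
    "load_stage_map",
    "map_stage",
    "validate_cohort",
    "CohortValidationError",
    "read_gmt",
    "write_gmt",
]


class CohortValidationError(ValueError):
    """Structured cohort-validation failure; carries the row-level report."""

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report if report is not None else pd.DataFrame()


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def _check_label_array(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: label image must be single-channel 2-D, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"{path}: label image must be integer-valued, got dtype {arr.dtype}"
        )
    if arr.min() < 0:
        raise ValueError(f"{path}: labels must be non-negative")
    return arr


def read_label_image(path) -> np.ndarray:
    """Lossless read of an unsigned-integer label map (PNG or TIFF)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    return _check_label_array(np.asarray(arr), path)


def write_label_image(labels: np.ndarray, path) -> None:
    """Write a label map as 16-bit (or 8-bit if it fits) unsigned PNG/TIFF."""
    labels = _check_label_array(np.asarray(labels), path)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed the uint16 range")
    out = labels.astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        Image.fromarray(out).save(path)  # PIL mode I;16 -> 16-bit gray PNG


def read_rgb_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit H x W x 3 RGB image")
    return arr


def write_rgb_image(rgb: np.ndarray, path) -> None:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.dtype != np.uint8:
        raise ValueError("expected an 8-bit H x W x 3 RGB image")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb)
    else:
        Image.fromarray(rgb).save(path)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def load_stage_map() -> dict[str, int]:
    """The editable AJCC-stage → ordinal collapse table shipped with the
    package (``data/stage_map.json``)."""
    text = resources.files("nucmorph").joinpath("data/stage_map.json").read_text()
    raw = json.loads(text)
    return {k.upper(): int(v) for k, v in raw.items() if not k.startswith("_")}


def map_stage(value, stage_map: dict[str, int] | None = None) -> float:
    """Map one stage entry to ordinal 1–4; unknown strings and missing
    values become NaN (missing, not errors)."""
    if stage_map is None:
        stage_map = load_stage_map()
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (int, np.integer)):
        return float(value) if value in (1, 2, 3, 4) else np.nan
    return float(stage_map.get(str(value).strip().upper(), np.nan))


MANDATORY_COHORT_COLUMNS = ("slide_id",)


def validate_cohort(
    path,
    *,
    require: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and type-check a cohort CSV/TSV.

    Returns ``(frame, report)`` where ``report`` collects row-level
    violations (slide_id, column, reason); offending rows are dropped from
    the frame.  Missing mandatory columns (or columns listed in
    ``require``) raise :class:`CohortValidationError`.  Stage strings are
    collapsed to ordinal 1–4 via the shipped mapping table; unknown stages
    become missing.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise CohortValidationError(f"{path}: empty cohort file") from None
    missing = [c for c in (*MANDATORY_COHORT_COLUMNS, *require)
               if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{path}: missing mandatory column(s): {missing}"
        )

    violations: list[dict] = []
    bad = pd.Series(False, index=df.index)

    if "stage" in df.columns:
        stage_map = load_stage_map()
        df["stage"] = [map_stage(v, stage_map) for v in df["stage"]]

    if "surv_event" in df.columns:
        ok = df["surv_event"].isin([0, 1]) | df["surv_event"].isna()
        for i in df.index[~ok]:
            violations.append(
                {"slide_id": df.at[i, "slide_id"], "column": "surv_event",
                 "reason": f"event must be 0/1, got {df.at[i, 'surv_event']!r}"}
            )
        bad |= ~ok
    if "surv_time" in df.columns:
        t = pd.to_numeric(df["surv_time"], errors="coerce")
        ok = (t > 0) | df["surv_time"].isna()
        for i in df.index[~ok]:
            violations.append(
                {"slide_id": df.at[i, "slide_id"], "column": "surv_time",
                 "reason": f"time must be > 0, got {df.at[i, 'surv_time']!r}"}
            )
        bad |= ~ok
    if "wgd_count" in df.columns:
        ok = df["wgd_count"].isin([0, 1, 2]) | df["wgd_count"].isna()
        for i in df.index[~ok]:
            violations.append(
                {"slide_id": df.at[i, "slide_id"], "column": "wgd_count",
                 "reason": f"wgd_count must be 0/1/2, got {df.at[i, 'wgd_count']!r}"}
            )
        bad |= ~ok

    dup = df["slide_id"].duplicated(keep=False)
    for i in df.index[dup]:
        violations.append({"slide_id": df.at[i, "slide_id"],
                           "column": "slide_id", "reason": "duplicate slide_id"})
    bad |= dup

    report = pd.DataFrame(violations,
                          columns=["slide_id", "column", "reason"])
    return df.loc[~bad].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes,
    tab-separated."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path,
              description: str = "nucmorph") -> None:
    lines = [
        "\t".join([name, description, *genes])
        for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
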