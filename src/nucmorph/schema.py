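"""Feature and cell-class vocabulary shared across the pipeline.

A *nuHIF* (nuclear human-interpretable feature) is a slide-level summary
statistic — the mean or standard deviation over all nuclei of one cell
class — of one per-nucleus morphologic or color feature.  Slide-level
column names round-trip the convention ``MEAN[<CLASS>_NUCLEUS_<FEATURE>]_H&E``.
"""

from __future__ import annotations

import re

#: The 15 per-nucleus features: 7 shape descriptors in micron units and
#: 8 color statistics (mean/SD of grayscale, HSV saturation, CIELAB a*, b*).
FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "circularity",
    "solidity",
    "gray_mean",
    "gray_sd",
    "sat_mean",
    "sat_sd",
    "lab_a_mean",
    "lab_a_sd",
    "lab_b_mean",
    "lab_b_sd",
)

SHAPE_FEATURES: tuple[str, ...] = FEATURE_NAMES[:7]
COLOR_FEATURES: tuple[str, ...] = FEATURE_NAMES[7:]

#: Pan-indication cell classes; extensible via the ``classes`` argument of
#: the aggregation functions.
DEFAULT_CLASSES: tuple[str, ...] = (
    "CANCER",
    "FIBROBLAST",
    "LYMPHOCYTE",
    "MACROPHAGE",
    "PLASMA",
)

#: Slide-level statistics applied per (class, feature).
SLIDE_STATS: tuple[str, ...] = ("MEAN", "STD")

_NUHIF_RE = re.compile(r"^(MEAN|STD)\[([A-Z0-9]+)_NUCLEUS_([A-Z0-9_]+)\]_H&E$")


def feature_token(feature: str) -> str:
    """Upper-snake token used inside a nuHIF column name."""
    return feature.upper()


def nuhif_name(stat: str, cell_class: str, feature: str) -> str:
    """Slide-level column name, e.g. ``MEAN[FIBROBLAST_NUCLEUS_AREA]_H&E``."""
    if stat not in SLIDE_STATS:
        raise ValueError(f"stat must be one of {SLIDE_STATS}, got {stat!r}")
    return f"{stat}[{cell_class.upper()}_NUCLEUS_{feature_token(feature)}]_H&E"


def parse_nuhif_name(name: str) -> tuple[str, str, str]:
    """Inverse of :func:`nuhif_name`: returns (stat, cell_class, feature).

    The feature component is returned in the lower-case per-nucleus
    vocabulary of :data:`FEATURE_NAMES`.
    """
    m = _NUHIF_RE.match(name)
    if m is None:
        raise ValueError(f"not a nuHIF column name: {name!r}")
    stat, cls, feat = m.groups()
    return stat, cls, feat.lower()


def nuhif_columns(classes=DEFAULT_CLASSES) -> list[str]:
    """All slide-level column names for the given classes (30 per class)."""
    return [
        nuhif_name(stat, cls, feat)
        for cls in classes
        for feat in FEATURE_NAMES
        for stat in SLIDE_STATS
    ]
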