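"""Slide-level nuHIF aggregation.

Per-nucleus features are collapsed to slide level as the mean and sample
standard deviation of each of the 15 features over each cell class's
nuclei, yielding 30 named columns per cell class (and 30 × C columns for a
C-class vocabulary).  Classes with no nuclei on a slide yield missing
values — absence is never encoded as zero; classes with a single nucleus
have a defined MEAN but a missing STD.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .morphometry import NucleusFeatureRecord
from .schema import DEFAULT_CLASSES, FEATURE_NAMES, nuhif_columns, nuhif_name

__all__ = ["aggregate_slide", "pool_cohort", "count_columns"]


def count_columns(classes: Sequence[str]) -> list[str]:
    return [f"N_{cls.upper()}_NUCLEI" for cls in classes]


def aggregate_slide(
    records: Iterable[NucleusFeatureRecord],
    slide_id: str,
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> pd.Series:
    """One slide's nuHIF row: 30 columns per cell class plus nucleus counts.

    Records whose ``cell_class`` is outside ``classes`` are ignored (the
    class vocabulary defines the schema).  Empty input yields a row of
    missing values with zero counts.
    """
    records = list(records)
    row: dict[str, float] = {}
    for cls in classes:
        cls_up = cls.upper()
        members = [r for r in records if r.cell_class.upper() == cls_up]
        row[f"N_{cls_up}_NUCLEI"] = len(members)
        for feat in FEATURE_NAMES:
            # sorted so aggregation commutes exactly with record reordering
            values = np.sort(np.array([getattr(r, feat) for r in members],
                                      dtype=float))
            mean = float(values.mean()) if len(values) else np.nan
            std = float(values.std(ddof=1)) if len(values) >= 2 else np.nan
            row[nuhif_name("MEAN", cls_up, feat)] = mean
            row[nuhif_name("STD", cls_up, feat)] = std
    out = pd.Series(row, name=slide_id)
    # stable column order: counts first, then the canonical nuHIF order
    order = count_columns(classes) + nuhif_columns(classes)
    return out.reindex(order)


def pool_cohort(slide_rows: Iterable[pd.Series]) -> pd.DataFrame:
    """Stack slide rows into a cohort table, one row per slide, sorted by
    slide id.  Duplicate slide ids or mismatched column schemas raise."""
    rows = list(slide_rows)
    if not rows:
        return pd.DataFrame()
    ref_cols = list(rows[0].index)
    for r in rows[1:]:
        if list(r.index) != ref_cols:
            missing = set(ref_cols).symmetric_difference(r.index)
            raise ValueError(
                f"slide {r.name!r} has a mismatched column schema "
                f"(differs in {sorted(missing)[:5]}...)"
            )
    ids = [r.name for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate slide_id(s): {dupes}")
    df = pd.DataFrame(rows).sort_index()
    df.index.name = "slide_id"
    return df
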