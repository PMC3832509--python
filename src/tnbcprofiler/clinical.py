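"""Clinical sample filtering on annotation tables.

Mirrors the kind of cohort definition used when assembling a validation set
from a public archive: equality and threshold conditions on annotation
fields, optionally collapsed to one sample per patient.
"""
from __future__ import annotations

from typing import Any, Mapping, Sequence

import pandas as pd

__all__ = ["filter_clinical"]

_THRESHOLD_OPS = {
    "min": lambda col, v: col >= v,
    "max": lambda col, v: col <= v,
}


def filter_clinical(
    annotation: pd.DataFrame,
    predicate_config: Mapping[str, Any],
    *,
    per_patient: bool = False,
) -> list[str]:
    """Return sample ids satisfying every condition in ``predicate_config``.

    Conditions are keyed by annotation column.  A scalar means equality; a
    list/set/tuple means membership; a dict like ``{"min": 30}`` /
    ``{"max": 70}`` thresholds a numeric column.  With ``per_patient=True``
    only the first surviving sample (by sample_id order) of each patient is
    kept.  Idempotent: filtering an already-filtered table returns the same
    ids.
    """
    if annotation.empty:
        return []
    mask = pd.Series(True, index=annotation.index)
    for field, condition in predicate_config.items():
        if field not in annotation.columns:
            raise KeyError(f"unknown annotation field {field!r}")
        col = annotation[field]
        if isinstance(condition, Mapping):
            for op, value in condition.items():
                if op not in _THRESHOLD_OPS:
                    raise ValueError(f"unknown threshold op {op!r} for {field!r}")
                mask &= _THRESHOLD_OPS[op](pd.to_numeric(col), value)
        elif isinstance(condition, (list, set, tuple, frozenset)) and not isinstance(
            condition, str
        ):
            mask &= col.isin(list(condition))
        else:
            mask &= col == condition
    kept = annotation.loc[mask]
    if per_patient:
        order = kept["sample_id"].to_numpy().argsort(kind="stable")
        kept = kept.iloc[order].drop_duplicates("patient_id", keep="first")
    return sorted(kept["sample_id"].tolist())
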