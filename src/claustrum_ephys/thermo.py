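"""Temperature sensitivity: Q10 coefficients and feature correction.

The temperature coefficient of a property P measured at two temperatures is

    Q10 = (P2 / P1) ** (10 / (T2 - T1))

For negative-valued properties (AHP amplitudes, decay rates, thresholds) the
ratio is taken on magnitudes and the sign restored, since the power law is
undefined across sign changes and the published coefficients for such
properties are positive.

A property table recorded at temperature T is corrected to the reference
temperature (24 C) by dividing each value's magnitude by
``Q10 ** ((T - T_ref) / 10)``.

Per-cell Q10 values are aggregated per property after discarding outliers
outside ``[Q1 - 3*IQR, Q3 + 3*IQR]``; the mean of the survivors is used.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry

__all__ = ["Q10Table", "q10", "aggregate_q10", "correct_to_reference", "shift_to_temperature"]

REFERENCE_TEMPERATURE_C = 24.0
IQR_FENCE_FACTOR = 3.0


@dataclass
class Q10Table:
    """Per-property temperature coefficients (mean, SEM, n survivors)."""

    values: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    reference_temperature: float = REFERENCE_TEMPERATURE_C

    def mean(self, key: str) -> float | None:
        entry = self.values.get(key)
        return entry[0] if entry else None

    def __contains__(self, key: str) -> bool:
        return key in self.values

    @classmethod
    def default(cls) -> "Q10Table":
        """The shipped per-property coefficient table (reference 24 C)."""
        with resources.files("claustrum_ephys.data").joinpath("q10.csv").open(
            encoding="utf-8"
        ) as fh:
            rows = list(csv.DictReader(fh))
        vals = {
            r["key"]: (float(r["mean_q10"]), float(r["sem"]), 13) for r in rows
        }
        return cls(values=vals)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Q10Table":
        df = pd.read_csv(path)
        name_col = df.columns[0]
        vals = {}
        for _, r in df.iterrows():
            key = registry.resolve_label(str(r[name_col]))
            if key is None:
                raise ValueError(f"unknown property '{r[name_col]}' in Q10 table")
            vals[key] = (float(r["mean_q10"]), float(r.get("sem", np.nan)), 0)
        return cls(values=vals)

    def to_csv(self, path: str | Path, feature_set: int = 63) -> None:
        rows = []
        for key, (m, sem, n) in self.values.items():
            p = registry.BY_KEY[key]
            label = (p.label_63 if feature_set == 63 else p.label_38) or p.label
            rows.append({"property": label, "mean_q10": m, "sem": sem, "n": n})
        pd.DataFrame(rows).to_csv(path, index=False)


def q10(p1: float, p2: float, t1: float, t2: float) -> float:
    """Temperature coefficient of one property measured at two temperatures.

    For negative-valued properties the ratio of magnitudes is used.  Zero or
    sign-mixed inputs are undefined and reported as NaN.
    """
    if t2 == t1:
        raise ValueError("t2 must differ from t1")
    if p1 == 0 or p2 == 0 or (p1 < 0) != (p2 < 0):
        return float("nan")
    return float((abs(p2) / abs(p1)) ** (10.0 / (t2 - t1)))


def aggregate_q10(
    per_cell: dict[str, np.ndarray | list[float]],
    reference_temperature: float = REFERENCE_TEMPERATURE_C,
) -> Q10Table:
    """Aggregate per-cell Q10 values per property with IQR outlier fencing.

    Values outside ``[Q1 - 3*IQR, Q3 + 3*IQR]`` are discarded; the mean and
    SEM of the survivors are stored.  Properties with fewer than three
    finite values raise; properties whose values are all discarded are
    dropped from the table.
    """
    table = Q10Table(reference_temperature=reference_temperature)
    for key, vals in per_cell.items():
        x = np.asarray(vals, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 3:
            raise ValueError(f"need >= 3 cells per property (got {x.size} for {key})")
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        keep = x[(x >= q1 - IQR_FENCE_FACTOR * iqr) & (x <= q3 + IQR_FENCE_FACTOR * iqr)]
        if keep.size == 0:
            continue
        sem = float(np.std(keep, ddof=1) / np.sqrt(keep.size)) if keep.size > 1 else 0.0
        table.values[key] = (float(np.mean(keep)), sem, int(keep.size))
    return table


def _scale(fv: pd.Series | dict, table: Q10Table, exponent_sign: float, delta_t: float):
    """Multiply (+1) or divide (-1) magnitudes by Q10**(delta_t/10)."""
    items = fv.items() if hasattr(fv, "items") else fv
    out = {}
    uncovered = []
    for key, val in items:
        m = table.mean(key)
        if m is None:
            if key in registry.BY_KEY:
                uncovered.append(key)
            out[key] = val
            continue
        if val is None or (isinstance(val, float) and np.isnan(val)):
            out[key] = val
            continue
        factor = m ** (exponent_sign * delta_t / 10.0)
        out[key] = float(np.sign(val) * abs(val) * factor) if val != 0 else 0.0
    return out, uncovered


def correct_to_reference(
    fv: pd.Series | dict[str, float], recorded_t: float, table: Q10Table | None = None
) -> dict[str, float]:
    """Correct a feature vector recorded at *recorded_t* to the table's
    reference temperature.  Uncovered properties pass through unchanged.
    Missing values stay missing."""
    table = table or Q10Table.default()
    delta = recorded_t - table.reference_temperature
    out, _ = _scale(fv, table, exponent_sign=-1.0, delta_t=delta)
    return out


def shift_to_temperature(
    fv: pd.Series | dict[str, float], target_t: float, table: Q10Table | None = None
) -> dict[str, float]:
    """Emulate recording at *target_t* from reference-temperature features
    (the exact inverse of :func:`correct_to_reference`)."""
    table = table or Q10Table.default()
    delta = target_t - table.reference_temperature
    out, _ = _scale(fv, table, exponent_sign=+1.0, delta_t=delta)
    return out
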