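"""Sweep and feature-table I/O plus recording quality control.

A *SweepSet* is one cell's family of 1-s current-step responses.  The
on-disk sweep format is a plain CSV with one ``time_s`` column and one
``I_<pA>`` column per sweep (UTF-8, '.' decimal).  Axon Binary Format files
can be read when the optional ``pyabf`` dependency is installed.

Quality control mirrors standard whole-cell criteria: access resistance
below 30 MOhm, Ra/Rm ratio below 20%, resting potential at least as negative
as -50 mV and stable, overshooting action potentials, and (for interneuron
max-activity features) saturation of the firing-frequency/current curve.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry

__all__ = [
    "SweepSet",
    "QCReport",
    "read_abf",
    "read_sweep_csv",
    "write_sweep_csv",
    "read_feature_csv",
    "write_feature_csv",
    "qc_check",
]

#: QC rule identifiers
RA_EXCEEDS = "ra_exceeds"
RA_RM_RATIO = "ra_rm_ratio"
RMP_UNSTABLE_OR_HIGH = "rmp_unstable_or_high"
NO_OVERSHOOT = "no_overshoot"
NO_SATURATION = "no_saturation"

RA_LIMIT_MOHM = 30.0
RA_RM_LIMIT = 0.20
RMP_LIMIT_MV = -50.0
RMP_DRIFT_LIMIT_MV = 5.0  # baseline drift between first and last sweep


@dataclass
class SweepSet:
    """A family of current-clamp step recordings from one cell.

    Parameters
    ----------
    cell_id : str
    currents : array of step amplitudes, pA, one per sweep
    voltages : 2-D array (n_sweeps, n_samples), mV
    sampling_rate : Hz
    stim_onset, stim_offset : stimulus window within each sweep, seconds
    temperature : bath temperature, Celsius
    access_resistance, membrane_resistance_estimate : MOhm, optional
    """

    cell_id: str
    currents: np.ndarray
    voltages: np.ndarray
    sampling_rate: float
    stim_onset: float = 0.1
    stim_offset: float = 1.1
    temperature: float = 24.0
    access_resistance: float | None = None
    membrane_resistance_estimate: float | None = None

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.voltages = np.atleast_2d(np.asarray(self.voltages, dtype=float))
        if self.voltages.shape[0] != self.currents.size:
            raise ValueError(
                f"{self.currents.size} current amplitudes but "
                f"{self.voltages.shape[0]} voltage sweeps"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n_stim = round((self.stim_offset - self.stim_onset) * self.sampling_rate)
        n_one_s = round(self.sampling_rate)
        if abs(n_stim - n_one_s) > 1:
            warnings.warn(
                f"stimulus window is {n_stim / self.sampling_rate:.4f} s, not 1 s",
                stacklevel=2,
            )
        order = np.argsort(self.currents, kind="stable")
        if not np.array_equal(order, np.arange(order.size)):
            self.currents = self.currents[order]
            self.voltages = self.voltages[order]

    @property
    def n_sweeps(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def sweep(self, index: int) -> np.ndarray:
        return self.voltages[index]

    def stim_slice(self) -> slice:
        i0 = int(round(self.stim_onset * self.sampling_rate))
        i1 = int(round(self.stim_offset * self.sampling_rate))
        return slice(i0, min(i1, self.n_samples))


@dataclass
class QCReport:
    """Outcome of the recording quality-control rules."""

    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def read_abf(path: str | Path) -> SweepSet:
    """Read an episodic current-clamp ABF file into a :class:`SweepSet`.

    Requires the optional ``pyabf`` dependency.
    """
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "Reading .abf files requires the optional dependency 'pyabf' "
            "(pip install claustrum-ephys[abf]); alternatively convert the "
            "recording to the CSV sweep format (read_sweep_csv)."
        ) from exc

    abf = pyabf.ABF(str(path))  # pragma: no cover - optional dependency
    if "mV" not in (abf.adcUnits[0] or ""):  # pragma: no cover
        raise ValueError("not a current-clamp recording (ADC unit is not mV)")
    currents, sweeps = [], []  # pragma: no cover
    for i in abf.sweepList:  # pragma: no cover
        abf.setSweep(i)
        sweeps.append(np.asarray(abf.sweepY, dtype=float))
        amps = np.asarray(abf.sweepC, dtype=float)
        currents.append(float(amps[np.argmax(np.abs(amps))]))
    lengths = {len(s) for s in sweeps}  # pragma: no cover
    if len(lengths) != 1:  # pragma: no cover
        raise ValueError("mismatched sweep lengths")
    return SweepSet(  # pragma: no cover
        cell_id=Path(path).stem,
        currents=np.array(currents),
        voltages=np.vstack(sweeps),
        sampling_rate=float(abf.dataRate),
    )


_SWEEP_COL = re.compile(r"^I_(-?\d+(?:\.\d+)?)$")


def read_sweep_csv(path: str | Path, **metadata) -> SweepSet:
    """Read the CSV sweep dialect: ``time_s`` plus one ``I_<pA>`` column per sweep."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("sweep CSV must contain a 'time_s' column")
    currents, cols = [], []
    for c in df.columns:
        m = _SWEEP_COL.match(c)
        if m:
            currents.append(float(m.group(1)))
            cols.append(c)
    if not cols:
        raise ValueError("no sweep columns of the form 'I_<pA>' found")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time_s must be uniformly sampled")
    if df[cols].isna().any().any():
        raise ValueError("mismatched sweep lengths (missing samples)")
    meta = {"cell_id": Path(path).stem, "sampling_rate": 1.0 / dt[0]}
    meta.update(metadata)
    return SweepSet(
        currents=np.array(currents), voltages=df[cols].to_numpy(dtype=float).T, **meta
    )


def write_sweep_csv(s: SweepSet, path: str | Path, precision: int = 6) -> None:
    """Write a :class:`SweepSet` in the CSV sweep dialect."""

    def fmt_amp(a: float) -> str:
        return f"{a:g}"

    cols = {"time_s": s.time}
    for amp, v in zip(s.currents, s.voltages):
        cols[f"I_{fmt_amp(amp)}"] = v
    pd.DataFrame(cols).to_csv(path, index=False, float_format=f"%.{precision}g")


def read_feature_csv(
    path: str | Path, on_unknown: str = "raise"
) -> pd.DataFrame:
    """Read a feature table whose columns carry registry labels.

    Column labels (or known aliases) are mapped onto registry keys; the
    result is a DataFrame keyed by registry keys.  ``on_unknown`` is one of
    ``"raise"``, ``"warn"`` (drop with a warning) or ``"ignore"``.

    Non-feature bookkeeping columns named ``cell_id`` or ``label`` pass
    through untouched.
    """
    df = pd.read_csv(path)
    rename: dict[str, str] = {}
    unknown: list[str] = []
    for c in df.columns:
        if c in ("cell_id", "label"):
            continue
        key = registry.resolve_label(str(c))
        if key is None:
            unknown.append(str(c))
        else:
            if key in rename.values():
                raise ValueError(f"duplicated feature column for '{key}'")
            rename[c] = key
    if not rename:
        raise ValueError("no recognizable feature columns in file")
    if unknown:
        msg = f"unknown feature columns: {unknown}"
        if on_unknown == "raise":
            raise ValueError(msg)
        if on_unknown == "warn":
            warnings.warn(msg, stacklevel=2)
        df = df.drop(columns=unknown)
    dup_targets = pd.Series(list(rename.values()))
    if dup_targets.duplicated().any():
        raise ValueError("duplicated feature column")
    return df.rename(columns=rename)


def write_feature_csv(
    df: pd.DataFrame, path: str | Path, feature_set: int = 38
) -> None:
    """Write a key-indexed feature table with printed registry labels."""
    rename = {
        k: lab
        for k, lab in zip(
            [c for c in df.columns if c in registry.BY_KEY],
            registry.labels_for([c for c in df.columns if c in registry.BY_KEY], feature_set),
        )
    }
    df.rename(columns=rename).to_csv(path, index=False)


def qc_check(
    rmp: float,
    ra: float | None,
    rm: float,
    ap_peaks: np.ndarray | list[float] | None = None,
    saturated: bool = True,
    rmp_drift: float = 0.0,
) -> QCReport:
    """Apply the recording exclusion rules; always returns a report.

    Rules: Ra > 30 MOhm; Ra/Rm > 20%; RMP above -50 mV or baseline drift
    beyond 5 mV; any accepted AP peak not overshooting 0 mV; firing
    frequency not saturating at the highest current (interneuron
    max-activity rule).
    """
    reasons: list[str] = []
    if ra is not None and ra > RA_LIMIT_MOHM:
        reasons.append(RA_EXCEEDS)
    if ra is not None and rm > 0 and ra / rm > RA_RM_LIMIT:
        reasons.append(RA_RM_RATIO)
    if rmp > RMP_LIMIT_MV or abs(rmp_drift) > RMP_DRIFT_LIMIT_MV:
        reasons.append(RMP_UNSTABLE_OR_HIGH)
    if ap_peaks is not None and len(ap_peaks) > 0 and np.min(ap_peaks) <= 0.0:
        reasons.append(NO_OVERSHOOT)
    if not saturated:
        reasons.append(NO_SATURATION)
    return QCReport(reasons=reasons)
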