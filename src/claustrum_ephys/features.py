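"""Extraction of intrinsic electrical properties from current-step families.

The canonical property sets (38-property population set, 63-property
interneuron set; see :mod:`claustrum_ephys.registry`) are computed from a
:class:`~claustrum_ephys.io.SweepSet` at up to three stimulus levels: the
current threshold (ct), twice the threshold (2xct) and the level evoking the
maximum firing frequency (max activity).

Detection conventions
---------------------
* AP threshold: first sample of a suprathreshold excursion where dV/dt
  exceeds 10 mV/ms (central differences on the raw trace, 1-ms debounce).
* APs must overshoot 0 mV to count.
* AHP amplitude is referenced to the AP threshold; AHP latency runs from
  the AP peak to the trough.
* ISIs run between consecutive AP peaks; instantaneous frequency is 1/ISI.
* Frequency adaptation compares the first inter-AP frequency with the mean
  of the last three inter-AP frequencies of the train.
* A statistic whose train is too short is reported missing (NaN), never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import registry
from .io import SweepSet

__all__ = [
    "APEvent",
    "ADPResult",
    "TrainStats",
    "detect_aps",
    "passive_properties",
    "current_threshold",
    "ap_waveform",
    "ahp_features",
    "detect_adp",
    "train_statistics",
    "initial_adaptation_features",
    "extract_features",
]

DVDT_THRESHOLD = 10.0  # mV/ms
DEBOUNCE_MS = 1.0
PEAK_SEARCH_MS = 10.0
DECAY_WINDOW_CAP_MS = 10.0
ADP_FILTER_HZ = 50.0
ADP_FILTER_ORDER = 8
ADP_MARGIN_MV = 0.3  # local-max significance margin against baseline noise


@dataclass
class APEvent:
    """One detected action potential (times in ms from trace start)."""

    i_thresh: int
    i_peak: int
    threshold_time: float
    threshold_v: float
    peak_time: float
    peak_v: float
    amplitude: float | None = None
    half_width: float | None = None
    max_rise: float | None = None
    max_decay: float | None = None
    ahp_v: float | None = None
    ahp_latency: float | None = None
    i_ahp: int | None = None


@dataclass
class ADPResult:
    """Afterdepolarization detection outcome."""

    present: bool
    integrated_amplitude: float = 0.0


@dataclass
class TrainStats:
    """Temporal statistics of one spike train (None = not measurable)."""

    n_ap: int
    latency_first_ap: float | None = None
    isis: np.ndarray = field(default_factory=lambda: np.empty(0))
    inst_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    initial_inst_freq: float | None = None
    max_adaptation: float | None = None
    isi_ratio: float | None = None
    mean_first2_isi: float | None = None
    sd_first2_isi: float | None = None
    delta_isi_1_2: float | None = None
    delta_f_1_2: float | None = None
    cv2_all: float | None = None
    cv2_excl1: float | None = None
    cv2_excl2: float | None = None
    amp_ratio_1_2: float | None = None
    amp_ratio_2_3: float | None = None
    amp_ratio_1_last3: float | None = None


def _dvdt(v: np.ndarray, fs: float) -> np.ndarray:
    """First derivative in mV/ms, central differences on the raw trace."""
    return np.gradient(v) * (fs / 1000.0)


def detect_aps(
    v: np.ndarray,
    fs: float,
    window: tuple[int, int] | None = None,
    dvdt_threshold: float = DVDT_THRESHOLD,
) -> list[APEvent]:
    """Detect APs in one voltage trace; events with peak <= 0 mV are rejected.

    ``window`` is a (start, stop) sample-index pair; detection is restricted
    to it but peak search may run to the trace end.
    """
    v = np.asarray(v, dtype=float)
    dv = _dvdt(v, fs)
    i0, i1 = (0, v.size) if window is None else window
    above = dv > dvdt_threshold
    deb = max(1, int(round(DEBOUNCE_MS * fs / 1000.0)))
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    rising = rising[(rising >= i0) & (rising < i1)]
    if above[i0] and (window is None or i0 == 0 or not above[i0 - 1]):
        rising = np.insert(rising, 0, i0)

    onsets: list[int] = []
    for idx in rising:
        lo = max(0, idx - deb)
        if above[lo:idx].any():
            continue  # retrigger within the debounce period
        onsets.append(int(idx))

    events: list[APEvent] = []
    dt_ms = 1000.0 / fs
    peak_span = int(round(PEAK_SEARCH_MS * fs / 1000.0))
    for k, on in enumerate(onsets):
        nxt = onsets[k + 1] if k + 1 < len(onsets) else v.size
        hi = min(nxt, on + peak_span, v.size)
        if hi <= on:
            continue
        rel = int(np.argmax(v[on:hi]))
        i_peak = on + rel
        if v[i_peak] <= 0.0:
            continue  # no overshoot -> rejected
        events.append(
            APEvent(
                i_thresh=on,
                i_peak=i_peak,
                threshold_time=on * dt_ms,
                threshold_v=float(v[on]),
                peak_time=i_peak * dt_ms,
                peak_v=float(v[i_peak]),
            )
        )
    return events


def passive_properties(
    s: SweepSet, ap_counts: np.ndarray | None = None
) -> tuple[float, float]:
    """Resting potential and input resistance from the V-I relation.

    Steady-state voltage (mean over the last fifth of the stimulus window)
    is regressed on injected current over all subthreshold sweeps; the slope
    gives Rm (MOhm), the intercept the RMP (mV).
    """
    if ap_counts is None:
        sl = s.stim_slice()
        ap_counts = np.array(
            [len(detect_aps(v, s.sampling_rate, (sl.start, sl.stop))) for v in s.voltages]
        )
    sub = np.flatnonzero(np.asarray(ap_counts) == 0)
    if sub.size < 2:
        raise ValueError("need at least two subthreshold sweeps for the V-I fit")
    sl = s.stim_slice()
    n_tail = max(1, (sl.stop - sl.start) // 5)
    vss = np.array([np.mean(s.voltages[i, sl.stop - n_tail : sl.stop]) for i in sub])
    amps = s.currents[sub]
    slope, intercept = np.polyfit(amps, vss, 1)
    return float(intercept), float(slope * 1000.0)  # mV/pA -> MOhm


def current_threshold(
    currents: np.ndarray, ap_counts: np.ndarray
) -> tuple[float, int, int, int]:
    """Current threshold and the three stimulus-level sweep indices.

    Returns ``(ct, idx_ct, idx_2xct, idx_max)``.  The 2xct sweep is the one
    whose amplitude is nearest to twice ct (ties go to the lower amplitude);
    the max-activity sweep fires the most APs (ties to the lowest amplitude).
    """
    currents = np.asarray(currents, dtype=float)
    ap_counts = np.asarray(ap_counts)
    firing = np.flatnonzero(ap_counts >= 1)
    if firing.size == 0:
        raise ValueError("no current threshold: no sweep fires an accepted AP")
    idx_ct = int(firing[0])
    ct = float(currents[idx_ct])
    dist = np.abs(currents - 2.0 * ct)
    best = np.min(dist)
    cands = np.flatnonzero(np.isclose(dist, best))
    idx_2x = int(cands[np.argmin(currents[cands])])
    top = np.max(ap_counts)
    cands = np.flatnonzero(ap_counts == top)
    idx_max = int(cands[np.argmin(currents[cands])])
    return ct, idx_ct, idx_2x, idx_max


def ap_waveform(
    e: APEvent, v: np.ndarray, fs: float, next_thresh_idx: int | None = None
) -> APEvent:
    """Fill amplitude, half-width and slope extrema of one AP in place."""
    dt_ms = 1000.0 / fs
    dv = _dvdt(v, fs)
    e.amplitude = e.peak_v - e.threshold_v
    stop = next_thresh_idx if next_thresh_idx is not None else v.size
    cap = min(stop, e.i_thresh + int(round(DECAY_WINDOW_CAP_MS * fs / 1000.0)), v.size)

    e.max_rise = float(np.max(dv[e.i_thresh : e.i_peak + 1]))
    if cap > e.i_peak:
        e.max_decay = float(np.min(dv[e.i_peak : cap]))

    half = e.threshold_v + e.amplitude / 2.0
    e.half_width = None
    t_up = _crossing_time(v, e.i_thresh, e.i_peak, half, rising=True, dt_ms=dt_ms)
    t_dn = _crossing_time(v, e.i_peak, stop, half, rising=False, dt_ms=dt_ms)
    if t_up is not None and t_dn is not None:
        e.half_width = t_dn - t_up
    return e


def _crossing_time(
    v: np.ndarray, i0: int, i1: int, level: float, rising: bool, dt_ms: float
) -> float | None:
    seg = v[i0 : min(i1 + 1, v.size)]
    if seg.size < 2:
        return None
    if rising:
        hits = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        hits = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if hits.size == 0:
        return None
    j = int(hits[0])
    frac = (level - seg[j]) / (seg[j + 1] - seg[j])
    return (i0 + j + frac) * dt_ms


def ahp_features(
    e: APEvent, v: np.ndarray, fs: float, end_idx: int | None = None
) -> APEvent:
    """Afterhyperpolarization of one AP: trough depth (threshold-referenced,
    negative) and latency from the AP peak.  The search window runs from the
    AP peak to the next AP threshold (or the supplied end index)."""
    stop = end_idx if end_idx is not None else v.size
    if stop <= e.i_peak + 1:
        raise ValueError("empty AHP search window")
    seg = v[e.i_peak + 1 : stop]
    i_min = e.i_peak + 1 + int(np.argmin(seg))
    e.i_ahp = i_min
    e.ahp_v = float(v[i_min] - e.threshold_v)
    e.ahp_latency = (i_min - e.i_peak) * 1000.0 / fs
    return e


def detect_adp(
    v: np.ndarray, fs: float, e: APEvent, end_idx: int | None = None
) -> ADPResult:
    """Detect an afterdepolarization following the AHP of *e* (ct level).

    The post-ADP local minimum is the minimum trace value after the AHP that
    precedes the first negative-to-positive sign change of the slope of the
    8-pole Bessel 50-Hz low-pass filtered (causal) trace.  If a local
    maximum lies between the AHP and that minimum, an ADP is present and its
    integrated amplitude is the mean of the positive part of the trace after
    subtracting the straight line joining the AHP and the local minimum.
    """
    if e.i_ahp is None:
        e = ahp_features(e, v, fs, end_idx)
    i0 = e.i_ahp
    stop = end_idx if end_idx is not None else v.size
    if i0 is None or stop - i0 < 3:
        return ADPResult(present=False)

    # filter only the post-AHP segment (state initialized at the trough):
    # the causal filter's lagged response to the spike itself would
    # otherwise dominate the slope sign changes we are looking for
    sos = signal.bessel(
        ADP_FILTER_ORDER, ADP_FILTER_HZ, btype="low", fs=fs, output="sos"
    )
    zi = signal.sosfilt_zi(sos) * v[i0]
    filt_seg, _ = signal.sosfilt(sos, v[i0:stop], zi=zi)
    filt = np.concatenate([np.full(i0, v[i0]), filt_seg])
    slope = np.diff(filt[i0:stop])
    # the slope's return to >= 0 only counts once a real downslope has
    # occurred: floating-point wiggle on flat segments is not a
    # repolarization, and the filtered slope decays asymptotically so the
    # immediately preceding sample alone cannot carry the test
    tol = 1e-3 * 1000.0 / fs  # 1e-3 mV/ms in per-sample units
    ever_neg = np.logical_or.accumulate(slope < -tol)
    cand = np.flatnonzero((slope[1:] >= 0) & ever_neg[:-1])
    if cand.size == 0:
        return ADPResult(present=False)
    # the post-ADP local minimum sits where the filtered slope turns from
    # negative to positive (the filter is used only to place this endpoint;
    # its lagged response to the spike itself must not define the maximum)
    i_min = i0 + int(cand[0]) + 1
    # presence of a local maximum between the AHP and that minimum is judged
    # on the raw trace with a noise margin
    interior = v[i0 + 1 : i_min]
    if interior.size == 0 or np.max(interior) <= max(v[i0], v[i_min]) + ADP_MARGIN_MV:
        return ADPResult(present=False)
    # baseline: straight line from the AHP trough to the local minimum
    n = i_min - i0
    line = v[i0] + (v[i_min] - v[i0]) * np.arange(n + 1) / n
    resid = v[i0 : i_min + 1] - line
    pos = resid[resid > 0]
    amp = float(np.mean(pos)) if pos.size else 0.0
    return ADPResult(present=amp > 0.0, integrated_amplitude=amp)


def _cv2(isis: np.ndarray) -> float | None:
    """Mean local coefficient of variation over consecutive ISI pairs."""
    if isis.size < 2:
        return None
    a, b = isis[:-1], isis[1:]
    return float(np.mean(2.0 * np.abs(b - a) / (b + a)))


def train_statistics(events: list[APEvent], stim_onset_ms: float) -> TrainStats:
    """Spike-train statistics for one sweep's accepted APs."""
    n = len(events)
    st = TrainStats(n_ap=n)
    if n == 0:
        return st
    st.latency_first_ap = events[0].threshold_time - stim_onset_ms
    if n < 2:
        return st
    peaks = np.array([e.peak_time for e in events])
    amps = np.array(
        [e.amplitude if e.amplitude is not None else np.nan for e in events]
    )
    st.isis = np.diff(peaks)
    st.inst_freqs = 1000.0 / st.isis
    st.initial_inst_freq = float(st.inst_freqs[0])

    st.cv2_all = _cv2(st.isis)
    st.cv2_excl1 = _cv2(st.isis[1:])
    st.cv2_excl2 = _cv2(st.isis[2:])

    if n >= 3:
        st.mean_first2_isi = float(np.mean(st.isis[:2]))
        st.sd_first2_isi = float(np.std(st.isis[:2], ddof=1))
        st.delta_isi_1_2 = float(st.isis[1] - st.isis[0])
        st.delta_f_1_2 = float(st.inst_freqs[1] - st.inst_freqs[0])
        if np.isfinite(amps[:3]).all():
            st.amp_ratio_2_3 = float(amps[1] / amps[2])
    if np.isfinite(amps[:2]).all():
        st.amp_ratio_1_2 = float(amps[0] / amps[1])
    if n >= 4 and np.isfinite(amps).all():
        st.amp_ratio_1_last3 = float(amps[0] / np.mean(amps[-3:]))
    if n >= 5:
        final = float(np.mean(st.inst_freqs[-3:]))
        st.max_adaptation = st.initial_inst_freq - final
        st.isi_ratio = final / st.initial_inst_freq
    return st


def initial_adaptation_features(
    currents: np.ndarray,
    stats: list[TrainStats],
    ct: float,
    idx_ct: int,
) -> dict[str, float]:
    """Initial-adaptation change over consecutive depolarization steps.

    For consecutive suprathreshold sweeps whose first AP-pair frequency is
    defined, the change of that frequency divided by the current difference
    is computed; the maximum is returned together with the current level
    (relative to ct) at which it occurred.  The second variant ignores pairs
    starting at the ct sweep and pairs that span a single-AP trace.
    """
    entries = [
        (i, float(currents[i]), st.initial_inst_freq, st.n_ap)
        for i, st in enumerate(stats)
        if st.n_ap >= 1 and i >= idx_ct
    ]
    defined = [(i, a, f) for i, a, f, n in entries if f is not None]
    out = {
        "max_init_adapt_change": np.nan,
        "adapt_change_rel_ct": np.nan,
        "init_adapt_change_v2": np.nan,
        "adapt_change_rel_ct_v2": np.nan,
    }
    if len(defined) < 2:
        return out
    single_ap = {i for i, _, f, n in entries if n == 1}
    best_v1 = best_v2 = -np.inf
    lvl_v1 = lvl_v2 = np.nan
    for (i1, a1, f1), (i2, a2, f2) in zip(defined[:-1], defined[1:]):
        if a2 == a1:
            continue
        change = (f2 - f1) / (a2 - a1)
        if change > best_v1:
            best_v1, lvl_v1 = change, a2 / ct
        spans_single = any(i1 < j < i2 for j in single_ap)
        if i1 != idx_ct and not spans_single and change > best_v2:
            best_v2, lvl_v2 = change, a2 / ct
    if np.isfinite(best_v1):
        out["max_init_adapt_change"] = best_v1
        out["adapt_change_rel_ct"] = lvl_v1
    if np.isfinite(best_v2):
        out["init_adapt_change_v2"] = best_v2
        out["adapt_change_rel_ct_v2"] = lvl_v2
    return out


def _level_features(
    s: SweepSet, idx: int, events: list[APEvent], prefix: str
) -> dict[str, float]:
    """Waveform + train features of one stimulus level (first-AP referenced)."""
    v = s.voltages[idx]
    fs = s.sampling_rate
    sl = s.stim_slice()
    out: dict[str, float] = {}
    if not events:
        return out
    nxt = [e.i_thresh for e in events[1:]] + [sl.stop]
    e0 = ap_waveform(events[0], v, fs, next_thresh_idx=nxt[0])
    e0 = ahp_features(e0, v, fs, end_idx=nxt[0])
    for e, stop in zip(events[1:], nxt[1:]):
        ap_waveform(e, v, fs, next_thresh_idx=stop)

    out[f"{prefix}_ap_thresh"] = e0.threshold_v
    out[f"{prefix}_ap_amp"] = e0.amplitude
    out[f"{prefix}_half_width"] = (
        e0.half_width if e0.half_width is not None else np.nan
    )
    out[f"{prefix}_max_rise"] = e0.max_rise
    out[f"{prefix}_max_decay"] = (
        e0.max_decay if e0.max_decay is not None else np.nan
    )
    out[f"{prefix}_ahp_amp"] = e0.ahp_v
    out[f"{prefix}_ahp_lat"] = e0.ahp_latency
    if e0.max_decay not in (None, 0):
        out[f"{prefix}_rise_decay_ratio"] = abs(e0.max_rise / e0.max_decay)
    if e0.amplitude:
        out[f"{prefix}_thresh_amp_ratio"] = e0.threshold_v / e0.amplitude
    if e0.half_width:
        out[f"{prefix}_rise_half_width_ratio"] = e0.max_rise / e0.half_width

    st = train_statistics(events, stim_onset_ms=sl.start * 1000.0 / fs)
    if prefix != "ct":
        out[f"{prefix}_n_ap"] = float(st.n_ap)
        out[f"{prefix}_latency"] = st.latency_first_ap
        pairs = {
            "init_freq": st.initial_inst_freq,
            "adaptation": st.max_adaptation,
            "isi_ratio": st.isi_ratio,
            "mean_first2_isi": st.mean_first2_isi,
            "sd_first2_isi": st.sd_first2_isi,
            "delta_isi_1_2": st.delta_isi_1_2,
            "delta_f_1_2": st.delta_f_1_2,
            "cv2_all": st.cv2_all,
            "cv2_excl1": st.cv2_excl1,
            "cv2_excl2": st.cv2_excl2,
            "amp_ratio_1_2": st.amp_ratio_1_2,
            "amp_ratio_2_3": st.amp_ratio_2_3,
            "amp_ratio_1_last": st.amp_ratio_1_last3,
        }
        for name, val in pairs.items():
            out[f"{prefix}_{name}"] = np.nan if val is None else val
    return out


def extract_features(s: SweepSet, feature_set: int = 38) -> dict[str, float]:
    """Extract the requested canonical property set from a sweep family.

    Returns a dict keyed by registry keys; properties that cannot be
    measured are NaN.  Raises if no sweep fires (no current threshold) or
    the passive fit is impossible.
    """
    if feature_set not in (38, 63):
        raise ValueError("feature_set must be 38 or 63")
    sl = s.stim_slice()
    fs = s.sampling_rate
    per_sweep = [
        detect_aps(v, fs, (sl.start, sl.stop)) for v in s.voltages
    ]
    counts = np.array([len(ev) for ev in per_sweep])
    rmp, rm = passive_properties(s, ap_counts=counts)
    ct, idx_ct, idx_2x, idx_max = current_threshold(s.currents, counts)

    out: dict[str, float] = {"rmp": rmp, "rm": rm, "ct": ct}
    out.update(_level_features(s, idx_ct, per_sweep[idx_ct], "ct"))
    out.update(_level_features(s, idx_2x, per_sweep[idx_2x], "x2"))

    # max-activity block, only meaningful when the f-I curve has saturated
    saturated = counts.size >= 2 and counts[-1] <= counts[-2]
    if feature_set == 63:
        if saturated:
            out.update(_level_features(s, idx_max, per_sweep[idx_max], "max"))
        else:
            warnings.warn(
                "firing frequency did not saturate; max-activity features missing",
                stacklevel=2,
            )

    if feature_set == 38:
        adp = (
            detect_adp(
                s.voltages[idx_ct],
                fs,
                per_sweep[idx_ct][0],
                end_idx=(
                    per_sweep[idx_ct][1].i_thresh
                    if len(per_sweep[idx_ct]) > 1
                    else sl.stop
                ),
            )
            if per_sweep[idx_ct]
            else ADPResult(False)
        )
        out["adp_probability"] = 1.0 if adp.present else 0.0
        out["adp_mean"] = adp.integrated_amplitude
        stats = [
            train_statistics(ev, stim_onset_ms=sl.start * 1000.0 / fs)
            for ev in per_sweep
        ]
        out.update(initial_adaptation_features(s.currents, stats, ct, idx_ct))

    keys = registry.KEYS_38 if feature_set == 38 else registry.KEYS_63
    return {k: float(out.get(k, np.nan)) for k in keys}
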