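"""Synthetic claustrum-neuron data.

Two generators:

* :func:`sample_feature_table` draws per-cell feature vectors from the
  published per-subtype summary statistics (projection-neuron subtypes:
  medians with SD approximated as 1.4826 x MAD; interneuron subtypes:
  means with SD = SEM x sqrt(n), n = 19/28/30 for PV/SST/VIP).  Properties
  are drawn independently (no within-subtype covariances are published);
  strictly positive heavy-tailed properties use a moment-matched log-normal,
  everything else a normal, with physical-range clipping.

* :func:`simulate_sweepset` integrates an adaptive leaky integrate-and-fire
  model (leak + spike-triggered adaptation + optional depolarizing
  after-current for ADP/doublet firing + slowly inactivating onset current
  for delayed firing + stochastic threshold jitter for irregular firing) at
  50 kHz over 1-s current steps and renders spikes with subtype-specific
  waveform templates, exercising the full extraction path.

The six ADP/initial-adaptation properties of the 38-property set have no
per-IN-subtype statistics; interneuron draws for them use the interneuron
population distribution (shared across PV/SST/VIP).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from . import registry
from .io import SweepSet

__all__ = [
    "SubtypePrototype",
    "CohortSpec",
    "prototypes",
    "sample_feature_table",
    "outlier_vip_vector",
    "simulate_trace",
    "simulate_sweepset",
    "default_cohort_spec",
]

PN_SUBTYPES = ["PN1", "PN2", "PN3", "PN4", "PN5"]
IN_SUBTYPES = ["PV", "SST", "VIP"]
IN_SUBTYPE_N = {"PV": 19, "SST": 28, "VIP": 30}
IN_POPULATION_N = 152
MAD_TO_SD = 1.4826

#: clipping bounds applied after sampling (physical ranges)
_CLIP: dict[str, tuple[float, float]] = {
    "adp_probability": (0.0, 1.0),
    "adp_mean": (0.0, np.inf),
    "x2_n_ap": (1.0, np.inf),
    "max_n_ap": (1.0, np.inf),
    "ct_half_width": (0.05, np.inf),
    "x2_half_width": (0.05, np.inf),
    "max_half_width": (0.05, np.inf),
    "ct_ap_amp": (1.0, np.inf),
    "x2_ap_amp": (1.0, np.inf),
    "max_ap_amp": (1.0, np.inf),
    "x2_amp_ratio_1_2": (0.05, np.inf),
    "x2_amp_ratio_2_3": (0.05, np.inf),
    "x2_amp_ratio_1_last": (0.05, np.inf),
    "max_amp_ratio_1_2": (0.05, np.inf),
    "max_amp_ratio_2_3": (0.05, np.inf),
    "max_amp_ratio_1_last": (0.05, np.inf),
    "x2_isi_ratio": (0.0, np.inf),
    "max_isi_ratio": (0.0, np.inf),
}


@dataclass(frozen=True)
class SimulatorParams:
    """Integrate-and-fire parameters realizing one firing phenotype."""

    rest: float            # mV
    rm: float              # MOhm
    tau_m: float           # ms
    thresh: float          # mV
    ahp: float             # mV, trough depth below threshold (negative)
    amp0: float            # mV, first-AP amplitude above threshold
    amp_inf: float         # asymptotic amplitude fraction (amplitude adaptation)
    amp_tau: float         # spikes, amplitude-decay constant
    max_rise: float        # mV/ms, template upstroke slope scale
    max_decay: float       # mV/ms (positive magnitude), downstroke slope scale
    adapt_b: float         # pA, spike-triggered adaptation increment
    adapt_tau: float       # ms
    adp_a: float = 0.0     # pA, depolarizing after-current amplitude
    adp_tau: float = 8.0   # ms
    onset_w: float = 0.0   # pA, slowly inactivating onset (delay) current
    onset_tau: float = 40.0  # ms
    thresh_jitter: float = 0.0  # mV, per-spike threshold SD (irregularity)


@dataclass(frozen=True)
class SubtypePrototype:
    """Per-property (center, scale) pairs plus simulator parameters."""

    name: str
    centers: dict[str, float]
    scales: dict[str, float]
    sim: SimulatorParams | None = None


@dataclass
class CohortSpec:
    """Counts per subtype, seed and feature set of a synthetic cohort."""

    counts: dict[str, int]
    seed: int
    feature_set: int = 38

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.feature_set not in (38, 63):
            raise ValueError("feature_set must be 38 or 63")


def _read_data(name: str) -> list[dict[str, str]]:
    with resources.files("claustrum_ephys.data").joinpath(name).open(
        encoding="utf-8"
    ) as fh:
        return list(csv.DictReader(fh))


_SIM_PRESETS: dict[str, SimulatorParams] = {
    # projection neurons: broad spikes, shallow AHP, modest rates
    "PN1": SimulatorParams(
        rest=-73.9, rm=248, tau_m=25, thresh=-36.1, ahp=-13.0, amp0=81.6,
        amp_inf=0.62, amp_tau=3.0, max_rise=222, max_decay=40,
        adapt_b=30, adapt_tau=250,
    ),
    "PN2": SimulatorParams(
        rest=-74.8, rm=151, tau_m=18, thresh=-32.1, ahp=-13.5, amp0=71.5,
        amp_inf=0.80, amp_tau=4.0, max_rise=191, max_decay=39,
        adapt_b=80, adapt_tau=240, adp_a=60, adp_tau=6,
    ),
    "PN3": SimulatorParams(
        rest=-71.5, rm=219, tau_m=20, thresh=-34.8, ahp=-9.0, amp0=77.2,
        amp_inf=0.85, amp_tau=4.0, max_rise=215, max_decay=44,
        adapt_b=55, adapt_tau=220, adp_a=140, adp_tau=7,
    ),
    "PN4": SimulatorParams(
        rest=-70.5, rm=238, tau_m=22, thresh=-33.1, ahp=-9.5, amp0=73.9,
        amp_inf=0.84, amp_tau=1.5, max_rise=167, max_decay=35,
        adapt_b=50, adapt_tau=200, adp_a=110, adp_tau=7, thresh_jitter=0.8,
    ),
    "PN5": SimulatorParams(
        rest=-68.7, rm=399, tau_m=28, thresh=-33.1, ahp=-10.5, amp0=74.2,
        amp_inf=0.88, amp_tau=4.0, max_rise=164, max_decay=34,
        adapt_b=40, adapt_tau=250, adp_a=45, adp_tau=8,
        onset_w=110, onset_tau=80, thresh_jitter=0.8,
    ),
    # interneurons: PV fast-spiking, SST regular, VIP irregular/excitable
    "PV": SimulatorParams(
        rest=-66.4, rm=159, tau_m=9, thresh=-37.5, ahp=-21.0, amp0=67.6,
        amp_inf=0.92, amp_tau=6.0, max_rise=250, max_decay=127,
        adapt_b=25, adapt_tau=100, thresh_jitter=0.1,
    ),
    "SST": SimulatorParams(
        rest=-62.2, rm=414, tau_m=16, thresh=-33.4, ahp=-19.0, amp0=69.5,
        amp_inf=0.90, amp_tau=5.0, max_rise=182, max_decay=66,
        adapt_b=18, adapt_tau=120, onset_w=25, onset_tau=50, thresh_jitter=0.4,
    ),
    "VIP": SimulatorParams(
        rest=-59.8, rm=653, tau_m=20, thresh=-33.3, ahp=-13.5, amp0=72.4,
        amp_inf=0.85, amp_tau=4.0, max_rise=161, max_decay=48,
        adapt_b=22, adapt_tau=160, onset_w=18, onset_tau=60, thresh_jitter=2.5,
    ),
}


def _build_prototypes() -> dict[str, SubtypePrototype]:
    protos: dict[str, SubtypePrototype] = {}
    pn_rows = _read_data("pn_prototypes.csv")
    for name in PN_SUBTYPES:
        centers = {r["key"]: float(r[f"{name}_median"]) for r in pn_rows}
        scales = {r["key"]: MAD_TO_SD * float(r[f"{name}_mad"]) for r in pn_rows}
        protos[name] = SubtypePrototype(name, centers, scales, _SIM_PRESETS[name])
    protos["outlierVIP"] = SubtypePrototype(
        "outlierVIP",
        {r["key"]: float(r["outlierVIP_value"]) for r in pn_rows},
        {r["key"]: 0.0 for r in pn_rows},
        None,
    )
    in_rows = _read_data("in_prototypes.csv")
    pop_rows = {r["key"]: r for r in _read_data("population.csv")}
    extra_keys = [
        "adp_probability", "adp_mean", "max_init_adapt_change",
        "adapt_change_rel_ct", "init_adapt_change_v2", "adapt_change_rel_ct_v2",
    ]
    for name in IN_SUBTYPES:
        n = IN_SUBTYPE_N[name]
        centers = {r["key"]: float(r[f"{name}_mean"]) for r in in_rows}
        scales = {r["key"]: float(r[f"{name}_sem"]) * np.sqrt(n) for r in in_rows}
        for k in extra_keys:  # population-level fallback, shared across IN subtypes
            centers[k] = float(pop_rows[k]["IN_mean"])
            scales[k] = float(pop_rows[k]["IN_sem"]) * np.sqrt(IN_POPULATION_N)
        protos[name] = SubtypePrototype(name, centers, scales, _SIM_PRESETS[name])
    return protos


_PROTOTYPES: dict[str, SubtypePrototype] | None = None


def prototypes() -> dict[str, SubtypePrototype]:
    global _PROTOTYPES
    if _PROTOTYPES is None:
        _PROTOTYPES = _build_prototypes()
    return _PROTOTYPES


def outlier_vip_vector() -> dict[str, float]:
    """The single outlier VIP interneuron's printed 38-property vector."""
    p = prototypes()["outlierVIP"]
    return {k: p.centers[k] for k in registry.KEYS_38}


def _draw(
    rng: np.random.Generator, key: str, center: float, scale: float, size: int
) -> np.ndarray:
    prop = registry.BY_KEY[key]
    if scale <= 0:
        vals = np.full(size, center)
    elif prop.lognormal and center > 0:
        sigma2 = np.log1p((scale / center) ** 2)
        mu = np.log(center) - sigma2 / 2.0
        vals = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)
    else:
        vals = rng.normal(center, scale, size=size)
    lo, hi = _CLIP.get(key, (-np.inf, np.inf))
    return np.clip(vals, lo, hi)


def sample_feature_table(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Sample a cohort of feature vectors; returns (table, true labels).

    The table is keyed by registry keys plus a ``cell_id`` column; draws are
    independent across properties and reproducible by seed.
    """
    protos = prototypes()
    unknown = set(spec.counts) - set(protos)
    if unknown:
        raise ValueError(f"unknown subtypes: {sorted(unknown)}")
    keys = registry.KEYS_38 if spec.feature_set == 38 else registry.KEYS_63
    rng = np.random.default_rng(spec.seed)
    frames, labels = [], []
    for name in sorted(spec.counts):
        n = spec.counts[name]
        if n == 0:
            continue
        proto = protos[name]
        missing = [k for k in keys if k not in proto.centers]
        if missing:
            raise ValueError(f"prototype {name} lacks properties {missing}")
        cols = {
            k: _draw(rng, k, proto.centers[k], proto.scales[k], n) for k in keys
        }
        df = pd.DataFrame(cols)
        frames.append(df)
        labels.extend([name] * n)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", [f"synth_{i:04d}" for i in range(len(table))])
    return table, pd.Series(labels, name="label")


def default_cohort_spec(kind: str, seed: int, scale: float = 1.0) -> CohortSpec:
    """Study-condition cohort sizes.

    ``population``: 152 interneurons (PV/SST/VIP in 19:28:30 proportion)
    plus 174 projection neurons over the 38-property set; ``pn``: the PN
    half alone; ``in``: the confirmed-interneuron cohort (19/28/30) over the
    63-property set, optionally scaled up.
    """
    def scaled(d: dict[str, int]) -> dict[str, int]:
        return {k: int(round(v * scale)) for k, v in d.items()}

    if kind == "population":
        counts = {"PV": 38, "SST": 55, "VIP": 59,
                  "PN1": 35, "PN2": 35, "PN3": 35, "PN4": 35, "PN5": 34}
        return CohortSpec(scaled(counts), seed, feature_set=38)
    if kind == "pn":
        return CohortSpec(
            scaled({"PN1": 35, "PN2": 35, "PN3": 35, "PN4": 35, "PN5": 34}),
            seed, feature_set=38,
        )
    if kind == "in":
        return CohortSpec(
            scaled({"PV": 19, "SST": 28, "VIP": 30}), seed, feature_set=63
        )
    raise ValueError(f"unknown cohort kind '{kind}'")


# ---------------------------------------------------------------------------
# spiking-trace simulator

def _spike_template(
    p: SimulatorParams, amp: float, thresh: float, fs: float
) -> np.ndarray:
    """Render one AP from threshold crossing to AHP trough (sine segments)."""
    peak = thresh + amp
    trough = thresh + p.ahp
    d_rise = amp * np.pi / (2.0 * p.max_rise)          # ms
    d_fall = (peak - trough) * np.pi / (2.0 * p.max_decay)  # ms
    n_r = max(2, int(round(d_rise * fs / 1000.0)))
    n_f = max(2, int(round(d_fall * fs / 1000.0)))
    u_r = np.linspace(0.0, 1.0, n_r, endpoint=False)
    rise = thresh + amp * np.sin(np.pi * u_r / 2.0)
    u_f = np.linspace(0.0, 1.0, n_f, endpoint=True)
    fall = trough + (peak - trough) * 0.5 * (1.0 + np.cos(np.pi * u_f))
    return np.concatenate([rise, fall])


def simulate_trace(
    proto: SubtypePrototype | str,
    current: float,
    seed: int | np.random.Generator = 0,
    fs: float = 50_000.0,
    duration: float = 1.2,
    stim_onset: float = 0.1,
    stim_offset: float = 1.1,
    oversample: int = 1,
    noise_sd: float = 0.15,
) -> np.ndarray:
    """Integrate one current step and return the voltage trace in mV.

    ``oversample`` subdivides each sample interval for the Euler update
    (spike times converge as the step shrinks).
    """
    if isinstance(proto, str):
        proto = prototypes()[proto]
    p = proto.sim
    if p is None:
        raise ValueError(f"no simulator parameters for subtype '{proto.name}'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration * fs))
    dt = 1000.0 / (fs * oversample)  # ms
    if p.tau_m <= dt:
        raise ValueError("unstable parameters: tau_m not resolved by the step")
    i_on, i_off = int(round(stim_onset * fs)), int(round(stim_offset * fs))
    v = np.empty(n)
    vm = p.rest
    w = 0.0          # adaptation current, pA
    i_adp = 0.0      # depolarizing after-current, pA
    onset = 0.0      # inactivating onset current, pA
    k_spike = 0
    thresh_eff = p.thresh + (p.thresh_jitter * rng.standard_normal() if p.thresh_jitter else 0.0)
    paste_until = -1
    template: np.ndarray = np.empty(0)
    paste_start = 0

    decay_w = np.exp(-dt / p.adapt_tau)
    decay_adp = np.exp(-dt / p.adp_tau)
    decay_on = np.exp(-dt / p.onset_tau)
    g = dt / p.tau_m
    # correlated (OU) noise, tau ~0.5 ms: emulates a 10-kHz-filtered baseline
    # without injecting unphysical sample-to-sample derivative noise
    if noise_sd > 0:
        from scipy.signal import lfilter

        a = np.exp(-1000.0 / fs / 0.5)
        white = rng.normal(0.0, noise_sd * np.sqrt(1 - a * a), size=n)
        noise = lfilter([1.0], [1.0, -a], white)
    else:
        noise = np.zeros(n)

    i = 0
    while i < n:
        if i < paste_until:
            v[i] = template[i - paste_start] + noise[i]
            i += 1
            continue
        inj = current if i_on <= i < i_off else 0.0
        if inj and onset == 0.0 and i == i_on and p.onset_w:
            onset = p.onset_w
        for _ in range(oversample):
            i_total = inj - w - onset + i_adp
            vm += g * (p.rest - vm + p.rm * i_total / 1000.0)
            w *= decay_w
            i_adp *= decay_adp
            onset *= decay_on
        v[i] = vm + noise[i]
        if vm >= thresh_eff and i_on <= i < i_off:
            amp = p.amp0 * (p.amp_inf + (1 - p.amp_inf) * np.exp(-k_spike / p.amp_tau))
            template = _spike_template(p, amp, thresh_eff, fs)
            paste_start = i
            paste_until = min(n, i + template.size)
            vm = thresh_eff + p.ahp  # resume from the AHP trough
            w += p.adapt_b
            i_adp += p.adp_a
            k_spike += 1
            thresh_eff = p.thresh + (
                p.thresh_jitter * rng.standard_normal() if p.thresh_jitter else 0.0
            )
        else:
            i += 1
    return v


def expected_ct(proto: SubtypePrototype | str) -> float:
    """Steady-state rheobase of the simulator model, pA."""
    if isinstance(proto, str):
        proto = prototypes()[proto]
    p = proto.sim
    return (p.thresh - p.rest) / p.rm * 1000.0


def default_ladder(proto: SubtypePrototype | str) -> np.ndarray:
    """Current ladder from -60 pA through ~2.6x the model rheobase."""
    ct = expected_ct(proto)
    step = max(5.0, np.round(ct / 4 / 5) * 5)
    ups = np.arange(step, 2.7 * ct + step, step)
    return np.concatenate([[-60.0, -40.0, -20.0], ups])


def simulate_sweepset(
    proto: SubtypePrototype | str,
    ladder: np.ndarray | list[float] | None = None,
    seed: int = 0,
    temperature: float = 24.0,
    cell_id: str | None = None,
    fs: float = 50_000.0,
    **kwargs,
) -> SweepSet:
    """Simulate a full current-step family for one cell."""
    if isinstance(proto, str):
        proto = prototypes()[proto]
    if ladder is None:
        ladder = default_ladder(proto)
    ladder = np.asarray(ladder, dtype=float)
    rng = np.random.default_rng(seed)
    sweeps = [
        simulate_trace(proto, amp, seed=rng, fs=fs, **kwargs) for amp in ladder
    ]
    return SweepSet(
        cell_id=cell_id or f"{proto.name}_sim{seed}",
        currents=ladder,
        voltages=np.vstack(sweeps),
        sampling_rate=fs,
        temperature=temperature,
    )
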