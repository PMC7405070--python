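"""Shared fixtures: synthetic cohorts and simulated recordings."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from claustrum_ephys import features, registry, synth


@pytest.fixture(scope="session")
def population_cohort():
    """Seeded full synthetic cohort (152 IN + 174 PN, 38-property set)."""
    spec = synth.default_cohort_spec("population", seed=1)
    table, labels = synth.sample_feature_table(spec)
    return table, labels


@pytest.fixture(scope="session")
def in_cohort():
    """Seeded interneuron cohort (19 PV / 28 SST / 30 VIP, 63 properties)."""
    spec = synth.default_cohort_spec("in", seed=1)
    return synth.sample_feature_table(spec)


@pytest.fixture(scope="session")
def simulated_cells():
    """One simulated sweep family per subtype preset, with extracted features."""
    out = {}
    for name in ["PV", "SST", "VIP", "PN1", "PN3", "PN5"]:
        s = synth.simulate_sweepset(name, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv = features.extract_features(s, feature_set=38)
        out[name] = (s, fv)
    return out


def make_triangular_spike(
    fs: float = 50_000.0,
    baseline: float = -70.0,
    threshold: float = -35.0,
    peak: float = 40.0,
    after: float = -45.0,
    ramp_slope: float = 5.0,
    rise_ms: float = 0.5,
    fall_ms: float = 1.0,
    tail_ms: float = 40.0,
):
    """Piecewise-linear trace with one idealized spike; returns (v, geometry).

    The subthreshold approach ramps at ``ramp_slope`` mV/ms (below the
    10 mV/ms detection criterion); the rise and fall are straight lines, so
    half-amplitude crossing times have a closed form.
    """
    dt = 1000.0 / fs
    seg_base = np.full(int(5.0 / dt), baseline)
    n_ramp = int(round((threshold - baseline) / ramp_slope / dt))
    seg_ramp = np.linspace(baseline, threshold, n_ramp, endpoint=False)
    n_rise = int(round(rise_ms / dt))
    seg_rise = np.linspace(threshold, peak, n_rise, endpoint=False)
    n_fall = int(round(fall_ms / dt))
    seg_fall = np.linspace(peak, after, n_fall, endpoint=False)
    seg_tail = np.linspace(after, baseline, int(tail_ms / dt))
    v = np.concatenate([seg_base, seg_ramp, seg_rise, seg_fall, seg_tail])
    geometry = {
        "i_corner": seg_base.size + seg_ramp.size,  # exact threshold corner
        "threshold": threshold,
        "peak": peak,
        "rise_ms": rise_ms,
        "fall_ms": fall_ms,
        "after": after,
        "fs": fs,
    }
    return v, geometry


@pytest.fixture()
def triangular_spike():
    return make_triangular_spike()
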