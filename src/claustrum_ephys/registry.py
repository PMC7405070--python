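"""Canonical registry of intrinsic electrical properties.

Every property measured from a current-step family has a stable key (used
internally and in model archives), a printed label per feature set (the
38-property population set and the 63-property interneuron set), a unit and
a stimulus level tag (``global``, ``ct``, ``2xct`` or ``maxap``).

Feature tables on disk use the printed labels; everything in memory is keyed
by the stable keys.  :func:`resolve_label` maps labels (including historical
spelling variants) back to keys.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

REGISTRY_VERSION = "1.0"


@dataclass(frozen=True)
class PropertyDef:
    key: str
    label_38: str | None
    label_63: str | None
    unit: str
    level: str
    lognormal: bool   # strictly positive, heavy-tailed: sampled log-normally
    negative: bool    # sign convention: property is negative-valued

    @property
    def label(self) -> str:
        """Preferred printed label (63-set label if defined, else 38-set)."""
        return self.label_63 or self.label_38  # type: ignore[return-value]


def _load() -> list[PropertyDef]:
    with resources.files("claustrum_ephys.data").joinpath("registry.csv").open(
        encoding="utf-8"
    ) as fh:
        rows = list(csv.DictReader(fh))
    return [
        PropertyDef(
            key=r["key"],
            label_38=r["label_38"] or None,
            label_63=r["label_63"] or None,
            unit=r["unit"],
            level=r["level"],
            lognormal=r["lognormal"] == "1",
            negative=r["negative"] == "1",
        )
        for r in rows
    ]


PROPERTIES: list[PropertyDef] = _load()
BY_KEY: dict[str, PropertyDef] = {p.key: p for p in PROPERTIES}

#: keys of the 38-property population set, in Table order
KEYS_38: list[str] = [p.key for p in PROPERTIES if p.label_38]
#: keys of the 63-property interneuron set, in Table order
KEYS_63: list[str] = [p.key for p in PROPERTIES if p.label_63]
#: union namespace (38-set extras precede nothing new beyond the above)
KEYS_ALL: list[str] = [p.key for p in PROPERTIES]


def labels_for(keys: Iterable[str], feature_set: int = 38) -> list[str]:
    """Printed labels for *keys* in the given feature set (38 or 63)."""
    out = []
    for k in keys:
        p = BY_KEY[k]
        lab = p.label_38 if feature_set == 38 else p.label_63
        out.append(lab or p.label)
    return out


def _norm(label: str) -> str:
    s = label.strip().lower()
    s = re.sub(r"\((mv/ms|hz/pa|mv|ms|hz|pa|mω|mohm)\)", "", s)
    s = s.replace("current threshold", "ct").replace("(ct:", "").replace("(ct", "")
    s = re.sub(r"[^a-z0-9/#]+", "", s)
    return s


# Spelling variants seen across the printed tables, mapped onto the
# normalised form of the canonical label.
_EXTRA_ALIASES: dict[str, str] = {
    # bare short names
    "rmp": "rmp",
    "rm": "rm",
    "ct": "ct",
    "ct)": "ct",
    # ct-level 38-set names without the level prefix handled via label_38
    # 2xct naming variants
    "2xct:adaptation": "x2_adaptation",
    "2xct:maxadaptation": "x2_adaptation",
    "2xct:#ap": "x2_n_ap",
    "2xct:numberofap": "x2_n_ap",
    "2xct:amp1st/2ndap": "x2_amp_ratio_1_2",
    "2xct:1st/2ndapratio": "x2_amp_ratio_1_2",
    "2xct:amp2nd/3rdap": "x2_amp_ratio_2_3",
    "2xct:2nd/3rdapratio": "x2_amp_ratio_2_3",
    "2xct:amp1st/lastap": "x2_amp_ratio_1_last",
    "2xct:1st/lastapratio": "x2_amp_ratio_1_last",
    "2xct:ahpamplitudelatency": "x2_ahp_lat",
    "2xct:averageinitialburstintervafirst3ap": "x2_mean_first2_isi",
    "2xct:averageinitialburstintervalfirst3ap": "x2_mean_first2_isi",
    "2xct:sdofaverageinitialburstintervalfirst3ap": "x2_sd_first2_isi",
    "2xct:sdofaverageinitialburstintervfirst3ap": "x2_sd_first2_isi",
    "2xct:changeofinitialinterspikeinterval": "x2_delta_isi_1_2",
    "2xct:changeofisidurationfrom1stto2ndap": "x2_delta_isi_1_2",
    "2xct:initialchangeofinstantfrequency": "x2_delta_f_1_2",
    "2xct:changeofinstantfrequencyfrom1stto2ndappair": "x2_delta_f_1_2",
    "maxap:changeofinstantaneousfrequencyfrom1stto2ndappair": "max_delta_f_1_2",
    "maxap:1st/2ndapratio": "max_amp_ratio_1_2",
    "maxap:2nd/3rdapratio": "max_amp_ratio_2_3",
    "maxap:latencytofirstap": "max_latency",
    "maxinitialadaptationchange": "max_init_adapt_change",
    "initialadaptationchange(2)": "init_adapt_change_v2",
    "initialadaptationchange2": "init_adapt_change_v2",
    "maxadaptationchangerelativetoct": "adapt_change_rel_ct",
    "maxadaptationchangerelativetoct(2)": "adapt_change_rel_ct_v2",
    "maxadaptationchangerelativetoct2": "adapt_change_rel_ct_v2",
    "adpprobability": "adp_probability",
    "meanadpvalue": "adp_mean",
}


def _build_alias_map() -> dict[str, str]:
    amap: dict[str, str] = {}
    for p in PROPERTIES:
        for lab in (p.label_38, p.label_63):
            if lab:
                amap[_norm(lab)] = p.key
    for p in PROPERTIES:
        # ct-level 38-set names are printed without the "ct:" prefix; also
        # accept the prefixed/unprefixed twin of whichever form is canonical.
        if p.level == "ct" and p.label_63:
            amap.setdefault(_norm(p.label_63).replace("ct:", "", 1), p.key)
    for alias, key in _EXTRA_ALIASES.items():
        amap[_norm(alias) if "(" in alias else alias] = key
        amap[alias] = key
    return amap


_ALIAS_MAP = _build_alias_map()


def resolve_label(label: str) -> str | None:
    """Map a printed column label (or known variant) to a registry key."""
    if label in BY_KEY:
        return label
    return _ALIAS_MAP.get(_norm(label))
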