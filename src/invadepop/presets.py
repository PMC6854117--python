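"""Built-in demographic-model presets for the four freshwater-invasion
scenarios.

The nine sampled populations are DT, PY, NY, LA, CH, TH, HZ, GY (lake
residents) and SH (anadromous).  ``A`` is the terminal ancestral population;
``R`` / ``R1`` / ``R2`` are unsampled resident ancestors.

* ``model1`` - every resident population splits directly from the anadromous
  lineage at a single time T1.
* ``model2`` - residents descend from one common resident ancestor R that
  split from the anadromous lineage at T1; R fans out at T2.
* ``model3`` - two independent invasions: a deep one (R1 -> DT, PY, NY;
  times T1, T2) and a shallow one (R2 -> LA, CH, TH, HZ, GY; times T3, T4).
* ``model4`` - model3 plus 28 directed migration rates over 14 adjacent
  population pairs.

Default numeric values are placeholders calibrated to reproduce the shape of
the study data (per-population diversity around 1e-3 to 3e-3 per site, a
deep versus shallow invasion-depth contrast, and about 4.6 SNPs per variable
capture region at full scale); they are not fitted values.  Every numeric
parameter is overridable.

Free-parameter counts are 10 / 11 / 13 / 41: the per-population sizes plus
the divergence times (plus the migration rates in model4); ancestral sizes
are tied to N_SH unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescent import DemographicModel, Fusion

POPULATIONS = ["DT", "PY", "NY", "LA", "CH", "TH", "HZ", "GY", "SH"]
DEEP_CLUSTER = ["DT", "PY", "NY"]
SHALLOW_CLUSTER = ["LA", "CH", "TH", "HZ", "GY"]

#: diploid individuals sampled per population in the study
STUDY_SAMPLE_SIZES = {"DT": 18, "PY": 21, "NY": 19, "LA": 9, "CH": 19,
                      "TH": 21, "HZ": 10, "GY": 8, "SH": 13}

#: 14 adjacent population pairs (configurable at call sites)
ADJACENT_PAIRS = [
    ("DT", "PY"), ("PY", "NY"), ("NY", "TH"), ("SH", "CH"), ("SH", "TH"),
    ("SH", "DT"), ("SH", "PY"), ("SH", "NY"), ("SH", "GY"), ("CH", "TH"),
    ("HZ", "GY"), ("HZ", "SH"), ("LA", "CH"), ("LA", "TH"),
]

_DEFAULT_SIZES = {
    "N_DT": 14000.0, "N_PY": 12500.0, "N_NY": 17000.0, "N_LA": 15000.0,
    "N_CH": 20500.0, "N_TH": 30000.0, "N_HZ": 17000.0, "N_GY": 17000.0,
    "N_SH": 28500.0,
}

_DEFAULT_TIMES = {"T1": 36000.0, "T2": 12000.0, "T3": 1070.0, "T4": 1030.0}

_DEFAULT_MUTATION = {"mu": 2.5e-8, "n_regions": 2869, "region_length": 214,
                     "generation_time": 3.0}


@dataclass
class ModelPreset:
    """A named scenario: parameter defaults plus a builder closure."""

    name: str
    defaults: dict
    free: list
    description: str = ""

    def params(self, overrides: dict = None) -> dict:
        p = dict(self.defaults)
        if overrides:
            unknown = set(overrides) - set(p)
            if unknown:
                raise KeyError(f"unknown parameters for {self.name}: {sorted(unknown)}")
            p.update(overrides)
        return p

    def build(self, overrides: dict = None) -> DemographicModel:
        return _BUILDERS[self.name](self.params(overrides))

    @property
    def d(self) -> int:
        return len(self.free)


def _sizes_from(params: dict) -> dict:
    sizes = {p: float(params[f"N_{p}"]) for p in POPULATIONS}
    n_sh = sizes["SH"]
    for anc in ("A", "R", "R1", "R2"):
        key = f"N_{anc}"
        if key in params and params[key] is not None:
            sizes[anc] = float(params[key])
        else:
            sizes[anc] = n_sh
    return sizes


def _mutation_kwargs(params: dict) -> dict:
    return {k: params[k] for k in ("mu", "n_regions", "region_length", "generation_time")}


def _ordered(events) -> list:
    return sorted(events, key=lambda e: e.time)


def _build_model1(params: dict) -> DemographicModel:
    sizes = _sizes_from(params)
    t1 = float(params["T1"])
    events = [Fusion(time=t1, source=p, sink="SH") for p in POPULATIONS if p != "SH"]
    events.append(Fusion(time=t1 + 1.0, source="SH", sink="A"))
    pops = POPULATIONS + ["A"]
    return DemographicModel(pop_names=pops, sizes={p: sizes[p] for p in pops},
                            events=_ordered(events), **_mutation_kwargs(params))


def _build_model2(params: dict) -> DemographicModel:
    sizes = _sizes_from(params)
    t1, t2 = float(params["T1"]), float(params["T2"])
    t1 = max(t1, t2 + 1.0)  # keep the fan-out below the invasion split
    events = [Fusion(time=t2, source=p, sink="R") for p in POPULATIONS if p != "SH"]
    events.append(Fusion(time=t1, source="R", sink="A"))
    events.append(Fusion(time=t1 + 1.0, source="SH", sink="A"))
    pops = POPULATIONS + ["R", "A"]
    return DemographicModel(pop_names=pops, sizes={p: sizes[p] for p in pops},
                            events=_ordered(events), **_mutation_kwargs(params))


def _model3_events(params: dict):
    t1, t2 = float(params["T1"]), float(params["T2"])
    t3, t4 = float(params["T3"]), float(params["T4"])
    t3 = max(t3, t4 + 1.0)   # shallow fan-out precedes the shallow invasion
    t1 = max(t1, t2 + 1.0, t3 + 1.0)
    events = [Fusion(time=t4, source=p, sink="R2") for p in SHALLOW_CLUSTER]
    events.append(Fusion(time=t3, source="R2", sink="SH"))
    events += [Fusion(time=t2, source=p, sink="R1") for p in DEEP_CLUSTER]
    events.append(Fusion(time=t1, source="R1", sink="A"))
    events.append(Fusion(time=t1 + 1.0, source="SH", sink="A"))
    return events


def _build_model3(params: dict) -> DemographicModel:
    sizes = _sizes_from(params)
    pops = POPULATIONS + ["R1", "R2", "A"]
    return DemographicModel(pop_names=pops, sizes={p: sizes[p] for p in pops},
                            events=_ordered(_model3_events(params)),
                            **_mutation_kwargs(params))


def _build_model4(params: dict) -> DemographicModel:
    sizes = _sizes_from(params)
    pops = POPULATIONS + ["R1", "R2", "A"]
    k = len(pops)
    idx = {p: i for i, p in enumerate(pops)}
    mig = np.zeros((k, k))
    for a, b in ADJACENT_PAIRS:
        mig[idx[a], idx[b]] = float(params[f"m_{a}_{b}"])
        mig[idx[b], idx[a]] = float(params[f"m_{b}_{a}"])
    return DemographicModel(pop_names=pops, sizes={p: sizes[p] for p in pops},
                            events=_ordered(_model3_events(params)),
                            migration=mig, **_mutation_kwargs(params))


_BUILDERS = {
    "model1": _build_model1,
    "model2": _build_model2,
    "model3": _build_model3,
    "model4": _build_model4,
}


def _migration_defaults() -> dict:
    out = {}
    for a, b in ADJACENT_PAIRS:
        out[f"m_{a}_{b}"] = 1e-5
        out[f"m_{b}_{a}"] = 1e-5
    return out


def get_preset(name: str) -> ModelPreset:
    size_names = [f"N_{p}" for p in POPULATIONS]
    common = {**_DEFAULT_SIZES, **_DEFAULT_MUTATION}
    if name == "model1":
        return ModelPreset(
            name=name,
            defaults={**common, "T1": _DEFAULT_TIMES["T1"]},
            free=size_names + ["T1"],
            description="all resident populations split from the anadromous "
                        "population at once",
        )
    if name == "model2":
        return ModelPreset(
            name=name,
            defaults={**common, "T1": _DEFAULT_TIMES["T1"], "T2": _DEFAULT_TIMES["T2"]},
            free=size_names + ["T1", "T2"],
            description="one invasion through a common resident ancestor",
        )
    if name == "model3":
        return ModelPreset(
            name=name,
            defaults={**common, **_DEFAULT_TIMES},
            free=size_names + ["T1", "T2", "T3", "T4"],
            description="two independent freshwater invasions",
        )
    if name == "model4":
        mig = _migration_defaults()
        return ModelPreset(
            name=name,
            defaults={**common, **_DEFAULT_TIMES, **mig},
            free=size_names + ["T1", "T2", "T3", "T4"] + sorted(mig),
            description="two invasions with migration between adjacent populations",
        )
    raise KeyError(f"unknown preset {name!r}; choose from model1..model4")


def preset_names() -> list:
    return ["model1", "model2", "model3", "model4"]
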