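"""Synthetic-data generator for the whole pipeline.

Every stage of the assessment can be exercised without laboratory data:
this module draws sediment chemistry tables, extract dose-response
series, comet nucleoid sets and per-individual biomarker panels with the
statistical structure the analysis assumes, under a single seed.

The generator encodes an estuarine study design with three site
archetypes:

* ``reference`` -- low contamination on every analyte (total SQG-Q
  below the 0.1 unimpacted threshold),
* ``industrial`` -- high metals and high PAH (harbour/industrial belt),
* ``riverine`` -- moderate metals, low PAH (agricultural, river-fed).

Dose-response truth is log-logistic with EC50s in the tens-to-hundreds
of mg SEQ/mL and a maximal %DNA in tail near 30%, matching the scale of
the in-vitro assays; FPG-treated series carry a lower truth EC50 than
their paired standard series (oxidative lesions add to strand breaks).
Biomarker individuals are lognormal around station-specific medians; the
GSH/GSSG ratio is built from separate total-glutathione and GSSG draws
as GSH/(GSSG/2) rather than drawn directly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseSeries, log_logistic

DEFAULT_DOSES = (0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0)

#: baseline analyte means for the reference archetype (units as the
#: marine PEL table: metals ug/g, organics ng/g dry weight)
_REFERENCE_MEANS = {
    "As": 0.5, "Cr": 3.0, "Ni": 4.0, "Cu": 5.0, "Zn": 15.0, "Cd": 0.03, "Pb": 4.0,
    "tPAH": 20.0, "tDDT": 0.05, "tPCB": 0.06,
}
_ANALYTE_CLASS = {a: ("organic" if a.startswith("t") else "metal")
                  for a in _REFERENCE_MEANS}


@dataclass
class SiteArchetype:
    """Multipliers applied to the reference baseline per contaminant class."""

    name: str
    metal_multiplier: float
    organic_multiplier: float

    def __post_init__(self):
        if self.metal_multiplier <= 0 or self.organic_multiplier <= 0:
            raise ValueError("archetype multipliers must be positive")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, fixed by one seed."""

    seed: int = 0
    archetypes: list = field(default_factory=lambda: [
        SiteArchetype("R", 1.0, 1.0),
        SiteArchetype("N1", 14.0, 60.0),
        SiteArchetype("N2", 13.0, 50.0),
        SiteArchetype("S1", 9.0, 10.0),
        SiteArchetype("S2", 11.0, 4.0),
    ])
    chemistry_cv: float = 0.15
    doses: tuple = DEFAULT_DOSES
    # truth EC50 (mg SEQ/mL) per (site, fraction) for the tail endpoint,
    # standard comet; FPG-treated series divide these by fpg_ec50_factor.
    ec50_truth: dict = field(default_factory=lambda: {
        ("N1", 1): 80.0, ("N2", 1): 130.0, ("S1", 1): 360.0,
        ("N2", 4): 200.0, ("S1", 4): 220.0,
    })
    slope_truth: float = 2.0
    fpg_ec50_factor: float = 2.5
    max_tail_pct: float = 30.0
    nucleoids_per_gel: int = 50
    gels_per_replicate: int = 2
    replicates: int = 3
    nucleoid_sd: float = 8.0            # %tail units, truncated to [0, 100]
    viability_control_abs: float = 1.0
    viability_cv: float = 0.05
    # biomarker truth: species -> biomarker -> station -> median; scale is
    # the lognormal sigma (on log scale) shared per biomarker
    biomarker_truth: dict = field(default_factory=lambda: {
        "clam": {
            "CAT": {"Reference": 18.0, "Sado 1": 25.0, "Sado 2": 33.0},
            "LPO": {"Reference": 0.001, "Sado 1": 0.002, "Sado 2": 0.003},
        },
        "fish": {
            "CAT": {"Reference": 25.0, "Sado 1": 24.0, "Sado 2": 47.0},
            "GST": {"Reference": 0.21, "Sado 1": 0.12, "Sado 2": 0.31},
            "LPO": {"Reference": 1.05, "Sado 1": 1.76, "Sado 2": 1.26},
        },
        "cuttlefish": {
            "GST": {"Reference": 0.002, "Sado 1": 0.005, "Sado 2": 0.003},
            "GSHt": {"Reference": 0.04, "Sado 1": 0.11, "Sado 2": 0.04},
            "LPO": {"Reference": 0.23, "Sado 1": 0.69, "Sado 2": 0.57},
        },
    })
    gssg_truth: dict = field(default_factory=lambda: {
        # GSSG medians chosen so GSH/(GSSG/2) falls with stress
        "Reference": 0.028, "Sado 1": 0.10, "Sado 2": 0.036,
    })
    biomarker_sigma: float = 0.6        # lognormal shape, ~ Table-2-like CVs
    individuals_per_station: int = 12
    coordinates: dict = field(default_factory=lambda: {
        "R": (2.0, 1.0), "N1": (1.0, 4.5), "N2": (2.2, 5.0),
        "S1": (5.5, 2.0), "S2": (6.5, 1.2),
    })

    def __post_init__(self):
        if 0.0 not in self.doses:
            raise ValueError("dose grid must include the 0 control")
        if self.individuals_per_station < 2:
            raise ValueError("need at least 2 individuals per station")
        names = [a.name for a in self.archetypes]
        if len(names) != len(set(names)):
            raise ValueError("archetype names must be unique")

    def rng(self, *key) -> np.random.Generator:
        """Independent stream for a simulation component, derived from the seed.

        Component keys are folded in through CRC32 so streams are stable
        across processes (Python's builtin hash is salted per run).
        """
        entropy = [self.seed % (2 ** 31)]
        entropy += [zlib.crc32(repr(k).encode()) for k in key]
        return np.random.default_rng(entropy)


def stress_gradient_config(seed: int = 0) -> SimConfig:
    """A clear-gradient scenario for parameter-recovery studies.

    Clam and fish biomarkers roughly double per step along
    Reference < Sado 1 < Sado 2 while cuttlefish responses peak at
    Sado 1, preserving the study's qualitative species pattern.  The
    configured truth-level global IBR ranking is
    Sado 2 > Sado 1 > Reference with a wide margin, so recovery failures
    indicate pipeline defects rather than an ambiguous truth.
    """
    truth = {
        "clam": {
            "CAT": {"Reference": 12.0, "Sado 1": 25.0, "Sado 2": 50.0},
            "LPO": {"Reference": 0.001, "Sado 1": 0.002, "Sado 2": 0.005},
        },
        "fish": {
            "CAT": {"Reference": 15.0, "Sado 1": 30.0, "Sado 2": 60.0},
            "GST": {"Reference": 0.08, "Sado 1": 0.16, "Sado 2": 0.35},
            "LPO": {"Reference": 0.6, "Sado 1": 1.2, "Sado 2": 2.5},
        },
        "cuttlefish": {
            "GST": {"Reference": 0.002, "Sado 1": 0.005, "Sado 2": 0.0035},
            "GSHt": {"Reference": 0.04, "Sado 1": 0.10, "Sado 2": 0.07},
            "LPO": {"Reference": 0.2, "Sado 1": 0.6, "Sado 2": 0.45},
        },
    }
    gssg = {"Reference": 0.028, "Sado 1": 0.09, "Sado 2": 0.055}
    return SimConfig(seed=seed, biomarker_truth=truth, gssg_truth=gssg)


def simulate_chemistry(config: SimConfig) -> pd.DataFrame:
    """Long chemistry table (site, analyte, mean, sd, units) from archetypes.

    Per-analyte site means are lognormal draws around the archetype
    target (baseline x class multiplier) with coefficient of variation
    ``chemistry_cv``; the reported sd mimics triplicate analytics.
    """
    rng = config.rng("chemistry")
    sigma = np.sqrt(np.log1p(config.chemistry_cv ** 2))
    rows = []
    for arch in config.archetypes:
        for analyte, base in _REFERENCE_MEANS.items():
            mult = (arch.metal_multiplier if _ANALYTE_CLASS[analyte] == "metal"
                    else arch.organic_multiplier)
            target = base * mult
            mean = float(rng.lognormal(np.log(target) - sigma ** 2 / 2, sigma))
            sd = float(abs(rng.normal(0, 0.1 * mean)) + 0.02 * mean)
            rows.append({"site": arch.name, "analyte": analyte, "mean": mean,
                         "sd": sd,
                         "units": "ug/g" if _ANALYTE_CLASS[analyte] == "metal" else "ng/g"})
    return pd.DataFrame(rows)


def _truth_ec50(config: SimConfig, site: str, fraction: int, fpg: bool) -> float:
    key = (site, fraction)
    if key not in config.ec50_truth:
        raise KeyError(f"no truth EC50 configured for site/fraction {key}")
    ec50 = config.ec50_truth[key]
    return ec50 / config.fpg_ec50_factor if fpg else ec50


def simulate_dose_response(config: SimConfig, site: str, fraction: int,
                           endpoint: str = "tail_pct",
                           fpg: bool = False) -> DoseResponseSeries:
    """One synthetic dose-response series around the configured truth.

    ``tail_pct``: per-replicate mean %tail values from truncated-normal
    nucleoid noise around the increasing log-logistic mean (responses on
    the raw %tail scale, 0 to ``max_tail_pct``).  ``viability_pct``:
    percent-of-control responses from Gaussian plate noise on the
    absorbances.
    """
    rng = config.rng("dose_response", site, fraction, endpoint, fpg)
    ec50 = _truth_ec50(config, site, fraction, fpg)
    doses = np.asarray(config.doses, dtype=float)
    rows = []
    if endpoint == "tail_pct":
        # increasing curve: slope sign negative in the fixed-asymptote form
        mean_curve = log_logistic(doses, ec50, -config.slope_truth,
                                  lower=0.0, upper=config.max_tail_pct)
        n_nuc = config.nucleoids_per_gel * config.gels_per_replicate
        for rep in range(1, config.replicates + 1):
            for d, mu in zip(doses, mean_curve):
                nuc = rng.normal(mu, config.nucleoid_sd, size=n_nuc)
                nuc = np.clip(nuc, 0.0, 100.0)
                rows.append({"concentration": d, "replicate": rep,
                             "response": float(nuc.mean())})
    elif endpoint == "viability_pct":
        mean_curve = log_logistic(doses, ec50, config.slope_truth,
                                  lower=0.0, upper=100.0)
        for rep in range(1, config.replicates + 1):
            for d, mu in zip(doses, mean_curve):
                abs_treated = rng.normal(config.viability_control_abs * mu / 100.0,
                                         config.viability_cv * config.viability_control_abs)
                rows.append({"concentration": d, "replicate": rep,
                             "response": float(max(abs_treated, 0.0)
                                               / config.viability_control_abs * 100.0)})
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return DoseResponseSeries(site=site, fraction=fraction, endpoint=endpoint,
                              fpg=fpg, observations=pd.DataFrame(rows))


def simulate_nucleoids(config: SimConfig, site: str, fraction: int,
                       fpg: bool = False) -> pd.DataFrame:
    """Per-nucleoid comet table (one row per nucleoid) for the KW workflow."""
    rng = config.rng("nucleoids", site, fraction, fpg)
    ec50 = _truth_ec50(config, site, fraction, fpg)
    doses = np.asarray(config.doses, dtype=float)
    mean_curve = log_logistic(doses, ec50, -config.slope_truth,
                              lower=0.0, upper=config.max_tail_pct)
    rows = []
    for d, mu in zip(doses, mean_curve):
        for rep in range(1, config.replicates + 1):
            for gel in range(1, config.gels_per_replicate + 1):
                nuc = np.clip(rng.normal(mu, config.nucleoid_sd,
                                         size=config.nucleoids_per_gel), 0.0, 100.0)
                for v in nuc:
                    rows.append({"site": site, "fraction": fraction, "fpg": fpg,
                                 "concentration": d, "replicate": rep, "gel": gel,
                                 "tail_pct": float(v)})
    return pd.DataFrame(rows)


def simulate_biomarkers(config: SimConfig) -> pd.DataFrame:
    """Per-individual biomarker table (station, species, biomarker, individual, value).

    Values are lognormal around the configured station medians.  The
    cuttlefish GSH/GSSG ratio is derived per individual from its GSHt
    and GSSG draws as GSH/(GSSG/2) with GSH = GSHt - GSSG (truncated
    at a small positive floor), so ratio noise propagates realistically.
    """
    rng = config.rng("biomarkers")
    sigma = config.biomarker_sigma
    n = config.individuals_per_station
    rows = []
    for species, biomarkers in config.biomarker_truth.items():
        stations = list(next(iter(biomarkers.values())))
        draws = {}
        for bm, medians in biomarkers.items():
            for st in stations:
                if medians[st] <= 0:
                    raise ValueError(f"nonpositive median for {species}/{bm}/{st}")
                draws[(bm, st)] = rng.lognormal(np.log(medians[st]), sigma, size=n)
        if species == "cuttlefish":
            for st in stations:
                gsht = draws[("GSHt", st)]
                gssg = rng.lognormal(np.log(config.gssg_truth[st]), sigma, size=n)
                gsh = np.maximum(gsht - gssg, 0.05 * gsht)
                draws[("GSH/GSSG", st)] = gsh / (gssg / 2.0)
        for (bm, st), values in draws.items():
            for i, v in enumerate(values, start=1):
                rows.append({"station": st, "species": species, "biomarker": bm,
                             "individual": i, "value": float(v)})
    return pd.DataFrame(rows)


def aggregate_biomarkers(individuals: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-individual rows to the panel format (mean, sd, n)."""
    grouped = individuals.groupby(["station", "species", "biomarker"], sort=False)
    panel = grouped["value"].agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    return panel.reset_index()


def simulate_bundle(config: SimConfig, out_dir) -> dict:
    """Write the four pipeline input CSVs plus a manifest; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    chem = simulate_chemistry(config)
    paths["chemistry"] = out / "chemistry.csv"
    chem.to_csv(paths["chemistry"], index=False)

    dr_frames = []
    for (site, fraction) in sorted(config.ec50_truth):
        for fpg in (False, True):
            series = simulate_dose_response(config, site, fraction,
                                            endpoint="tail_pct", fpg=fpg)
            df = series.observations.copy()
            df.insert(0, "fpg", fpg)
            df.insert(0, "endpoint", "tail_pct")
            df.insert(0, "fraction", fraction)
            df.insert(0, "site", site)
            dr_frames.append(df)
    paths["dose_response"] = out / "dose_response.csv"
    pd.concat(dr_frames, ignore_index=True).to_csv(paths["dose_response"], index=False)

    individuals = simulate_biomarkers(config)
    paths["biomarkers"] = out / "biomarkers.csv"
    individuals.to_csv(paths["biomarkers"], index=False)

    coords = pd.DataFrame([{"site": s, "x": xy[0], "y": xy[1]}
                           for s, xy in config.coordinates.items()])
    paths["coordinates"] = out / "coordinates.csv"
    coords.to_csv(paths["coordinates"], index=False)

    manifest = {
        "seed": config.seed,
        "doses": list(config.doses),
        "ec50_truth": {f"{s}/f{f}": v for (s, f), v in config.ec50_truth.items()},
        "fpg_ec50_factor": config.fpg_ec50_factor,
        "max_tail_pct": config.max_tail_pct,
        "archetypes": [dataclasses.asdict(a) for a in config.archetypes],
        "files": {k: p.name for k, p in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = manifest_path
    return paths
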