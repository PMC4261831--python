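"""Sediment quality guideline quotients (SQG-Q).

Sediment contaminant concentrations are contrasted to probable effects
level (PEL) guidelines: each analyte contributes a quotient
``concentration / PEL``, quotients are averaged per contaminant class
(metals/metalloids, organics) and over all PEL-bearing analytes, and the
pooled mean classifies the sediment as unimpacted (SQG-Q < 0.1),
moderately impacted (0.1 <= SQG-Q <= 1) or highly impacted (SQG-Q > 1).

The bundled default guideline table carries marine PELs for seven
metals/metalloids (As, Cr, Ni, Cu, Zn, Cd, Pb) and three organic groups
(total PAH, total DDT, total PCB).  Selenium has no PEL and is skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .exceptions import EmptyClassError, GuidelineError

logger = logging.getLogger(__name__)

IMPACT_UNIMPACTED = "unimpacted"
IMPACT_MODERATE = "moderate"
IMPACT_HIGH = "high"


@dataclass(frozen=True)
class GuidelineEntry:
    """A single analyte guideline: PEL value, units, contaminant class."""

    pel: float
    units: str
    contaminant_class: str

    def __post_init__(self):
        if not self.pel > 0:
            raise GuidelineError(f"PEL must be positive, got {self.pel}")


@dataclass
class GuidelineTable:
    """Analyte -> PEL guideline mapping used as quotient denominators."""

    entries: dict[str, GuidelineEntry] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GuidelineTable":
        """Build from a table with columns analyte, pel, units, class."""
        entries = {}
        for row in frame.to_dict("records"):
            analyte = str(row["analyte"])
            if analyte in entries:
                raise GuidelineError(f"duplicate analyte {analyte!r}")
            entries[analyte] = GuidelineEntry(
                float(row["pel"]), str(row["units"]), str(row["class"]))
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "GuidelineTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def default_marine_pel(cls) -> "GuidelineTable":
        """The bundled marine PEL table (MacDonald-type guidelines)."""
        with resources.files("sedtriad.data").joinpath("pel_marine.csv").open() as fh:
            return cls.from_frame(pd.read_csv(fh))

    def analytes_of_class(self, contaminant_class: str) -> list[str]:
        return [a for a, e in self.entries.items() if e.contaminant_class == contaminant_class]

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.entries


@dataclass
class SedimentChemistry:
    """Per-site analyte concentration summary (mean, optional sd, units)."""

    site: str
    measurements: dict[str, dict]  # analyte -> {mean, sd, units}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "list[SedimentChemistry]":
        """Split a long table (site, analyte, mean, sd, units) into per-site records."""
        out = []
        for site, grp in frame.groupby("site", sort=False):
            meas = {}
            for row in grp.to_dict("records"):
                sd = row.get("sd")
                meas[str(row["analyte"])] = {
                    "mean": float(row["mean"]),
                    "sd": float(sd) if pd.notna(sd) else None,
                    "units": str(row.get("units", "")),
                }
            out.append(cls(site=str(site), measurements=meas))
        return out


@dataclass
class SqgqReport:
    """SQG-Q summary for one site."""

    site: str
    per_analyte_quotients: dict[str, float]
    class_quotients: dict[str, float]
    total_quotient: float
    impact_class: str

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "per_analyte_quotients": self.per_analyte_quotients,
            "class_quotients": self.class_quotients,
            "total_quotient": self.total_quotient,
            "impact_class": self.impact_class,
        }


def pel_quotient(concentration: float, pel: float) -> float:
    """Quotient of a sediment concentration over its probable effects level."""
    if not pel > 0:
        raise GuidelineError(f"PEL must be positive, got {pel}")
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration}")
    return concentration / pel


def _quotients(chem: SedimentChemistry, guidelines: GuidelineTable,
               analytes) -> dict[str, float]:
    out = {}
    for analyte in analytes:
        if analyte not in chem.measurements:
            continue
        if analyte not in guidelines:
            logger.info("analyte %r has no PEL guideline; skipped for site %s",
                        analyte, chem.site)
            continue
        out[analyte] = pel_quotient(chem.measurements[analyte]["mean"],
                                    guidelines.entries[analyte].pel)
    return out


def class_quotient(chem: SedimentChemistry, contaminant_class: str,
                   guidelines: GuidelineTable) -> float:
    """Mean PEL quotient over the analytes of one contaminant class.

    Analytes present in the chemistry but lacking a PEL (e.g. Se) are
    skipped with a log message.
    """
    q = _quotients(chem, guidelines, guidelines.analytes_of_class(contaminant_class))
    if not q:
        raise EmptyClassError(
            f"no analyte of class {contaminant_class!r} with a PEL at site {chem.site}")
    return sum(q.values()) / len(q)


def total_quotient(chem: SedimentChemistry, guidelines: GuidelineTable) -> float:
    """Mean PEL quotient pooled over ALL PEL-bearing analytes.

    This pools metals and organics into a single mean; it is not the mean
    of the class means.
    """
    q = _quotients(chem, guidelines, list(guidelines.entries))
    if not q:
        raise EmptyClassError(f"no analyte with a PEL at site {chem.site}")
    return sum(q.values()) / len(q)


def classify_impact(q: float) -> str:
    """Impact class from a total SQG-Q.

    q < 0.1 -> unimpacted; 0.1 <= q <= 1 -> moderate; q > 1 -> high.
    Boundary values fall in the moderate bin.
    """
    if q < 0:
        raise ValueError(f"SQG-Q must be non-negative, got {q}")
    if q < 0.1:
        return IMPACT_UNIMPACTED
    if q <= 1.0:
        return IMPACT_MODERATE
    return IMPACT_HIGH


def sqgq_report(chem: SedimentChemistry, guidelines: GuidelineTable) -> SqgqReport:
    """Full SQG-Q report for one site: per-analyte, per-class, total, impact class."""
    per_analyte = _quotients(chem, guidelines, list(guidelines.entries))
    if not per_analyte:
        raise EmptyClassError(f"no analyte with a PEL at site {chem.site}")
    classes = sorted({guidelines.entries[a].contaminant_class for a in per_analyte})
    class_q = {c: class_quotient(chem, c, guidelines) for c in classes}
    total = sum(per_analyte.values()) / len(per_analyte)
    return SqgqReport(
        site=chem.site,
        per_analyte_quotients=per_analyte,
        class_quotients=class_q,
        total_quotient=total,
        impact_class=classify_impact(total),
    )


def sqgq_table(chemistry: "list[SedimentChemistry]",
               guidelines: GuidelineTable) -> pd.DataFrame:
    """SQG-Q summary table for several sites (one row per site)."""
    rows = []
    for chem in chemistry:
        rep = sqgq_report(chem, guidelines)
        row = {"site": rep.site}
        row.update({f"sqgq_{c}": v for c, v in rep.class_quotients.items()})
        row["sqgq_total"] = rep.total_quotient
        row["impact_class"] = rep.impact_class
        rows.append(row)
    return pd.DataFrame(rows)
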