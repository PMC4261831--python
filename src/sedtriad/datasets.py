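"""Bundled example data: the Sado estuary case study tables.

These are the printed summary tables of the underlying field study —
sediment chemistry for five sites (R, N1, N2, S1, S2), the nine-row
three-station biomarker panel for clam, sole and cuttlefish, and the
EC50 tables for the neutral-red and (FPG-modified) comet assays — plus
a *synthetic* planar coordinate layout for the sites (the study's true
coordinates are not part of the bundle).

`build_loe_matrix` assembles the sites-x-endpoints lines-of-evidence
matrix that feeds clustering and mapping: SQG-Q indices computed from
the chemistry, EC50-derived potencies, and the IBR per area attached to
its sites (fish/cuttlefish reference animals are allocated to site R).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import ibr as ibr_mod
from .integrate import ec50_to_potency
from .sqgq import GuidelineTable, SedimentChemistry, sqgq_table

#: which area's IBR each site inherits
SITE_AREA = {"R": "Reference", "N1": "Sado 1", "N2": "Sado 1",
             "S1": "Sado 2", "S2": "Sado 2"}
SITE_ORDER = ["R", "N1", "N2", "S1", "S2"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("sedtriad.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_guidelines() -> GuidelineTable:
    """The bundled marine PEL guideline table."""
    return GuidelineTable.default_marine_pel()


def load_sediment_chemistry(as_records: bool = True):
    """Per-site sediment contaminant summary (metals ug/g, organics ng/g dw)."""
    frame = _read("sado_sediment_chemistry.csv")
    return SedimentChemistry.from_frame(frame) if as_records else frame


def load_biomarker_panel() -> pd.DataFrame:
    """Three-station biomarker panel (station, species, biomarker, mean, sd)."""
    return _read("sado_biomarkers.csv")


def load_ec50_estimates() -> pd.DataFrame:
    """EC50 tables for the viability, comet and FPG-comet assays.

    ``status`` distinguishes estimable entries from "-" (no estimate at
    the tested doses, ``nd``) and not-assayed cells (``na``).
    """
    return _read("sado_ec50.csv")


def load_site_coordinates() -> pd.DataFrame:
    """Synthetic planar site layout (site, x, y); not the study's geography."""
    return _read("sado_sites_synthetic_coords.csv")


def _potency_column(ec50: pd.DataFrame, assay: str, fraction: int) -> pd.Series:
    sub = ec50[(ec50["assay"] == assay) & (ec50["fraction"] == fraction)]
    sub = sub.set_index("site").reindex(SITE_ORDER)
    values = sub["ec50"].to_numpy(dtype=float)   # NaN where non-estimable
    return pd.Series(ec50_to_potency(values), index=SITE_ORDER)


def build_loe_matrix(ibr_method: str = "pooled_total") -> pd.DataFrame:
    """Sites-x-endpoints matrix combining the three lines of evidence.

    Columns: total/metal/organic SQG-Q, strand-break potency (comet,
    fraction 1), oxidative strand-break potencies (FPG comet, fractions
    1 and 4), and the global IBR of each site's area computed from the
    bundled panel.
    """
    chem = load_sediment_chemistry()
    sq = sqgq_table(chem, load_guidelines()).set_index("site").reindex(SITE_ORDER)

    ec50 = load_ec50_estimates()
    panel = load_biomarker_panel()
    res = ibr_mod.global_ibr(panel, method=ibr_method)
    ibr_by_site = pd.Series({s: res.ibr[SITE_AREA[s]] for s in SITE_ORDER})

    matrix = pd.DataFrame({
        "sqgq_total": sq["sqgq_total"],
        "sqgq_metal": sq["sqgq_metal"],
        "sqgq_organic": sq["sqgq_organic"],
        "potency_sb_f1": _potency_column(ec50, "comet", 1),
        "potency_oxsb_f1": _potency_column(ec50, "comet_fpg", 1),
        "potency_oxsb_f4": _potency_column(ec50, "comet_fpg", 4),
        "ibr_ox": ibr_by_site,
    })
    matrix.index.name = "site"
    return matrix
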