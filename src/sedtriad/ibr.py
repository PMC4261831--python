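"""Integrated Biomarker Response (IBR).

The IBR condenses a battery of biomarkers measured at several stations
into one index per station.  For each biomarker the station means are
standardized to deviation scores Y, the sign is flipped for biomarkers
that *decrease* under stress (Z = +/-Y), and partial scores
S = Z + |min Z| are formed so the least-stressed station scores exactly
zero.  The k partial scores of a station are laid out as radii of a star
plot (angle 2*pi/k between consecutive biomarkers); the area between
consecutive radii is

    A_i = S_i * S_{i+1} * sin(2*pi/k) / 2        (wrapping around)

and the station's IBR is the sum of the A_i.  No division by the number
of biomarkers is applied, so IBR values are comparable only within a
panel of fixed composition.  Because adjacency matters, the IBR depends
on the star order up to rotation/reflection; an order-sensitivity helper
quantifies that dependence.

Two standardizations are offered.  ``across_station_means`` uses the
mean and sample SD of the station means alone.  ``pooled_total``
(default) pools the within-station variances with the between-station
variance of the means --- the spread of the underlying individuals, not
just of the means --- which damps biomarkers whose stations differ by
much less than their biological variability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IncompletePanelError

INCREASES = "increases_with_stress"
DECREASES = "decreases_with_stress"

#: default direction registry: oxidative-stress biomarkers rise under
#: stress except the reduced/oxidized glutathione ratio, which falls as
#: GSH is consumed.
DEFAULT_DIRECTIONS = {"GSH/GSSG": DECREASES}


@dataclass(frozen=True)
class BiomarkerSpec:
    """Identity and stress-response direction of one biomarker in one species."""

    species: str
    name: str
    direction: str = INCREASES
    units: str = ""

    def __post_init__(self):
        if self.direction not in (INCREASES, DECREASES):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def id(self) -> str:
        return f"{self.species}:{self.name}"


@dataclass
class IbrResult:
    """Full IBR decomposition for one panel.

    Attributes
    ----------
    scores : DataFrame, biomarkers (star order) x stations, partial scores S
    areas : DataFrame, star segments x stations, A_i (leading vertex = row)
    ibr : Series, global IBR per station
    species_scores : DataFrame, species x stations, sum of the A_i whose
        leading vertex belongs to that species (a partition of the global
        star, not species-local stars)
    star_coordinates : DataFrame with columns station, biomarker, angle,
        radius, for star-plot export
    """

    scores: pd.DataFrame
    areas: pd.DataFrame
    ibr: pd.Series
    species_scores: pd.DataFrame
    star_coordinates: pd.DataFrame
    standardized: pd.DataFrame = field(default_factory=pd.DataFrame)


def standardize(means, method: str = "pooled_total", sds=None, ns=None) -> np.ndarray:
    """Deviation scores Y for one biomarker's station means.

    ``across_station_means``: Y = (x - m)/s with m, s the mean and sample
    SD (ddof=1) of the station means.  ``pooled_total``: s is the total
    SD of the underlying individuals, sqrt(mean within-station variance
    + population variance of the station means); with station sizes
    ``ns`` the two terms are frequency-weighted, otherwise equal n is
    assumed.  A zero-variance biomarker yields all-zero Y.
    """
    x = np.asarray(means, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs at least 2 stations")
    if method == "across_station_means":
        m = x.mean()
        s = x.std(ddof=1)
    elif method == "pooled_total":
        if sds is None:
            raise ValueError("pooled_total standardization requires station SDs")
        sd = np.asarray(sds, dtype=float)
        if ns is None:
            w = np.full(x.size, 1.0 / x.size)
        else:
            n = np.asarray(ns, dtype=float)
            w = n / n.sum()
        m = float(np.sum(w * x))
        s = math.sqrt(float(np.sum(w * sd ** 2) + np.sum(w * (x - m) ** 2)))
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    if s == 0:
        return np.zeros_like(x)
    return (x - m) / s


def deviation_score(y, direction: str) -> np.ndarray:
    """Direction-adjusted score Z: Y as-is when the biomarker rises under
    stress, -Y when it falls, so larger Z always means more stress."""
    y = np.asarray(y, dtype=float)
    if direction == INCREASES:
        return y
    if direction == DECREASES:
        return -y
    raise ValueError(f"unknown direction {direction!r}")


def partial_scores(z) -> np.ndarray:
    """S = Z + |min Z| over stations; the minimum station scores exactly 0."""
    z = np.asarray(z, dtype=float)
    return z + abs(z.min())


def star_ibr(s, k: int | None = None) -> dict:
    """Star-plot areas and their sum for one station's partial scores.

    ``s`` is the S vector in star order; ``k`` defaults to len(s).  With
    k = 2 the polygon is degenerate (sin(pi) = 0) and the IBR is 0.
    """
    s = np.asarray(s, dtype=float)
    if k is None:
        k = s.size
    if k < 2:
        raise ValueError("a star plot needs at least 2 biomarkers")
    if k == 2:
        warnings.warn("2-biomarker star is degenerate: sin(pi) = 0, IBR = 0",
                      stacklevel=2)
    sin_beta = math.sin(2.0 * math.pi / k)
    areas = s * np.roll(s, -1) * sin_beta / 2.0
    return {"areas": areas, "ibr": float(areas.sum())}


def _panel_matrix(panel: pd.DataFrame, star_order: list | None):
    """Pivot a long panel into biomarker-x-station mean/sd/n matrices in star order."""
    panel = panel.copy()
    panel["biomarker_id"] = panel["species"].astype(str) + ":" + panel["biomarker"].astype(str)
    if star_order is None:
        star_order = list(dict.fromkeys(panel["biomarker_id"]))
    stations = list(dict.fromkeys(panel["station"]))
    means = panel.pivot_table(index="biomarker_id", columns="station",
                              values="mean", aggfunc="first")
    if means.isna().any().any() or \
            not set(star_order) <= set(means.index):
        missing = sorted(set(star_order) - set(means.index)) or \
            [f"{i}@{c}" for i, c in zip(*np.where(means.isna()))]
        raise IncompletePanelError(f"panel missing station x biomarker cells: {missing}")
    means = means.loc[star_order, stations]
    sds = ns = None
    if "sd" in panel.columns and panel["sd"].notna().all():
        sds = panel.pivot_table(index="biomarker_id", columns="station",
                                values="sd", aggfunc="first").loc[star_order, stations]
    if "n" in panel.columns and panel["n"].notna().all():
        ns = panel.pivot_table(index="biomarker_id", columns="station",
                               values="n", aggfunc="first").loc[star_order, stations]
    species_of = dict(zip(panel["biomarker_id"], panel["species"].astype(str)))
    return means, sds, ns, species_of


def global_ibr(panel: pd.DataFrame,
               directions: dict | None = None,
               star_order: list | None = None,
               method: str = "pooled_total") -> IbrResult:
    """Run the full IBR pipeline on a long-format biomarker panel.

    Parameters
    ----------
    panel : DataFrame with columns station, species, biomarker, mean and
        (for pooled_total) sd; optional n.  Every biomarker must be
        measured at every station.
    directions : map from biomarker name or "species:name" id to a
        direction constant; unlisted biomarkers default to
        increases_with_stress (the GSH/GSSG ratio defaults to
        decreases_with_stress).
    star_order : list of "species:name" ids; defaults to panel row order.
    method : standardization method (see :func:`standardize`).
    """
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    means, sds, ns, species_of = _panel_matrix(panel, star_order)
    stations = list(means.columns)
    order = list(means.index)
    k = len(order)

    y_rows, z_rows, s_rows = [], [], []
    for bm in order:
        row_sds = sds.loc[bm].to_numpy() if sds is not None else None
        row_ns = ns.loc[bm].to_numpy() if ns is not None else None
        y = standardize(means.loc[bm].to_numpy(), method=method, sds=row_sds, ns=row_ns)
        name = bm.split(":", 1)[1]
        direction = directions.get(bm, directions.get(name, INCREASES))
        z = deviation_score(y, direction)
        y_rows.append(y)
        z_rows.append(z)
        s_rows.append(partial_scores(z))

    scores = pd.DataFrame(s_rows, index=order, columns=stations)
    standardized = pd.DataFrame(y_rows, index=order, columns=stations)

    area_rows = {}
    ibr_vals = {}
    for st in stations:
        res = star_ibr(scores[st].to_numpy(), k)
        area_rows[st] = res["areas"]
        ibr_vals[st] = res["ibr"]
    segment_labels = [f"{order[i]}->{order[(i + 1) % k]}" for i in range(k)]
    areas = pd.DataFrame(area_rows, index=segment_labels)
    ibr = pd.Series(ibr_vals, name="ibr")

    species_rows = {}
    for i, bm in enumerate(order):
        sp = species_of[bm]
        species_rows.setdefault(sp, np.zeros(len(stations)))
        species_rows[sp] += areas.iloc[i].to_numpy()
    species_scores = pd.DataFrame(species_rows, index=stations).T

    beta = 2.0 * math.pi / k
    coords = [
        {"station": st, "biomarker": bm, "angle": i * beta,
         "radius": float(scores.loc[bm, st])}
        for st in stations for i, bm in enumerate(order)
    ]
    star_coordinates = pd.DataFrame(coords)

    return IbrResult(scores=scores, areas=areas, ibr=ibr,
                     species_scores=species_scores,
                     star_coordinates=star_coordinates,
                     standardized=standardized)


def order_sensitivity(panel: pd.DataFrame,
                      directions: dict | None = None,
                      method: str = "pooled_total",
                      n_samples: int = 100,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """IBR per station over sampled star-order permutations.

    The IBR is invariant to rotations and reversals of the star order
    but not to arbitrary permutations; this reports the spread a user
    should expect when the order is not fixed by convention.
    """
    rng = rng or np.random.default_rng()
    base = global_ibr(panel, directions=directions, method=method)
    order = list(base.scores.index)
    rows = []
    for i in range(n_samples):
        perm = list(rng.permutation(order))
        res = global_ibr(panel, directions=directions, star_order=perm, method=method)
        row = {"sample": i}
        row.update(res.ibr.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
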