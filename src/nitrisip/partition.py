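"""Nitrification potentials from shaken-slurry kinetics and their partition
into guild contributions under the multi-inhibitor design.

A soil slurry saturated with ammonium accumulates NO2- and NO3- linearly over
24 h; the slope R (mg N L^-1 h^-1) converts to a nitrification potential

    Np = R * (0.1 + V) / m * 24        [mg N kg^-1 dry soil d^-1]

with 0.1 L of buffer, V the soil water volume (L) and m the soil dry mass
(kg).  Selective inhibitors split the process among guilds:

========================  =======  =========================
assay (inhibitors, ion)   analyte  measures
========================  =======  =========================
NaClO3                    NO2-     [AOA + AOB] combined
NaClO3                    NO3-     [comammox], AOA/AOB active
NaClO3 + Sim              NO2-     AOB alone (AOA blocked)
NaClO3 + DMPP             NO2-     AOA alone (AOB blocked)
NaClO3 + Sim + DMPP       NO3-     comammox alone
========================  =======  =========================

NaClO3 blocks nitrite oxidation so NO2- accumulates; Sim is the
archaeal-selective inhibitor, DMPP the bacterial one.  Two percentage schemes
are reported: scheme U from the uninhibited pair ([AOA+AOB], [comammox]) and
scheme I from the fully resolved singles (AOA, AOB, comammox).  Interaction
indices delta_AB = Np_[AOA+AOB] - (Np_AOA + Np_AOB) and
delta_C = Np_[comammox] - Np_comammox_alone quantify non-additivity: a
negative delta_AB is antagonism between the ammonia oxidizers, a positive
delta_C means the presence of active AOA/AOB boosts comammox.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SlurryTimeSeries",
    "RateFit",
    "PotentialAssay",
    "PartitionResult",
    "ASSAY_ROLES",
    "fit_rate",
    "nitrification_potential",
    "subtract_background",
    "partition_contributions",
    "interaction_report",
    "partition_from_table",
]

BUFFER_VOLUME_L = 0.1
DEFAULT_QC_R2 = 0.9

# (inhibitor combo, analyte) -> role in the partition design
ASSAY_ROLES: dict[tuple[frozenset, str], str] = {
    (frozenset({"NaClO3"}), "NO2"): "AOA+AOB",
    (frozenset({"NaClO3"}), "NO3"): "comammox_coexist",
    (frozenset({"NaClO3", "Sim"}), "NO2"): "AOB",
    (frozenset({"NaClO3", "DMPP"}), "NO2"): "AOA",
    (frozenset({"NaClO3", "Sim", "DMPP"}), "NO3"): "comammox_alone",
}


@dataclass(frozen=True)
class SlurryTimeSeries:
    soil: str
    substrate: str
    inhibitor_combo: frozenset
    analyte: str  # "NO2" | "NO3"
    replicate: str
    times_h: tuple[float, ...]
    conc_mgN_L: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h)
        if t.size < 3:
            raise ValueError("a slurry series needs at least 3 time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.asarray(self.conc_mgN_L) < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class RateFit:
    slope: float          # R, mg N L^-1 h^-1
    intercept: float      # mg N L^-1
    r_squared: float
    qc_pass: bool
    n_points: int
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class PotentialAssay:
    """Nitrification potential of one assay (possibly replicate-averaged)."""

    soil: str
    substrate: str
    inhibitor_combo: frozenset
    analyte: str
    np_mg_kg_d: float
    np_sd: float = 0.0
    V: float = 0.0
    m: float = 1.0
    fits: tuple[RateFit, ...] = field(default_factory=tuple)
    background_subtracted: bool = False
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def qc_pass(self) -> bool:
        return all(f.qc_pass for f in self.fits) if self.fits else True


@dataclass(frozen=True)
class PartitionResult:
    soil: str
    substrate: str
    np_aoa: float
    np_aob: float
    np_comammox_alone: float
    np_aoa_plus_aob: float
    np_comammox_coexist: float
    pct_scheme_u: dict[str, float]   # {"AOA+AOB": %, "comammox": %}
    pct_scheme_i: dict[str, float]   # {"AOA": %, "AOB": %, "comammox": %}
    delta_ab: float
    delta_c: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def fit_rate(series: SlurryTimeSeries, qc_r2: float = DEFAULT_QC_R2) -> RateFit:
    """Ordinary least-squares line of concentration on time.

    ``r_squared`` is the squared Pearson correlation; a constant-concentration
    series has slope 0 and (degenerate) r_squared defined as 0, flagged.
    """
    t = np.asarray(series.times_h, dtype=float)
    c = np.asarray(series.conc_mgN_L, dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("constant time vector")
    flags: list[str] = []
    if np.ptp(c) == 0:
        slope, intercept, r2 = 0.0, float(c[0]), 0.0
        flags.append("constant_concentration")
    else:
        res = sps.linregress(t, c)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return RateFit(
        slope=slope, intercept=intercept, r_squared=r2,
        qc_pass=bool(r2 >= qc_r2), n_points=int(t.size), flags=tuple(flags),
    )


def nitrification_potential(
    fit: RateFit, V: float, m: float, series: SlurryTimeSeries | None = None
) -> PotentialAssay:
    """Np = R * (0.1 + V) / m * 24, in mg N per kg dry soil per day."""
    if m <= 0:
        raise ValueError("soil dry mass m must be positive")
    if V < 0:
        raise ValueError("soil water volume V must be non-negative")
    np_val = fit.slope * (BUFFER_VOLUME_L + V) / m * 24.0
    meta = series or SlurryTimeSeries(
        "", "", frozenset(), "NO2", "", (0.0, 1.0, 2.0), (0.0, 0.0, 0.0)
    )
    return PotentialAssay(
        soil=meta.soil, substrate=meta.substrate,
        inhibitor_combo=meta.inhibitor_combo, analyte=meta.analyte,
        np_mg_kg_d=float(np_val), V=float(V), m=float(m), fits=(fit,),
    )


def potential_from_series(
    series_list: Sequence[SlurryTimeSeries], V: float, m: float,
    qc_r2: float = DEFAULT_QC_R2,
) -> PotentialAssay:
    """Per-replicate fits averaged into one assay (mean Np, sd over n=3)."""
    if not series_list:
        raise ValueError("no series supplied")
    key = {(s.soil, s.substrate, frozenset(s.inhibitor_combo), s.analyte) for s in series_list}
    if len(key) != 1:
        raise ValueError("series mix soils/substrates/combos/analytes")
    fits = tuple(fit_rate(s, qc_r2=qc_r2) for s in series_list)
    nps = np.array([f.slope * (BUFFER_VOLUME_L + V) / m * 24.0 for f in fits])
    ref = series_list[0]
    flags = tuple(sorted({fl for f in fits for fl in f.flags}))
    return PotentialAssay(
        soil=ref.soil, substrate=ref.substrate,
        inhibitor_combo=frozenset(ref.inhibitor_combo), analyte=ref.analyte,
        np_mg_kg_d=float(nps.mean()),
        np_sd=float(nps.std(ddof=1)) if len(nps) > 1 else 0.0,
        V=float(V), m=float(m), fits=fits, flags=flags,
    )


def subtract_background(assay: PotentialAssay, ace_control: PotentialAssay) -> PotentialAssay:
    """Subtract the acetylene-control (heterotrophic background) potential.

    Negative net potentials are retained and flagged, never clamped.
    """
    if (assay.soil, assay.substrate, assay.analyte) != (
        ace_control.soil, ace_control.substrate, ace_control.analyte
    ):
        raise ValueError("background control does not match assay soil/substrate/analyte")
    net = assay.np_mg_kg_d - ace_control.np_mg_kg_d
    flags = list(assay.flags)
    if net < 0:
        flags.append("negative_net_potential")
    if ace_control.np_mg_kg_d == 0:
        flags.append("zero_background")
    return replace(
        assay, np_mg_kg_d=float(net), background_subtracted=True, flags=tuple(flags)
    )


def _percentages(components: dict[str, float]) -> tuple[dict[str, float], list[str]]:
    flags: list[str] = []
    vals = {}
    for k, v in components.items():
        if v < 0:
            flags.append(f"negative_potential_floored:{k}")
            v = 0.0
        vals[k] = v
    total = sum(vals.values())
    if total <= 0:
        flags.append("percentages_undefined_total_nonpositive")
        return {k: float("nan") for k in vals}, flags
    return {k: 100.0 * v / total for k, v in vals.items()}, flags


def partition_contributions(
    assays: Mapping[tuple[frozenset, str], PotentialAssay]
) -> PartitionResult:
    """Map the five required assays to named potentials and both percentage
    schemes, plus the interaction indices."""
    missing = [k for k in ASSAY_ROLES if k not in assays]
    if missing:
        names = [f"({'+'.join(sorted(c))}, {a}) -> {ASSAY_ROLES[(c, a)]}" for c, a in missing]
        raise KeyError(f"missing assay combination(s): {'; '.join(names)}")
    by_role = {ASSAY_ROLES[k]: assays[k] for k in ASSAY_ROLES}
    ref = by_role["AOA+AOB"]

    np_aoa = by_role["AOA"].np_mg_kg_d
    np_aob = by_role["AOB"].np_mg_kg_d
    np_com_alone = by_role["comammox_alone"].np_mg_kg_d
    np_ab = by_role["AOA+AOB"].np_mg_kg_d
    np_com_co = by_role["comammox_coexist"].np_mg_kg_d

    pct_u, flags_u = _percentages({"AOA+AOB": np_ab, "comammox": np_com_co})
    pct_i, flags_i = _percentages({"AOA": np_aoa, "AOB": np_aob, "comammox": np_com_alone})
    flags = sorted(set(flags_u + flags_i))
    for role, a in by_role.items():
        if not a.qc_pass:
            flags.append(f"qc_fail:{role}")

    return PartitionResult(
        soil=ref.soil, substrate=ref.substrate,
        np_aoa=np_aoa, np_aob=np_aob, np_comammox_alone=np_com_alone,
        np_aoa_plus_aob=np_ab, np_comammox_coexist=np_com_co,
        pct_scheme_u=pct_u, pct_scheme_i=pct_i,
        delta_ab=float(np_ab - (np_aoa + np_aob)),
        delta_c=float(np_com_co - np_com_alone),
        flags=tuple(flags),
    )


def interaction_report(
    results: Sequence[PartitionResult], tolerance: float = 0.05
) -> pd.DataFrame:
    """Per soil x substrate interaction summary.

    ``tolerance`` is a fraction of the scheme-U total potential; a delta
    within +/- tolerance*total is classified as additivity, otherwise as
    synergy (positive) or antagonism (negative).
    """
    if len(results) < 1:
        raise ValueError("need at least one partition result")

    def classify(delta: float, total: float) -> str:
        tol = tolerance * total
        if abs(delta) <= tol:
            return "additivity"
        return "synergy" if delta > 0 else "antagonism"

    rows = []
    for r in results:
        total = r.np_aoa_plus_aob + r.np_comammox_coexist
        rows.append(
            {
                "soil": r.soil,
                "substrate": r.substrate,
                "delta_AB": r.delta_ab,
                "delta_C": r.delta_c,
                "comammox_share_U": r.pct_scheme_u["comammox"],
                "comammox_share_I": r.pct_scheme_i["comammox"],
                "class_AB": classify(r.delta_ab, total),
                "class_C": classify(r.delta_c, total),
            }
        )
    return pd.DataFrame(rows)


def series_from_table(df: pd.DataFrame) -> list[SlurryTimeSeries]:
    """Parse a long-format slurry table (columns: soil, substrate,
    inhibitor_combo, analyte, replicate, time_h, conc_mgN_L)."""
    required = {"soil", "substrate", "inhibitor_combo", "analyte", "replicate",
                "time_h", "conc_mgN_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"slurry table missing columns: {sorted(missing)}")
    out = []
    keys = ["soil", "substrate", "inhibitor_combo", "analyte", "replicate"]
    for (soil, sub, combo, analyte, rep), g in df.groupby(keys, sort=True):
        g = g.sort_values("time_h")
        combo_set = frozenset() if combo in ("", "none") else frozenset(str(combo).split("+"))
        out.append(
            SlurryTimeSeries(
                soil=str(soil), substrate=str(sub), inhibitor_combo=combo_set,
                analyte=str(analyte), replicate=str(rep),
                times_h=tuple(float(t) for t in g["time_h"]),
                conc_mgN_L=tuple(float(c) for c in g["conc_mgN_L"]),
            )
        )
    return out


def partition_from_table(
    df: pd.DataFrame, V: float, m: float,
    qc_r2: float = DEFAULT_QC_R2, ace_baseline: bool = False,
) -> tuple[list[PartitionResult], pd.DataFrame]:
    """Full partition analysis of a slurry table.

    Returns per soil x substrate PartitionResults and a tidy per-assay
    potentials table.  With ``ace_baseline`` the matched acetylene assay is
    subtracted from every potential before partitioning.
    """
    series = series_from_table(df)
    grouped: dict[tuple, dict[tuple[frozenset, str], list[SlurryTimeSeries]]] = {}
    for s in series:
        grouped.setdefault((s.soil, s.substrate), {}).setdefault(
            (s.inhibitor_combo, s.analyte), []
        ).append(s)

    results, pot_rows = [], []
    for (soil, sub), assays_series in sorted(grouped.items()):
        assays = {
            key: potential_from_series(sl, V=V, m=m, qc_r2=qc_r2)
            for key, sl in assays_series.items()
        }
        if ace_baseline:
            corrected = {}
            for (combo, analyte), a in assays.items():
                ace_key = (frozenset({"Ace"}), analyte)
                if combo != frozenset({"Ace"}) and ace_key in assays:
                    corrected[(combo, analyte)] = subtract_background(a, assays[ace_key])
                else:
                    corrected[(combo, analyte)] = a
            assays = corrected
        for (combo, analyte), a in sorted(assays.items(), key=lambda kv: (sorted(kv[0][0]), kv[0][1])):
            for f in a.fits:
                pot_rows.append(
                    {
                        "soil": soil, "substrate": sub,
                        "inhibitor_combo": "+".join(sorted(combo)) or "none",
                        "analyte": analyte, "R": f.slope, "R2": f.r_squared,
                        "qc_pass": f.qc_pass,
                        "Np": f.slope * (BUFFER_VOLUME_L + a.V) / a.m * 24.0,
                    }
                )
        if any(k in assays for k in ASSAY_ROLES):
            # an incomplete design raises, naming the missing assay arm(s)
            results.append(partition_contributions(assays))
    return results, pd.DataFrame(pot_rows)
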