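"""Seeded synthetic datasets with the statistical structure the analysis
assumes, plus a machine-readable ground-truth record for recovery testing.

Three generators mirror the three measurement layers:

* CsCl gradient qPCR profiles — DNA of a marker gene equilibrates around a
  buoyant density set by its GC content, ``d0 = 1.660 + 0.098 * GC`` (the
  classical empirical relation); full 13C labeling shifts the peak by
  0.036 g ml^-1, scaled linearly by the atom fraction excess.  Fraction
  copy numbers are bin integrals of the two-component Gaussian mixture
  ``(1-p) * N(d0, sd) + p * N(d1, sd)`` times multiplicative lognormal qPCR
  noise.  Fraction 1 is the densest (bottom-collected).
* Shaken-slurry kinetics — NO2-/NO3- concentrations rise linearly; the
  effective rate is the sum of the guild rates surviving the inhibitor
  design, with two interaction knobs: ``interaction_ab`` multiplies the
  combined AOA+AOB rate when both are active (values < 1 emulate the
  observed antagonism), and ``comammox_coexistence_boost`` multiplies the
  comammox rate when AOA and AOB are active (values > 1 emulate
  cross-feeding).  Measurement noise is additive Gaussian.
* Heavy-fraction ASV counts — negative-binomial counts with planted
  13C-enrichment classes driving fold-changes per inhibitor context.

Presets CK (unfertilized control), WI1 and WI2 (long-term organic liquid
fertilization) encode the qualitative regimes of the study system: AOA- and
comammox-leaning control soil versus AOB-dominated fertilized soils, with a
comammox coexistence boost only in WI2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .partition import SlurryTimeSeries
from .sipquant import FractionProfile, GradientPair

__all__ = [
    "GradientProtocol",
    "GeneLabelTruth",
    "LabelTruth",
    "GuildRates",
    "InhibitorDesign",
    "SlurryProtocol",
    "ScenarioTruth",
    "Scenario",
    "simulate_gradient",
    "simulate_slurry",
    "effective_rates",
    "simulate_asv_counts",
    "make_scenario",
    "PRESETS",
]

GENES = ("AOA", "AOB", "comammox")
INHIBITORS = ("NaClO3", "Sim", "DMPP", "Ace")
PROCESSES = ("AOA", "AOB", "comammox", "NOB")
ASV_CLASSES = ("both", "inorganic_only", "organic_only", "unlabeled")

GC_DENSITY_INTERCEPT = 1.660   # g ml^-1 at GC = 0
GC_DENSITY_SLOPE = 0.098       # g ml^-1 per GC fraction
FULL_LABEL_SHIFT = 0.036       # g ml^-1 density shift at 100 atom% 13C


@dataclass(frozen=True)
class GradientProtocol:
    n_fractions: int = 15
    density_min: float = 1.690
    density_max: float = 1.760
    peak_sd: float = 0.006      # within-population buoyant-density spread
    noise_cv: float = 0.05      # CV of multiplicative lognormal qPCR noise
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_fractions < 3:
            raise ValueError("need at least 3 fractions")
        if self.density_max <= self.density_min:
            raise ValueError("density_max must exceed density_min")
        if self.peak_sd <= 0:
            raise ValueError("peak_sd must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    def bin_edges(self) -> np.ndarray:
        """Density bin edges, descending: fraction 1 spans the densest bin."""
        return np.linspace(self.density_max, self.density_min, self.n_fractions + 1)

    def midpoints(self) -> np.ndarray:
        e = self.bin_edges()
        return (e[:-1] + e[1:]) / 2.0


@dataclass(frozen=True)
class GeneLabelTruth:
    gc_content: float
    atom_excess: float          # 13C atom fraction excess of the labeled pool
    labeled_proportion: float   # true p
    total_copies: float         # copies per g dry soil

    def __post_init__(self) -> None:
        for name in ("gc_content", "atom_excess", "labeled_proportion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.total_copies <= 0:
            raise ValueError("total_copies must be positive")

    @property
    def unlabeled_peak(self) -> float:
        return GC_DENSITY_INTERCEPT + GC_DENSITY_SLOPE * self.gc_content

    @property
    def labeled_peak(self) -> float:
        return self.unlabeled_peak + self.atom_excess * FULL_LABEL_SHIFT


@dataclass(frozen=True)
class LabelTruth:
    genes: dict[str, GeneLabelTruth]


@dataclass(frozen=True)
class GuildRates:
    aoa_rate: float                        # NO2- production, mg N L^-1 h^-1
    aob_rate: float
    comammox_nitrate_rate: float           # NO3- production, mg N L^-1 h^-1
    interaction_ab: float = 1.0            # multiplier on combined AOA+AOB rate
    comammox_coexistence_boost: float = 1.0
    heterotrophic_background_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("aoa_rate", "aob_rate", "comammox_nitrate_rate",
                     "heterotrophic_background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("interaction_ab", "comammox_coexistence_boost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _default_efficacy() -> dict[str, dict[str, float]]:
    eff = {inh: {proc: 0.0 for proc in PROCESSES} for inh in INHIBITORS}
    eff["NaClO3"]["NOB"] = 1.0
    eff["Sim"]["AOA"] = 1.0
    eff["DMPP"]["AOB"] = 1.0
    eff["Ace"]["AOA"] = eff["Ace"]["AOB"] = eff["Ace"]["comammox"] = 1.0
    return eff


@dataclass(frozen=True)
class InhibitorDesign:
    """Suppression fraction per inhibitor x target process, each in [0, 1].

    Defaults are the operational reading of the assay design: NaClO3 blocks
    nitrite oxidation (NOB), Sim blocks archaeal ammonia oxidation, DMPP the
    bacterial one, acetylene all autotrophic ammonia oxidation.  Continuous
    values allow stress-testing non-specific or incomplete inhibition.
    """

    efficacy: dict[str, dict[str, float]] = field(default_factory=_default_efficacy)

    def __post_init__(self) -> None:
        for inh, row in self.efficacy.items():
            if inh not in INHIBITORS:
                raise ValueError(f"unknown inhibitor {inh!r}")
            for proc, v in row.items():
                if proc not in PROCESSES:
                    raise ValueError(f"unknown target process {proc!r}")
                if not (0.0 <= v <= 1.0):
                    raise ValueError("efficacies must be in [0, 1]")

    def surviving(self, process: str, combo: frozenset) -> float:
        s = 1.0
        for inh in combo:
            s *= 1.0 - self.efficacy.get(inh, {}).get(process, 0.0)
        return s


@dataclass(frozen=True)
class SlurryProtocol:
    sample_times: tuple[float, ...] = (2.0, 4.0, 8.0, 20.0, 22.0, 24.0)
    soil_water_volume: float = 0.005   # V, L
    soil_dry_mass: float = 0.0095      # m, kg
    measurement_sd: float = 0.0        # mg N L^-1, additive Gaussian
    n_replicates: int = 3
    initial_conc: float = 0.05         # intercept, mg N L^-1

    buffer_volume: float = 0.1         # L, fixed by the assay

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing, >= 2 points")
        if self.buffer_volume != 0.1:
            raise ValueError("buffer volume is fixed at 0.1 L")
        if self.soil_dry_mass <= 0:
            raise ValueError("soil dry mass must be positive")
        if self.soil_water_volume < 0:
            raise ValueError("soil water volume must be non-negative")


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth of one generated scenario; JSON round-trippable."""

    preset: str
    seed: int
    label_truth: LabelTruth
    guild_rates: GuildRates
    inhibitor_design: InhibitorDesign
    asv_classes: dict[str, str]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioTruth":
        d = json.loads(text)
        return cls(
            preset=d["preset"],
            seed=int(d["seed"]),
            label_truth=LabelTruth(
                genes={g: GeneLabelTruth(**v) for g, v in d["label_truth"]["genes"].items()}
            ),
            guild_rates=GuildRates(**d["guild_rates"]),
            inhibitor_design=InhibitorDesign(efficacy=d["inhibitor_design"]["efficacy"]),
            asv_classes=dict(d["asv_classes"]),
        )


# ---------------------------------------------------------------------------
# gradient simulation
# ---------------------------------------------------------------------------

def _mixture_bin_mass(
    edges: np.ndarray, mu0: float, mu1: float, p: float, sd: float
) -> np.ndarray:
    """Integral of the two-component Gaussian mixture over each density bin.

    ``edges`` descending; returns mass per bin (fraction 1 first).
    """
    hi, lo = edges[:-1], edges[1:]

    def comp(mu: float) -> np.ndarray:
        return norm.cdf(hi, mu, sd) - norm.cdf(lo, mu, sd)

    return (1.0 - p) * comp(mu0) + p * comp(mu1)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_gradient(
    label_truth: LabelTruth,
    protocol: GradientProtocol = GradientProtocol(),
    seed: int = 0,
) -> dict[str, GradientPair]:
    """Simulate matched 12C/13C replicate gradient profiles per gene.

    The 12C control uses p = 0 (no labeled subpopulation); the 13C gradient
    places a fraction ``p`` of the population at the shifted peak.  Raises if
    a labeled peak would fall beyond the densest edge of the gradient.
    """
    rng = np.random.default_rng(seed)
    edges = protocol.bin_edges()
    mids = protocol.midpoints()
    indices = tuple(range(1, protocol.n_fractions + 1))
    pairs: dict[str, GradientPair] = {}
    for gene in sorted(label_truth.genes):
        truth = label_truth.genes[gene]
        if truth.labeled_peak > protocol.density_max:
            raise ValueError(
                f"labeled peak {truth.labeled_peak:.4f} g/ml for {gene} exceeds "
                f"density_max {protocol.density_max}: protocol/truth mismatch"
            )
        profiles: dict[str, list[FractionProfile]] = {"12C": [], "13C": []}
        for iso, p in (("12C", 0.0), ("13C", truth.labeled_proportion)):
            mass = _mixture_bin_mass(edges, truth.unlabeled_peak, truth.labeled_peak,
                                     p, protocol.peak_sd)
            for rep in range(1, protocol.n_replicates + 1):
                noise = _lognormal_noise(rng, protocol.noise_cv, mass.size)
                profiles[iso].append(
                    FractionProfile(
                        gene=gene, isotope=iso, replicate=f"r{rep}",
                        indices=indices,
                        densities=tuple(float(d) for d in mids),
                        copies=tuple(float(c) for c in truth.total_copies * mass * noise),
                    )
                )
        pairs[gene] = GradientPair(
            gene=gene,
            profiles_12C=tuple(profiles["12C"]),
            profiles_13C=tuple(profiles["13C"]),
        )
    return pairs


# ---------------------------------------------------------------------------
# slurry simulation
# ---------------------------------------------------------------------------

def effective_rates(
    rates: GuildRates, design: InhibitorDesign, combo: frozenset
) -> dict[str, float]:
    """Noise-free NO2-/NO3- production rates under an inhibitor combination.

    The interaction multiplier applies to the combined AOA+AOB rate, and the
    coexistence boost to the comammox rate, only while both ammonia-oxidizer
    guilds remain (at least partially) uninhibited.  Surviving NOB transfer
    the ammonia-oxidizer NO2- flux onward to NO3-.
    """
    unknown = set(combo) - set(INHIBITORS)
    if unknown:
        raise ValueError(f"unknown inhibitor(s) in combo: {sorted(unknown)}")
    s_aoa = design.surviving("AOA", combo)
    s_aob = design.surviving("AOB", combo)
    s_com = design.surviving("comammox", combo)
    s_nob = design.surviving("NOB", combo)

    both_active = s_aoa > 0 and s_aob > 0
    ao_flux = (s_aoa * rates.aoa_rate + s_aob * rates.aob_rate)
    if both_active:
        ao_flux *= rates.interaction_ab
    com_flux = s_com * rates.comammox_nitrate_rate
    if both_active:
        com_flux *= rates.comammox_coexistence_boost

    bg = rates.heterotrophic_background_rate
    return {
        "NO2": ao_flux * (1.0 - s_nob) + bg,
        "NO3": com_flux + ao_flux * s_nob + bg,
    }


def simulate_slurry(
    guild_rates: GuildRates,
    design: InhibitorDesign,
    protocol: SlurryProtocol,
    inhibitor_combo: frozenset,
    seed: int = 0,
    soil: str = "soil",
    substrate: str = "substrate",
) -> list[SlurryTimeSeries]:
    """Replicate NO2- and NO3- time series under one inhibitor combination.

    ``conc(t) = initial + rate_eff * t + N(0, measurement_sd)``, clamped at
    zero (clamping is rare at realistic noise and is surfaced by the
    downstream fit QC rather than a flag on the series).
    """
    rng = np.random.default_rng(seed)
    rates = effective_rates(guild_rates, design, frozenset(inhibitor_combo))
    t = np.asarray(protocol.sample_times)
    out = []
    for analyte in ("NO2", "NO3"):
        for rep in range(1, protocol.n_replicates + 1):
            noise = (
                rng.normal(0.0, protocol.measurement_sd, t.size)
                if protocol.measurement_sd > 0
                else np.zeros(t.size)
            )
            conc = np.clip(protocol.initial_conc + rates[analyte] * t + noise, 0.0, None)
            out.append(
                SlurryTimeSeries(
                    soil=soil, substrate=substrate,
                    inhibitor_combo=frozenset(inhibitor_combo), analyte=analyte,
                    replicate=f"r{rep}",
                    times_h=tuple(float(x) for x in t),
                    conc_mgN_L=tuple(float(c) for c in conc),
                )
            )
    return out


# ---------------------------------------------------------------------------
# ASV count simulation
# ---------------------------------------------------------------------------

def simulate_asv_counts(
    asv_classes: Mapping[str, str],
    base_means: Mapping[str, float] | float = 200.0,
    fold_change: float = 8.0,
    dispersion: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    contexts: Sequence[str] = ("no_inhibitor", "ace"),
) -> pd.DataFrame:
    """Negative-binomial ASV counts with planted 13C-enrichment classes.

    An ASV's 13C mean is multiplied by ``fold_change`` relative to 12C in the
    no-inhibitor context iff its class is ``both`` or ``inorganic_only``, and
    in the acetylene context iff its class is ``both`` or ``organic_only``.
    Counts are Gamma-Poisson draws with variance ``mu + dispersion * mu^2``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if fold_change <= 1:
        raise ValueError("planted fold-change must exceed 1")
    bad = {c for c in asv_classes.values() if c not in ASV_CLASSES}
    if bad:
        raise ValueError(f"unknown ASV class(es): {sorted(bad)}")
    rng = np.random.default_rng(seed)
    rows = []
    for asv in sorted(asv_classes):
        cls = asv_classes[asv]
        mu0 = base_means[asv] if isinstance(base_means, Mapping) else float(base_means)
        for context in contexts:
            enriched = (
                cls in ("both", "inorganic_only") if context == "no_inhibitor"
                else cls in ("both", "organic_only")
            )
            for iso in ("12C", "13C"):
                mu = mu0 * fold_change if (iso == "13C" and enriched) else mu0
                lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion,
                                size=n_replicates)
                counts = rng.poisson(lam)
                for rep, c in enumerate(counts, start=1):
                    rows.append(
                        {"asv_id": asv, "context": context, "isotope": iso,
                         "replicate": f"r{rep}", "count": int(c)}
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def _np_to_rate(np_mg_kg_d: float, protocol: SlurryProtocol) -> float:
    """Invert Np = R * (0.1 + V) / m * 24 to the slurry rate R."""
    return np_mg_kg_d * protocol.soil_dry_mass / (
        (protocol.buffer_volume + protocol.soil_water_volume) * 24.0
    )


_SLURRY = SlurryProtocol(measurement_sd=0.02)

# Target per-guild potentials (mg N kg^-1 d^-1) and labeling regimes per soil.
# CK: AOA/comammox-leaning control; WI1/WI2: AOB-dominated fertilized soils;
# only WI2 carries a comammox coexistence boost.
PRESETS: dict[str, dict] = {
    "CK": dict(
        np_aoa=1.6, np_aob=11.0, np_com=8.8, interaction_ab=0.85, boost=1.0,
        background=0.27,
        p=dict(AOA=0.40, AOB=0.05, comammox=0.35),
        totals=dict(AOA=8e7, AOB=1e7, comammox=5e7),
    ),
    "WI1": dict(
        np_aoa=1.5, np_aob=12.0, np_com=6.0, interaction_ab=0.80, boost=1.0,
        background=0.27,
        p=dict(AOA=0.30, AOB=0.35, comammox=0.25),
        totals=dict(AOA=4e7, AOB=8e7, comammox=3e7),
    ),
    "WI2": dict(
        np_aoa=1.3, np_aob=20.0, np_com=6.7, interaction_ab=0.70, boost=1.5,
        background=0.27,
        p=dict(AOA=0.803, AOB=0.50, comammox=0.642),
        totals=dict(AOA=2e7, AOB=2e8, comammox=1e7),
    ),
}

SCENARIO_COMBOS: tuple[frozenset, ...] = (
    frozenset(),
    frozenset({"NaClO3"}),
    frozenset({"NaClO3", "Sim"}),
    frozenset({"NaClO3", "DMPP"}),
    frozenset({"NaClO3", "Sim", "DMPP"}),
    frozenset({"Ace"}),
)

_GC = dict(AOA=0.50, AOB=0.55, comammox=0.52)


@dataclass(frozen=True)
class Scenario:
    truth: ScenarioTruth
    gradients: pd.DataFrame
    slurry: pd.DataFrame
    totals: pd.DataFrame
    asv_counts: pd.DataFrame
    gradient_pairs: dict[str, GradientPair]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gradients.to_csv(out / "gradients.tsv", sep="\t", index=False)
        self.slurry.to_csv(out / "slurry.tsv", sep="\t", index=False)
        self.totals.to_csv(out / "totals.tsv", sep="\t", index=False)
        self.asv_counts.to_csv(out / "asv_counts.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(self.truth.to_json())


def _gradient_table(pairs: dict[str, GradientPair]) -> pd.DataFrame:
    rows = []
    for gene in sorted(pairs):
        pair = pairs[gene]
        for prof in (*pair.profiles_12C, *pair.profiles_13C):
            for i, d, c in zip(prof.indices, prof.densities, prof.copies):
                rows.append(
                    {"gene": gene, "isotope": prof.isotope, "replicate": prof.replicate,
                     "fraction": i, "density_g_ml": d, "copies": c}
                )
    return pd.DataFrame(rows)


def _slurry_table(series: list[SlurryTimeSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        combo = "+".join(sorted(s.inhibitor_combo)) or "none"
        for t, c in zip(s.times_h, s.conc_mgN_L):
            rows.append(
                {"soil": s.soil, "substrate": s.substrate, "inhibitor_combo": combo,
                 "analyte": s.analyte, "replicate": s.replicate,
                 "time_h": t, "conc_mgN_L": c}
            )
    return pd.DataFrame(rows)


def make_scenario(
    preset: str,
    seed: int = 0,
    n_asv_per_class: int = 20,
    gradient_protocol: GradientProtocol = GradientProtocol(),
    slurry_protocol: SlurryProtocol = _SLURRY,
    out_dir: str | Path | None = None,
) -> Scenario:
    """Generate the full synthetic dataset for one soil preset.

    Deterministic under (preset, seed); optionally writes the four TSV input
    tables plus ``truth.json`` to ``out_dir``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    root = np.random.SeedSequence(seed)
    s_grad, s_slurry, s_asv = (int(s.generate_state(1)[0] % 2**31)
                               for s in root.spawn(3))

    label_truth = LabelTruth(
        genes={
            g: GeneLabelTruth(
                gc_content=_GC[g], atom_excess=1.0,
                labeled_proportion=cfg["p"][g], total_copies=cfg["totals"][g],
            )
            for g in GENES
        }
    )
    rates = GuildRates(
        aoa_rate=_np_to_rate(cfg["np_aoa"], slurry_protocol),
        aob_rate=_np_to_rate(cfg["np_aob"], slurry_protocol),
        comammox_nitrate_rate=_np_to_rate(cfg["np_com"], slurry_protocol),
        interaction_ab=cfg["interaction_ab"],
        comammox_coexistence_boost=cfg["boost"],
        heterotrophic_background_rate=_np_to_rate(cfg["background"], slurry_protocol),
    )
    design = InhibitorDesign()

    pairs = simulate_gradient(label_truth, gradient_protocol, seed=s_grad)
    series: list[SlurryTimeSeries] = []
    for k, combo in enumerate(SCENARIO_COMBOS):
        series.extend(
            simulate_slurry(
                rates, design, slurry_protocol, combo,
                seed=(s_slurry + k) % 2**31, soil=preset, substrate="urea",
            )
        )
    classes = {
        f"ASV{idx:03d}": cls
        for idx, cls in enumerate(
            [c for c in ASV_CLASSES for _ in range(n_asv_per_class)], start=1
        )
    }
    asv_counts = simulate_asv_counts(classes, seed=s_asv)

    totals = pd.DataFrame(
        [{"gene": g, "treatment": preset, "copies_per_g": cfg["totals"][g]}
         for g in GENES]
    )
    scenario = Scenario(
        truth=ScenarioTruth(
            preset=preset, seed=seed, label_truth=label_truth, guild_rates=rates,
            inhibitor_design=design, asv_classes=classes,
        ),
        gradients=_gradient_table(pairs),
        slurry=_slurry_table(series),
        totals=totals,
        asv_counts=asv_counts,
        gradient_pairs=pairs,
    )
    if out_dir is not None:
        scenario.write(out_dir)
    return scenario
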