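"""Quantification of 13C incorporation from paired CsCl gradient profiles.

DNA of organisms that assimilate a 13C substrate becomes denser and migrates
toward the heavy (high buoyant density) end of a CsCl gradient.  Comparing a
13C-amended gradient to its 12C control therefore measures, per marker gene,
how much of the population incorporated label.  This module normalizes
fraction profiles, defines the heavy window (fixed density threshold or
adaptively, as the region where the 13C profile is enriched relative to the
12C control), estimates the labeled proportion with a bootstrap confidence
interval, converts it to a labeled absolute abundance, and tests enrichment
significance between replicate profiles.

Estimators
----------
With ``S13``/``S12`` the replicate-mean summed relative abundance in the
heavy window for the 13C/12C gradients:

* ``raw_excess``:        p_hat = clamp(S13 - S12, 0, 1)
* ``normalized_excess``: p_hat = clamp((S13 - S12) / (1 - S12), 0, 1)

The normalized form is the default: when fully labeled DNA falls entirely in
the window it is an unbiased estimate of the labeled proportion, because a
fraction ``p`` of the population leaves the light region (contributing
``p*(1 - S12_light_share)`` ... algebraically ``S13 = p + (1-p)*S12``, so
``(S13 - S12)/(1 - S12) = p``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .stats import two_sample_t

__all__ = [
    "FractionProfile",
    "GradientPair",
    "LabelEstimate",
    "normalize_profile",
    "define_heavy_window",
    "labeled_proportion",
    "labeled_abundance",
    "enrichment_significance",
    "quantify_pair",
    "pairs_from_table",
]

DEFAULT_ANALYSIS_RANGE = (2, 14)
DEFAULT_HEAVY_THRESHOLD = 1.725  # g ml^-1, conventional heavy-fraction cutoff


@dataclass(frozen=True)
class FractionProfile:
    """One replicate gradient profile of a marker gene.

    Fraction 1 is the densest (bottom-collected); densities must be strictly
    monotone in the fraction index.
    """

    gene: str
    isotope: Literal["12C", "13C"]
    replicate: str
    indices: tuple[int, ...]
    densities: tuple[float, ...]
    copies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.indices) < 3:
            raise ValueError("a profile needs at least 3 fractions")
        d = np.asarray(self.densities)
        if not (np.all(np.diff(d) > 0) or np.all(np.diff(d) < 0)):
            raise ValueError("densities must be strictly monotone in fraction index")
        if np.any(np.asarray(self.copies) < 0):
            raise ValueError("copies must be non-negative")

    def density_of(self, index: int) -> float:
        return self.densities[self.indices.index(index)]


@dataclass(frozen=True)
class GradientPair:
    """Matched 12C/13C replicate profiles for one gene and treatment."""

    gene: str
    profiles_12C: tuple[FractionProfile, ...]
    profiles_13C: tuple[FractionProfile, ...]
    analysis_range: tuple[int, int] = DEFAULT_ANALYSIS_RANGE

    def __post_init__(self) -> None:
        if not self.profiles_12C or not self.profiles_13C:
            raise ValueError("both isotopes need at least one replicate profile")
        ref = self.profiles_12C[0]
        for p in (*self.profiles_12C, *self.profiles_13C):
            if p.indices != ref.indices:
                raise ValueError("all replicates must share the fraction grid")
            if np.max(np.abs(np.asarray(p.densities) - np.asarray(ref.densities))) > 1e-6:
                raise ValueError("replicate fraction densities differ by more than 1e-6")

    @property
    def range_indices(self) -> list[int]:
        lo, hi = self.analysis_range
        return [i for i in self.profiles_12C[0].indices if lo <= i <= hi]


@dataclass(frozen=True)
class LabelEstimate:
    """Labeled proportion p_hat with bootstrap CI and the activity product."""

    gene: str
    heavy_window: tuple[int, ...]
    p_hat: float
    ci_low: float
    ci_high: float
    labeled_abundance: float | None = None
    p_value: float | None = None
    estimator: str = "normalized_excess"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0):
            raise ValueError("CI must satisfy 0 <= ci_low <= p_hat <= ci_high <= 1")


def normalize_profile(
    profile: FractionProfile, analysis_range: tuple[int, int] = DEFAULT_ANALYSIS_RANGE
) -> pd.Series:
    """Relative abundance over the analysis fraction range (sums to one).

    Raises on an all-zero profile within the range (a failed gradient).
    """
    lo, hi = analysis_range
    mask = [(lo <= i <= hi) for i in profile.indices]
    idx = [i for i, m in zip(profile.indices, mask) if m]
    copies = np.asarray(profile.copies, dtype=float)[mask]
    total = copies.sum()
    if total <= 0:
        raise ValueError(
            f"all-zero profile for {profile.gene}/{profile.isotope}/{profile.replicate} "
            f"within fractions {lo}-{hi} (failed gradient)"
        )
    return pd.Series(copies / total, index=pd.Index(idx, name="fraction"))


def _mean_relative(pair: GradientPair, isotope: str) -> pd.Series:
    profiles = pair.profiles_12C if isotope == "12C" else pair.profiles_13C
    rel = [normalize_profile(p, pair.analysis_range) for p in profiles]
    return pd.concat(rel, axis=1).mean(axis=1)


def define_heavy_window(
    pair: GradientPair,
    mode: Literal["fixed", "adaptive"] = "fixed",
    threshold: float = DEFAULT_HEAVY_THRESHOLD,
) -> tuple[int, ...]:
    """Heavy-window fraction indices, within the analysis range.

    ``fixed``: fractions whose density is at least ``threshold``.
    ``adaptive``: the longest contiguous run of fractions denser than the 12C
    modal fraction in which the mean 13C relative abundance exceeds the mean
    12C relative abundance — the operational "enriched relative to the 12C
    control" definition.  The 12C modal fraction itself is never included.
    An empty window is a valid outcome (no enrichment anywhere).
    """
    ref = pair.profiles_12C[0]
    idx = pair.range_indices
    dens = {i: ref.density_of(i) for i in idx}
    if mode == "fixed":
        return tuple(i for i in idx if dens[i] >= threshold)
    if mode != "adaptive":
        raise ValueError(f"unknown window mode {mode!r}")

    m12 = _mean_relative(pair, "12C")
    m13 = _mean_relative(pair, "13C")
    modal = int(m12.idxmax())
    denser = [i for i in idx if dens[i] > dens[modal]]
    # longest contiguous enriched run among the denser-than-modal fractions,
    # ties broken toward the denser end
    runs: list[list[int]] = []
    current: list[int] = []
    for i in sorted(denser, key=lambda j: dens[j], reverse=True):
        if m13.loc[i] > m12.loc[i]:
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    if not runs:
        return ()
    best = max(runs, key=len)
    return tuple(sorted(best))


def _window_sums(pair: GradientPair, window: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate summed relative abundance over the window (12C, 13C)."""
    w = list(window)
    s12 = np.array(
        [normalize_profile(p, pair.analysis_range).loc[w].sum() for p in pair.profiles_12C]
    )
    s13 = np.array(
        [normalize_profile(p, pair.analysis_range).loc[w].sum() for p in pair.profiles_13C]
    )
    return s12, s13


def _point_estimate(s12: float, s13: float, estimator: str) -> tuple[float, list[str]]:
    flags: list[str] = []
    excess = s13 - s12
    if estimator == "raw_excess":
        return float(np.clip(excess, 0.0, 1.0)), flags
    if estimator == "normalized_excess":
        if s12 >= 1.0 - 1e-9:
            flags.append("s12_saturated")
            return 0.0, flags
        return float(np.clip(excess / (1.0 - s12), 0.0, 1.0)), flags
    raise ValueError(f"unknown estimator {estimator!r}")


def labeled_proportion(
    pair: GradientPair,
    window: Sequence[int],
    estimator: Literal["normalized_excess", "raw_excess"] = "normalized_excess",
    n_boot: int = 1000,
    seed: int = 0,
) -> LabelEstimate:
    """Estimate the labeled proportion p_hat with a percentile bootstrap CI.

    The bootstrap resamples replicates with replacement independently within
    each isotope.  An empty window yields a flagged zero estimate with a
    degenerate CI.
    """
    window = tuple(sorted(int(i) for i in window))
    lo, hi = pair.analysis_range
    if any(not (lo <= i <= hi) for i in window):
        raise ValueError("window must lie within the analysis fraction range")
    if not window:
        return LabelEstimate(
            gene=pair.gene, heavy_window=(), p_hat=0.0, ci_low=0.0, ci_high=0.0,
            estimator=estimator, flags=("empty_window",),
        )

    s12, s13 = _window_sums(pair, window)
    p_hat, flags = _point_estimate(s12.mean(), s13.mean(), estimator)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r12 = rng.integers(0, len(s12), len(s12))
        r13 = rng.integers(0, len(s13), len(s13))
        boots[b], _ = _point_estimate(s12[r12].mean(), s13[r13].mean(), estimator)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    # percentile CIs from few replicates may not bracket the point estimate
    ci_low = float(min(ci_low, p_hat))
    ci_high = float(max(ci_high, p_hat))
    return LabelEstimate(
        gene=pair.gene, heavy_window=window, p_hat=p_hat,
        ci_low=ci_low, ci_high=ci_high, estimator=estimator, flags=tuple(flags),
    )


def labeled_abundance(estimate: LabelEstimate, total_copies: float) -> LabelEstimate:
    """Attach the labeled absolute abundance p_hat x total gene copies."""
    if total_copies < 0:
        raise ValueError("total_copies must be non-negative")
    return replace(estimate, labeled_abundance=estimate.p_hat * float(total_copies))


def enrichment_significance(
    pair: GradientPair,
    window: Sequence[int],
    mode: Literal["student", "welch"] = "student",
) -> float:
    """Two-sided two-sample t-test of per-replicate heavy-window relative
    abundance, 13C vs 12C."""
    for iso, profiles in (("12C", pair.profiles_12C), ("13C", pair.profiles_13C)):
        if len(profiles) < 2:
            raise ValueError(f"need at least 2 replicates for isotope {iso}")
    if not window:
        return 1.0
    s12, s13 = _window_sums(pair, window)
    return two_sample_t(s13, s12, mode=mode).p_value


def quantify_pair(
    pair: GradientPair,
    total_copies: float,
    window_mode: Literal["fixed", "adaptive"] = "fixed",
    threshold: float = DEFAULT_HEAVY_THRESHOLD,
    estimator: Literal["normalized_excess", "raw_excess"] = "normalized_excess",
    n_boot: int = 1000,
    seed: int = 0,
) -> LabelEstimate:
    """Full per-gene quantification: window, p_hat + CI, abundance, p-value."""
    window = define_heavy_window(pair, mode=window_mode, threshold=threshold)
    est = labeled_proportion(pair, window, estimator=estimator, n_boot=n_boot, seed=seed)
    est = labeled_abundance(est, total_copies)
    if len(pair.profiles_12C) >= 2 and len(pair.profiles_13C) >= 2:
        est = replace(est, p_value=enrichment_significance(pair, window))
    return est


def pairs_from_table(
    df: pd.DataFrame, analysis_range: tuple[int, int] = DEFAULT_ANALYSIS_RANGE
) -> dict[str, GradientPair]:
    """Build GradientPair objects from a long-format gradient table.

    Expects columns: gene, isotope, replicate, fraction, density_g_ml, copies.
    """
    required = {"gene", "isotope", "replicate", "fraction", "density_g_ml", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gradient table missing columns: {sorted(missing)}")
    pairs: dict[str, GradientPair] = {}
    for gene, gdf in df.groupby("gene", sort=True):
        by_iso: dict[str, list[FractionProfile]] = {"12C": [], "13C": []}
        for (iso, rep), pdf in gdf.groupby(["isotope", "replicate"], sort=True):
            pdf = pdf.sort_values("fraction")
            by_iso[str(iso)].append(
                FractionProfile(
                    gene=str(gene), isotope=str(iso), replicate=str(rep),
                    indices=tuple(int(i) for i in pdf["fraction"]),
                    densities=tuple(float(d) for d in pdf["density_g_ml"]),
                    copies=tuple(float(c) for c in pdf["copies"]),
                )
            )
        pairs[str(gene)] = GradientPair(
            gene=str(gene),
            profiles_12C=tuple(by_iso["12C"]),
            profiles_13C=tuple(by_iso["13C"]),
            analysis_range=analysis_range,
        )
    return pairs
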