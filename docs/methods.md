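# Methods

This note documents the models behind `nitrisip`, the parameters that
matter, the synthetic-data generator used for validation, and the design
choices made where the methodology was genuinely open.

## Gradient model and labeled-proportion estimation

DNA of a marker gene equilibrates in a CsCl gradient around a buoyant
density set by its GC content; we use the classical empirical relation
`d0 = 1.660 + 0.098·GC` (g ml⁻¹). Full ¹³C labeling raises the density by
0.036 g ml⁻¹; partial labeling scales that shift linearly by the atom
fraction excess. A population in which a proportion `p` incorporated label
is therefore a two-component Gaussian mixture
`(1−p)·N(d0, σ) + p·N(d0 + a·0.036, σ)` with σ the within-population density
spread (default 0.006 g ml⁻¹). Fraction copy numbers are the integrals of
this mixture over the fraction density bins times the total gene abundance.
This closed form is what makes the generator a usable oracle: the expected
heavy-window mass is available by quadrature.

Fractionation follows the bottom-collected convention: fraction 1 is the
densest; densities sit at the midpoints of a uniform grid over
1.690–1.760 g ml⁻¹ (15 fractions); fractions 2–14 form the default analysis
range, mirroring the usual practice of discarding the extreme fractions.
The direction and grid are configurable — real fractionation protocols vary
and rarely publish per-fraction densities.

**Heavy window.** Two definitions are provided. `fixed` takes every analysis
fraction with density ≥ 1.725 g ml⁻¹ (a conventional SIP cutoff). `adaptive`
mirrors the operational definition used with paired controls: the longest
contiguous run of fractions denser than the ¹²C modal fraction in which the
mean ¹³C relative abundance exceeds the mean ¹²C relative abundance; the
¹²C modal fraction itself is never included, and an empty window is a valid
(flagged) outcome. The heavy window is always intersected with the analysis
range, so on the default grid the fixed window is fractions 2–8.

**Estimators.** With S13/S12 the replicate-mean summed relative abundance in
the window:

- `raw_excess`: `p̂ = clamp(S13 − S12, 0, 1)`;
- `normalized_excess` (default): `p̂ = clamp((S13 − S12)/(1 − S12), 0, 1)`.

When fully labeled DNA falls entirely inside the window, S13 = p + (1−p)·S12
and the normalized form returns `p` exactly, which is why it is the default;
the raw form is retained for comparability with simple excess reporting.
Uncertainty comes from a percentile bootstrap over replicates (1,000
resamples, seeded) — replicate-to-replicate variation is the only
uncertainty the data can speak to. Enrichment significance is a two-sample
t-test (Student by default) of per-replicate window sums, ¹³C vs ¹²C.

**Known biases.** Partial labeling (atom excess < 1) moves the labeled peak
only part of the shift, so mass straddles the window boundary and p̂ is
biased downward; no atom-fraction model is attempted. The same edge effect
appears when a high-GC gene's labeled peak sits near the top of the
gradient: mass in fraction 1 (outside the analysis range) is lost from the
window but also from the normalization, producing a mild underestimate
(e.g. p̂ ≈ 0.44 at p = 0.5 for a gene whose labeled peak is 0.005 g ml⁻¹
below the fraction-1/2 boundary). Estimates are replicate-averaged; per
gradient estimation would need within-gradient error models the data do not
support.

## Slurry kinetics and the guild partition

Concentrations are modeled as `c(t) = c0 + r_eff·t + ε`,
ε ~ N(0, σ_meas), over sampling times 2, 4, 8, 20, 22, 24 h. Slopes come
from ordinary least squares over all points; R² (squared Pearson
correlation) below 0.9 flags a failed fit (configurable); a constant series
has slope 0 and a flagged, degenerate R² of 0. Fits are per replicate;
potentials are averaged with their standard deviation (n = 3 by default).
An option to drop late points when NO₂⁻ plateaus was considered and
rejected: with six points, outlier-robust heuristics destabilize the fit
more than the plateau biases it, and the QC flag already surfaces such
series.

The potential formula `Np = R·(0.1+V)/m·24` is implemented exactly and
checked as an identity. V and m are required user inputs (defaults 0.005 L
and 0.0095 kg correspond to a 10 g fresh-soil aliquot at roughly 50%
water-filled capacity); they are not estimated.

The five-assay design maps to named potentials (see README). Percentages
are reported in two non-mixing schemes: scheme U from the uninhibited pair
([AOA+AOB], [comammox]) and scheme I from the fully resolved singles.
Negative potentials (possible after background subtraction) are retained
and flagged, and floored at zero only inside percentage normalization, so
diagnostics survive while shares stay interpretable. Acetylene-control
(heterotrophic background) subtraction is OFF by default and applied only
when matched Ace assays are supplied — published potentials are often not
background-corrected, and silently changing the convention would change
results. Interaction classes use a tolerance of 5% of the scheme-U total:
|Δ| below tolerance is additivity, otherwise synergy/antagonism by sign.

## Differential enrichment and metabolic classification

Heavy-fraction ASV counts are compared ¹³C vs ¹²C per inhibitor context
with a log-scale two-sample t-test (pseudocount 1). The p-value is
one-sided in the enrichment direction — depletion has no meaning in SIP —
which makes the flag exactly calibrated at α on null data. By default no
library-size normalization is applied: heavy-fraction libraries carry no
meaningful depth information once gene abundance is fixed by qPCR, and
global rescaling under strong asymmetric enrichment (in SIP a large share
of taxa may genuinely be labeled) absorbs true signal into the size
factors — measured on planted data, total-count normalization halves
classification accuracy. `total` and `median_ratio` normalizations are
available for count tables with real depth variation, and externally
computed per-ASV p-values (e.g. from a negative-binomial Wald test) can be
dropped in. Benjamini–Hochberg correction is optional; the default is raw
p < 0.05.

Classification is a pure function of the two context flags:
(no-inhibitor, acetylene) = (T,T) → both capacities, (T,F) →
inorganic only, (F,T) → organic only, (F,F) → unlabeled. This is the
mechanistic reading — enrichment that persists when autotrophy is blocked
by acetylene demonstrates organic-substrate assimilation. A `literal`
mapping that swaps the two single-capacity classes is provided as a config
switch because verbal statements of this rule are sometimes internally
inconsistent.

## Statistics toolkit

ANOVA is the classical fixed-effects decomposition. Duncan's multiple range
test uses protection levels `α_p = 1 − (1−α)^(p−1)` and critical ranges
`R_p = q(1−α_p, p, df)·√(MSE/n_h)` with the studentized-range quantile from
`scipy.stats.studentized_range` (cached) and the harmonic mean group size
for unbalanced designs. The stepwise rule never tests inside a stretch
already declared homogeneous; because homogeneous sets are therefore
contiguous in the sorted order, the compact letter display assigns one
letter per maximal homogeneous interval. Ties in means are broken by group
label for deterministic output. Duncan's familywise error exceeds the
nominal α by construction — that is a property of the test, asserted (not
"fixed") in the suite. Measurements are analyzed on the raw scale by
default; log-transform before calling if abundances span decades.

## Synthetic-data generator

The generator emulates exactly the statistical structure the estimators
assume: two-Gaussian gradient mixtures with multiplicative lognormal qPCR
noise (CV 5% default); linear kinetics with additive Gaussian measurement
noise and an inhibitor-efficacy matrix (defaults: NaClO₃→NOB, Sim→AOA,
DMPP→AOB, Ace→all ammonia oxidation, each fully effective; continuous
values allow stress-testing incomplete or non-specific inhibition);
Gamma–Poisson (negative-binomial) ASV counts with planted per-context fold
changes. Two interaction knobs act only while both AOA and AOB survive
inhibition: `interaction_ab` multiplies their combined rate (< 1 =
antagonism) and `comammox_coexistence_boost` multiplies the comammox rate
(> 1 = cross-feeding). Surviving nitrite oxidizers transfer the
ammonia-oxidizer NO₂⁻ flux onward to NO₃⁻; a heterotrophic background rate
adds to both analytes.

Three presets encode the study regimes the package targets: `CK`
(unfertilized control; AOA/comammox-leaning labeling, per-guild potentials
1.6/11.0/8.8 mg kg⁻¹ d⁻¹, mild antagonism 0.85, no boost), `WI1` and `WI2`
(long-term organic fertilization; AOB-dominated, stronger antagonism, and
in WI2 a comammox boost of 1.5 with high AOA labeling 0.803 and comammox
labeling 0.642). Slurry noise defaults to 0.02 mg N L⁻¹, about 2% of the
largest 24-h concentration in these presets.

What the generator does *not* emulate — and hence what passing recovery
tests cannot show about real data: fraction-to-fraction carryover and
smearing in real gradients, GC heterogeneity within a guild, qPCR
inhibition and primer bias, compositional sequencing effects and depth
variation, nonlinear (substrate-depleting or pH-drifting) slurry kinetics,
and genuinely non-specific inhibitor action beyond the efficacy matrix.

## Numerical choices and degenerate inputs

All randomness flows from a single root seed split per stage with
`numpy.random.SeedSequence`; identical configurations are byte-stable.
Gaussian bin masses use exact normal CDF differences (no quadrature error);
lognormal noise is mean-one parameterized from the CV. Degenerate cases are
returned flagged rather than raised wherever a value is still defined:
zero-variance t-tests (p = 1), constant concentration series (slope 0),
empty heavy windows (p̂ = 0), saturated S12 (p̂ = 0), negative net
potentials (kept, floored only for shares). Errors are reserved for
contract violations: all-zero profiles, mismatched fraction grids, missing
assay arms (named), unknown inhibitors/presets/keys.

Problem sizes in the validation suite (200 seeds for recovery and detection
rates, 10 seeds × 80 ASVs for classification accuracy, 2,000 null tests for
calibration, 1,000 random triples for the potential-formula identity) were
chosen so Monte-Carlo error is comfortably below each criterion's margin.
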