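# nitrisip

Tools for quantifying which microbial guilds — ammonia-oxidizing archaea
(AOA), ammonia-oxidizing bacteria (AOB), and complete ammonia oxidizers
(comammox *Nitrospira*) — drive nitrification in soil, by combining two
measurement strategies:

1. **DNA stable-isotope probing (SIP).** Organisms that assimilate a
   ¹³C-labeled substrate build denser DNA, which migrates toward the heavy
   end of a CsCl buoyant-density gradient. Comparing the *amoA* qPCR profile
   of a ¹³C-amended gradient with its ¹²C control yields, per guild, the
   proportion of the population that incorporated label, and — multiplied by
   the total *amoA* abundance — its ¹³C-labeled absolute abundance.
2. **Shaken-slurry nitrification potentials with selective inhibitors.** In
   an ammonium-saturated slurry, NO₂⁻/NO₃⁻ accumulate linearly; the slope
   *R* (mg N L⁻¹ h⁻¹) converts to a nitrification potential

   *Np = R · (0.1 + V) / m · 24*  [mg N kg⁻¹ dry soil d⁻¹]

   where 0.1 L is the buffer volume, *V* the soil water volume (L) and *m*
   the soil dry mass (kg). Chlorate (NaClO₃) blocks nitrite oxidation so
   NO₂⁻ accumulates; simvastatin (Sim) silences AOA, DMPP silences AOB, and
   acetylene (Ace) blocks all autotrophic ammonia oxidation. Five assays
   resolve the guilds: NO₂⁻ under NaClO₃ → [AOA+AOB] combined; NO₃⁻ under
   NaClO₃ → [comammox] with AOA/AOB active; NO₂⁻ under NaClO₃+Sim → AOB;
   NO₂⁻ under NaClO₃+DMPP → AOA; NO₃⁻ under all three → comammox alone.
   Interaction indices Δ_AB = Np₍AOA+AOB₎ − (Np_AOA + Np_AOB) and
   Δ_C = Np₍comammox₎ − Np_comammox,alone quantify non-additivity between
   guilds (antagonism between the ammonia oxidizers, cross-feeding boosts of
   comammox).

The package also classifies heavy-fraction amplicon sequence variants (ASVs)
by metabolic capability — comparing ¹³C vs ¹²C counts with and without
acetylene separates organisms that assimilate carbon autotrophically
(inorganic), organotrophically (organic), or both — and ships the
statistical toolkit used throughout (one-way ANOVA, Duncan's multiple range
test with compact letter display, two-sample t-tests).

Because raw gradient and slurry measurements of this kind are rarely
published, a first-class synthetic-data generator produces all input tables
with known ground truth (density-shifted Gaussian gradient profiles,
inhibitor-modulated linear kinetics, negative-binomial ASV counts), so every
estimator is validated by parameter recovery.

## Worked example

Generate a fertilized-soil scenario (preset `WI2`: AOB-dominated, strong
AOA labeling, comammox boosted by AOA/AOB coexistence) and run the full
pipeline:

```bash
nitrisip all --preset WI2 --seed 42 --out demo/
```

prints

```
report written to demo/report.json
WI2: scheme_I={'AOA': 5.398..., 'AOB': 70.341..., 'comammox': 24.259...}
```

and `demo/report.json` contains (abridged):

| gene     | p̂ (labeled) | labeled abundance (copies g⁻¹) | t-test p | truth |
|----------|-------------|-------------------------------|----------|-------|
| AOA      | 0.794       | 1.59×10⁷                      | 5.8×10⁻¹⁰ | 0.803 |
| AOB      | 0.442       | 8.83×10⁷                      | 3.3×10⁻¹¹ | 0.500 |
| comammox | 0.615       | 6.15×10⁶                      | 7.9×10⁻⁷  | 0.642 |

The labeled proportions recover the generator's truth (the AOB
underestimate is the documented edge effect of a labeled peak near the top
of the gradient; see `docs/methods.md`). The partition stage reports the two
percentage schemes and the interaction indices:

```
scheme U: {AOA+AOB: 59.8%, comammox: 40.2%}
scheme I: {AOA: 5.4%, AOB: 70.3%, comammox: 24.3%}
delta_AB = -6.58 mg kg⁻¹ d⁻¹ (antagonism between AOA and AOB)
delta_C  = +3.23 mg kg⁻¹ d⁻¹ (comammox boosted when AOA/AOB are active)
```

Note the comammox share is larger under scheme U (40.2%, AOA/AOB active)
than scheme I (24.3%, everything else inhibited) — the signature of a
coexistence boost, which this preset plants (boost 1.5). The classify stage
recovers the planted 20-ASVs-per-class design
(`{'both': 22, 'inorganic_only': 18, 'organic_only': 22, 'unlabeled': 18}`),
and the stats stage letters the five assay potentials by Duncan's test.

The same analyses run on your own TSV tables via the `sip-quant`,
`partition`, `classify` and `stats` subcommands; schemas are documented in
the module docstrings and checked by `nitrisip.validate_inputs`.

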