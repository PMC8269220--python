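# Methods

This note documents the models implemented in `ecophys`, their assumptions,
the defaults that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Catabolic energetics (`ecophys.thermo`)

**Model.** The overall Gibbs energy of a dissolved-phase reaction is

    ΔG_r = ΔG_r° + R·T·ln Q_r,      Q_r = Π_i a_i^ν_i,

with R = 8.314462618×10⁻³ kJ mol⁻¹ K⁻¹. Standard state is the classical
chemical-thermodynamic convention: unit activity for pure liquids (water),
and for aqueous species a hypothetical 1 molal solution referenced to
infinite dilution. Activities are a_i = γ_i (C_i/C_iθ) with C_iθ = 1 molal;
the H⁺ activity is set directly by pH (no γ applied to it), so the pH is a
true activity scale.

**Scope: 25 °C, 1 bar only.** Temperature- and pressure-dependent formation
energies (HKF equations of state) are deliberately out of scope; all pinned
ΔG_f° values in `ecophys/data/species.tsv` are SUPCRT92-consistent 25 °C /
1 bar values (Helgeson-school compilations, converted cal → kJ at 4.184).
The experiments these calculations describe were run at or near 25 °C, so a
single-temperature table is sufficient and avoids reimplementing an
equation-of-state package. The `temperature` argument on
`activity_coefficient` is validated but the Debye-Hückel constants are the
25 °C values.

**Activity coefficients.** B-dot extended Debye-Hückel (Helgeson 1969):

    log₁₀ γ_i = −A z_i² √I / (1 + å_i B √I) + Ḃ·I

with A = 0.5092 kg^½ mol^−½, B = 0.3283 Å⁻¹ kg^½ mol^−½, Ḃ = 0.041 kg mol⁻¹.
Ion sizes å are Kielland (1937) values; charged species without a value get
å = 4.0 Å. Neutral aqueous species are assigned γ = 1 (the Ḃ·I salting-out
correction for neutral nonpolar solutes is omitted; at I = 0.7 it would be a
~7% activity effect on O₂, i.e. well under 0.1 kJ per electron in the
reactions computed here). Ionic strength may be supplied directly — the
seawater-like default is I = 0.7 mol/kg — or computed as ½ Σ C_i z_i² when
the full composition is itemized. No speciation/equilibrium solving is done;
the user supplies HCO₃⁻ (etc.) directly.

**NOSC and composite organic carbon.** For C_a H_b N_c O_d P_e S_f with net
charge Z, the nominal oxidation state of carbon is
NOSC = −(−Z + 4a + b − 3c − 2d + 5e − 2f)/a + 4. Alkali/alkaline-earth
counter-ions in neutral salt formulas are stripped and charged to Z so that
e.g. sodium acetate scores as the acetate anion. A medium's composite NOSC
is the carbon-delivery-weighted mean Σ(C_i·a_i·NOSC_i)/Σ(C_i·a_i) — i.e.
per mole of carbon, not per mole of compound, which is the natural reading
of a "weighted average" NOSC and keeps the composite within the component
range.

**Composite DOC oxidation.** `doc_oxidation_reaction(ν)` builds, per mole of
carbon, C_org + ((4−ν)/4) O₂ → HCO₃⁻ + H⁺ + ((h−2)/2) H₂O, where the
pseudo-species C_org = CH_hO_o reproduces the composite NOSC (h = 2 − ν,
o = 1 for ν ≤ 2). Electrons transferred per mol C: n_e = 4 − ν. Its standard
energy couples the linear NOSC relation for the carbon-oxidation half
reaction to bicarbonate, ΔG°_Cox = 60.3 − 28.5·ν kJ (mol C)⁻¹ (LaRowe & Van
Cappellen 2011), to the O₂(aq)/H₂O half reaction computed from the pinned
table. The bicarbonate (not CO₂) product convention is used consistently in
both the half-reaction energy and the reaction quotient. NOSC = +4 is a
degenerate (zero-electron) case and is rejected. Because the pseudo-species
has fractional H stoichiometry, reaction balance checks accept real-valued
coefficients (tolerance 10⁻⁹); ordinary table species still have integer
formulas.

**Validation behavior.** `standard_gibbs` validates element and charge
balance before touching energies and reports per-element residuals on
failure; every single-coefficient ±1 perturbation of a balanced reaction is
rejected. Reactions built from the NOSC relation carry their standard energy
with them since the composite species has no tabulated ΔG_f°.

## Sparse growth curves (`ecophys.growth`)

**Model.** log₂(cell density) is piecewise linear in time: at most three
contiguous phases (two breakpoints), each with ≥ 3 points and its own OLS
fit, so slopes are directly doublings/h. Segmentations are enumerated
exhaustively (curves have ≤ ~12 points, so this is trivial and
deterministic) and scored by BIC on the pooled residual sum of squares,
n·ln(RSS/n) + p·ln(n) with p = 3k − 1 for k segments; ties break toward
fewer phases, then earlier breakpoints.

**Two numerical choices beyond plain BIC**, both forced by the sparseness:

1. *Pooled-variance slope tests.* A 3-point segment leaves one residual
   degree of freedom, so per-segment slope t-tests are nearly powerless and
   would classify genuine 18-fold growth segments as stationary. All slope
   tests therefore use the error variance pooled across segments
   (df = n − 2k), the standard practice in segmented regression.
2. *Post-selection merging.* With n ≈ 7, BIC's penalty (3·ln n per extra
   segment) is weak enough that noisy single-phase exponentials are split
   about half the time. Adjacent segments whose slopes are statistically
   indistinguishable (pooled-variance t-test, α = 0.05) are merged and
   refitted until stable.

**Classification.** A retained segment is a growth phase (rate > 0) or death
phase (rate < 0) only if its slope differs from zero (pooled t-test,
p < 0.05) *and* its fitted fold change is at least `min_fold_change`
(default 2). Everything else is stationary and excluded. A curve with no
growth phase raises a "no growth detected" signal rather than reporting a
zero rate. Replicate summaries use the arithmetic mean and the n−1 sample
standard deviation; doubling time is 1/mean rate.

**Known limitations.** No parametric (logistic/Gompertz/Baranyi) fits, no
lag-time point estimate beyond phase boundaries. When the exponential phase
spans fewer than three samples (fast growth against a nearby carrying
capacity at 12-h sampling), the growth segment necessarily includes the
capacity shoulder and the rate is biased low — at 0.36 doublings/h under the
default simulation conditions this bias is ~12%, which is why the recovery
tolerance is 15%.

## Salinity arithmetic (`ecophys.media`)

S‰ = 1.80655 × Cl‰ (chlorinity in g/kg). The NaCl-addition series interprets
% w/v as g per 100 ml and takes solution density as 1 kg/l, so x% adds
10·x·(35.453/58.443) g/kg of chloride; the series is affine in the percent
with slope ≈ 10.96 ‰ per %. The proportional-dilution series is exactly
linear in the dilution factor. No seawater equation of state (TEOS-10) and
no conductivity-based salinity.

## Recruitment statistics (`ecophys.recruit`)

Read filtering and mapping are upstream; this module consumes genome ×
sample count tables with genome lengths (bp) and per-sample library sizes.

- RPKM[g,s] = counts/(length_kb × libsize_millions); TPM rescales the
  length-normalized rates to 10⁶ per sample (all-zero samples stay zero).
  Both are invariant to duplicating a sample.
- log₁₀ transform default pseudocount: half the smallest nonzero entry.
- Weighted UniFrac (scikit-bio implementation behind the module surface;
  verified in the test suite against an independent branch-by-branch oracle)
  uses tip proportional abundances; the normalized variant (default) divides
  by Σ l_b(P_A + P_B) and lies in [0, 1]. Unrooted input trees are
  midpoint-rooted.
- PCoA is classical scaling (double-center −½D², eigendecompose); axes with
  non-positive eigenvalues are reported but never returned as coordinates.
- ANOSIM is authored in-package: R = (mean between-group rank − mean
  within-group rank)/(n(n−1)/4) on ranked pairwise distances (average-rank
  ties); Monte-Carlo p = (1 + #{R_perm ≥ R_obs})/(1 + permutations) with a
  seeded generator recorded in the result (default 999 permutations), or an
  exact p over all n! relabelings for n ≤ 9. Cross-checked against
  scikit-bio's ANOSIM in the tests.
- Per-genome abundance–environment fits are two-sided OLS slope t-tests; raw
  p-values by default, optional Benjamini–Hochberg q-values.

## Genome cohorts (`ecophys.genomes`)

Estimated complete size = assembly length / (completeness/100), rounded to
the nearest bp; completeness/contamination come from upstream (CheckM-style)
output and are never computed. Cohort medians use the ordinary order
statistic; Mbp values are rounded to two decimals only at report time.

## Synthetic data (`ecophys.simulate`)

**Growth curves** are piecewise: flat at the inoculum density during the
lag, exponential at the true rate, capped at the carrying capacity, with an
optional exponential death tail after capacity is reached. Noise is
multiplicative log-normal, mean-preserving, with a given CV — flow-cytometry
counting error is approximately proportional. Defaults mirror the culturing
conditions analyzed here: inoculum 10⁴ cells/ml, capacity 2×10⁶ cells/ml
(the observed maximum densities), no lag, 12-h sampling over 72 h, CV 10%,
triplicates. Not emulated: sampling jitter, detection limits, contamination
events, or density-dependent rate decline before the cap (growth stops
abruptly at capacity).

**Count tables** draw log-normal base genome abundances (log₁₀ SD 0.5),
genome lengths uniform on 1.5–3.0 Mbp, library sizes log-uniform on
10⁵–10⁷, and an optional group effect (log₁₀ units) on a designated fraction
of genomes in the second half of the samples. Expected reads are
proportional to abundance × length × (mapped fraction × library size), with
mapped fraction 0.05 — a small clade recruits a minor share of a metagenome —
observed through a Poisson layer (optional gamma overdispersion knob, default
off: the simplest model that calibrates the ANOSIM and regression nulls).
Not emulated: compositional coupling to non-target community members,
mapping bias, or genome-similarity cross-mapping.

**Trees** are random coalescent-style topologies with exponential waiting
times between merges; tip labels match the simulated genome names. All
generators are deterministic under a recorded seed and return ground truth
alongside the data, so every downstream estimator can be tested as a closed
loop. Passing these tests demonstrates correct arithmetic and calibration
under the stated generative assumptions, not robustness to the real-data
artifacts listed above.

## Problem sizes used in the shipped test suite

Rate-recovery experiments run 100 draws of triplicate 7-point curves per
true rate (0.05–0.36 doublings/h); the ANOSIM null calibration runs 500
simulated communities (8 genomes × 10 samples) at 199 permutations each;
UniFrac is checked against the brute-force oracle on 50 random 6-tip trees;
exact ANOSIM enumeration uses 6-sample instances (720 relabelings). These
sizes give stable calibration statistics while keeping the whole suite fast.
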