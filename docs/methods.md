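# Methods

## Scope and structure

`trichoproj` is an offline projection: it takes gridded ocean fields as
given and applies algebraic scalings to them. Nothing here simulates
ocean circulation or plankton growth; the only kinetics implemented is
the dual-substrate phosphorus limitation factor used to classify cells.
The pipeline has five stages — synthetic ocean generation, culture
calibration, P-limitation masking, acidification projection, and
reporting — each usable on its own through the library API.

## Acidification scalings

Both scalings are linear in hydrogen-ion concentration, anchored at
[H⁺]₀ = 10⁻⁸·⁰¹ and [H⁺]₁ = 10⁻⁷·⁸¹ mol L⁻¹ (pH on the total scale),
the interval spanned by the paired ambient/acidified laboratory
cultures. With x the fractional position of a cell's [H⁺] in that
interval:

* P-replete: factor 1 + oa·x, oa = −0.184. At x = 1 the factor is
  exactly 0.816.
* P-limited: factor (1 + oap_C·x)(1 + oap_N·x), oap_C = −0.392,
  oap_N = −0.101. The first bracket is the C-biomass (POC:POP) response,
  the second the C-biomass-specific fixation-rate response; their
  product at x = 1 is 0.546592, a 45.3 % reduction.

The linear form is applied by interpolation inside the interval and
extrapolation outside it. Two numerical choices were genuinely open:

* **Clamping.** Strong extrapolation (very acidic cells) can drive a
  linear term negative. Each term is clamped at zero before use — a
  biomass or rate cannot be negative. Clamping each bracket separately
  (rather than the product) keeps both factors monotone non-increasing
  in [H⁺].
* **Alkaline side.** Cells more alkaline than the lower anchor get
  factors above 1. These are allowed (the scaling is a calibration line,
  not a cap), and `ProjectionResult.any_factor_above_1` records when any
  ocean cell is in that regime.

Application order per cell is mask → factor → multiply; there is no
spatial smoothing, and the reference era's state is an explicit input
(the reference is the future-era climatology *without* acidification
effects, NF × R_Tr).

## Phosphorus limitation

The limiting factor uses one shared saturation denominator for the two
substrates, so V_P = V_PO4 + V_DOP is bounded in [0, 1) and
V_PO4/V_DOP = (PO₄·K_DOP)/(DOP·K_PO4) identically. The half-saturation
constants default to K_PO4 = 0.01 and K_DOP = 0.05 mmol m⁻³. Only their
5:1 ratio is externally constrained (phosphate is the preferred P
source); the absolute values are package defaults chosen at the low end
of oligotrophic surface phosphate, and both are overridable.

"P-limited" is defined operationally, since limitation strength is a
continuous quantity: the default `argmin` rule flags a cell where V_P is
strictly below every auxiliary (Fe, N, …) limitation factor, with ties
resolving to not-P-limited so the stronger combined penalty is applied
conservatively. A `threshold` mode (V_P below a fixed cutoff) is
available; the mode used is recorded in the run summary.

## Culture calibration

Effect parameters derive from paired ambient/acidified replicate tables
of per-cell measurements. oap_C is the fractional change of POC:POP and
oap_N of N₂ fixation per POC, both computed by default from ratios of
treatment means — the convention in which culture stoichiometry ratios
like 332:1 are reported — with a mean-of-per-replicate-ratios variant
exposed via `method=`. oa is not derivable from a P-limited table: it is
the P-replete decline from prior work and is accepted as an input
constant (−0.184). Supporting arithmetic implemented alongside:
percent changes (antisymmetric in sign under swap, invariant to common
rescaling), biomass-normalized rates, paired Student's t-tests (two- or
one-tailed; one-tailed is half the two-tailed p in the favoured
direction, used for field incubations), cell density from filament
lengths (total filament length per mL over mean cell length), DNA-P
quotas (two P atoms per base pair × genome size × genome copies; the
7,750,108-bp genome at 100 copies gives 2.574 fmol P cell⁻¹), RNA-P
quotas (one P per 320.5 g mol⁻¹ nucleotide residue), and the 4:1
ethylene-to-N₂ conversion of acetylene-reduction assays.

The synthetic culture-table generator injects known multiplicative
treatment effects with optional log-normal replicate noise (mean-one
parameterisation), so parameter recovery is exact at zero noise and
convergent under noise; default ambient means are of the magnitude seen
in P-limited chemostats (e.g. POC ≈ 830, POP ≈ 2.5 fmol cell⁻¹, N₂
fixation ≈ 1.6 fmol N cell⁻¹ h⁻¹).

## Synthetic ocean generator

The generator emulates the statistical structure of Earth-system output,
not its dynamics. Defaults are fixed study conditions:

* Grid: regular 2° × 2.5° lat-lon, all-ocean mask (any land template is
  injectable). Cell areas use the exact spherical formula, so the sphere
  area is closed-form exact.
* NF: tropical-peaked Gaussian latitude envelope (30° e-folding) times
  log-normal noise (σ = 0.5), rescaled exactly so the global integral
  hits the era target — 155 Tg N yr⁻¹ for 1981–2000 and 130 Tg N yr⁻¹
  for 2081–2100 (the historical total less the projected 25 Tg decline).
  NF is stored areal (g N m⁻² yr⁻¹) so integration is a pure area sum.
* R_Tr: smooth tropical envelope plus noise, scaled to area-weighted
  means of 60/155 ≈ 0.39 (historical) and 47.4/130 ≈ 0.36 (future),
  the *Trichodesmium* shares implied by the global estimates. Because
  NF and R_Tr are positively correlated in latitude, the NF·R_Tr
  integral exceeds mean(R_Tr)·∫NF; the reference integral is therefore
  an emergent quantity, not a target.
* pH: per-cell normal around era means 8.05 (1981–2000) and 7.80
  (2081–2100), spread 0.03 — bracketing the laboratory calibration
  interval.
* PO₄: log-normal around a latitude-dependent median (0.03 mmol m⁻³ in
  the gyres rising poleward); DOP coupled to PO₄ with a ratio of 2 and
  extra log-normal scatter.
* Auxiliary limitation factors: uniform draws (Fe in [0.2, 0.9], N in
  [0.3, 1.0]).

All draws come from one seeded generator per (seed, era) in a documented
order, so identical configs are bit-identical. What the generator does
**not** emulate: land geometry, seasonality, spatially correlated noise,
co-variation of pH with temperature, or any mechanistic nutrient
climatology. Passing tests therefore demonstrate the correctness of the
calibration arithmetic, limitation kinetics, scalings and integration —
not the realism of any particular global number; headline integrals
computed on synthetic states are structural analogues of the published
projection, not reproductions of it (those require the original
Earth-system output and abundance maps).

## nifH upscaling

Group rates follow rate = abundance / copies-per-cell × cell-specific
rate, scaled to daily totals by the active photoperiod (12 h d⁻¹
default), and contribution fractions are each group's share of the
summed rate. Per-group conversion factors and cell rates are
configuration read from a CSV, not constants — published group-level
values vary widely. The spatial abundance mapping keeps only the
interface of a trained model (`predict(predictors) -> abundance per
group`); the bundled default is a deterministic parametric surface with
log₁₀-abundance linear in a temperature proxy, so the pipeline runs with
no learned weights. Training a statistical mapping from climatological
predictors is out of scope.

## Pipeline and problem sizes

A run is fully described by a YAML-serializable config (seed included);
the emitted summary embeds the resolved config and re-running it
reproduces the summary bit-for-bit. Idealised-experiment switches
(`force_uniform_ph`, `force_all_p_limited`) exist for closed-form
end-to-end checks: with uniform pH 7.81 and an all-true mask the global
reductions equal the factor endpoints exactly (18.4 % and 45.3408 %).

Test and acceptance runs use 4°–15° grids (648–3240 cells); results of
the algebraic stages are resolution-independent, and the coarse grids
keep the full suite and the acceptance script each within seconds.

## Known limitations

* No uncertainty propagation over internal variability or parameter
  spread; the projection is a first-order, offline estimate by design.
* The linear [H⁺] response is a calibration over one laboratory
  interval; far-field extrapolation (clamped at zero) has no mechanistic
  support.
* Volumetric-to-areal conversion of upscaled rates (depth integration)
  is not modelled; R_Tr is accepted directly as a field or computed from
  already-areal group rates.
* The CSV state format stores full float precision but is intended for
  tiny fixtures; NetCDF is the working format.
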