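# Methods

## Fluorescence indices

Indices are computed on offset-corrected, standard-normalized channel
signals; the normalization step defaults to the identity (zero offsets,
unit standard) because study-grade instruments report already-corrected
signals. "log" is the decimal logarithm throughout, consistent with the
index literature. The identity `FLAV + FERARI = FLAV_UV` holds to machine
precision by construction — the FRF_R terms cancel — and is asserted at
1e-12. A common multiplicative gain on all channels leaves the ratio
indices (ANTH_RG, FLAV, SFR_R) unchanged but shifts the single-signal
indices (FERARI, FLAV_UV) by −log10(gain); the tests document this
asymmetry, which is why single-signal indices need the fluorescence
standard while ratio indices do not.

## Calibration fitting

* **Linear / polynomial:** ordinary least squares via `numpy.polyfit`;
  coefficients stored in descending powers. Preconditions: ≥ 3 points and
  non-zero predictor variance (linear); n ≥ degree + 2 with ≥ degree + 1
  distinct x (polynomial). The polynomial degree is caller-specified
  (2 for the flavonol curve, 4 for the bi-phasic ANTH_RG curve); there is
  no automatic degree search.
* **Sigmoid** `y = a/(1 + exp(b − c·x))`: Levenberg–Marquardt-style
  nonlinear least squares (`scipy.optimize.curve_fit`, trust-region with
  a > 0 bound). Starting values use the logit trick: a₀ = 1.05·max(y),
  then log(y/(a₀−y)) is linear in x with slope c₀ and intercept −b₀. Up to
  10 jittered restarts (factors drawn in [0.5, 1.5] from a fixed generator,
  so fitting is deterministic) before a failure is declared carrying the
  best residual norm. Tolerances 1e-10, 5000 function evaluations per
  start.
* **r²** is the conventional 1 − SSE/SST about the mean. Published r²
  values may come from other software's definitions, so tests assert
  coefficient recovery, not r² equality, on refits.
* **Model selection** picks the highest r² among requested families,
  breaking near-ties (9 decimal places) by fewest coefficients, since the
  original per-cultivar family choices were made by inspection and no
  selection rule exists to copy.
* **Inversion** is closed-form for lines (non-zero slope) and sigmoids
  (x = (b − ln(a/y − 1))/c, defined on 0 < y < a); polynomials are not
  invertible and raise.
* The SFR_R↔TSS calibration carries an inclusive domain of TSS ≥ 10 °Brix
  (configurable): below that the berry is still chlorophyll-green and the
  index reflects tissue scattering, not ripening.
* Basis conversion: anth_skin = anth_berry / (skin_pct/100), valid for
  0 < skin_pct ≤ 100.

## Synthetic generator

The generator defines the study conditions under which everything is
tested; its defaults are the published single-season values.

* **Chemistry trajectories:** one logistic per variable,
  `v(t) = v0 + (v_harvest − v0)·s(t)/s(t_harvest)` with
  `s(t) = 1/(1+exp(−k(t−t0)))`, midpoint t0 = 215 (anthocyanins 222),
  rate k = 0.12/day (anthocyanins 0.15). The rescaling anchors the harvest
  date exactly at the published harvest value (TSS 27.2 °Brix for the
  Barbera-like profile, etc.); the pre-veraison lag phase is the logistic's
  lower tail rather than a separate model. Onset values where no published
  number exists (TSS 5 °Brix at veraison onset, TA 25 g/L, malic 15 g/L,
  pH 2.75 at lag phase) are ordinary mid-European ripening magnitudes,
  chosen once. The skin-to-berry percentage drifts linearly from
  2 points above its harvest anchor down to it, clipped to 8–13%.
  Default season: 8 weekly dates ending at harvest (DOY 233 for the
  whites, 249 for the others); 3 replicates per date; additive Gaussian
  replicate noise with sd = 3% of each variable's seasonal maximum
  (anth_skin is derived from noisy anth_berry by the basis conversion, so
  the two bases stay exactly consistent row by row).
* **Channels:** FERARI comes from inverting the cultivar's anthocyanin
  calibration (sigmoid for the reds, line for the pink Malvasia R.;
  whites borrow the Malvasia R. line, which at zero anthocyanin gives a
  small positive FERARI baseline). ANTH_RG and FLAV_UV come from forward
  evaluation of their curves at the sample's anthocyanin and flavonol
  values. SFR_R follows the cultivar's TSS line above 10 °Brix (with a
  0.02 floor guarding the near-flat Barbera line, whose published slope
  crosses zero within the season's TSS range) and is drawn uniformly from
  the 0.5–1.1 band below threshold, mimicking the wide pre-veraison
  scatter. Channels are then FRF_R = 10^−FERARI,
  FRF_G = FRF_R·10^−ANTH_RG, FRF_UV = 10^−FLAV_UV, RF_R = FRF_R/SFR_R,
  with multiplicative lognormal noise (σ = 0.03 per channel by default).
  Anthocyanin above 98% of a sigmoid's asymptote is clipped before
  inversion with a logged warning — the curve saturates there and higher
  pigment is optically invisible. Refits on generated data therefore drop
  rows outside a model's invertible/applicable domain (saturated
  anthocyanin; TSS < 10) exactly as the calibration itself does.
* **Cluster sides:** a reading is treated as the NE face; the SW face is
  produced by mapping each of ANTH_RG, FERARI, FLAV_UV, SFR_R through its
  published linear side relation (slopes 0.8537/0.9131/0.951/0.7180) plus
  optional Gaussian index-scale noise, then rebuilding channels from the
  mapped indices.
* **What the generator does not emulate:** real between-replicate
  correlation structure, weather forcing, berry-optics physics, multi-site
  or multi-season variation, and the ANOVA block structure of the field
  trial. Passing tests therefore demonstrate correctness of the fitting
  and appraisal machinery under the stated statistical assumptions, not
  field-level predictive accuracy; in particular the published
  per-cultivar r² values on real data are not reproducible from synthetic
  data and are not asserted.

Two published equations needed interpretation: the Ortrugo TSS line is
printed without its "x" (slope −0.0205 adopted), and the Barbera quartic's
x¹ coefficient is taken as +1.2373 — with the printed minus sign the curve
is monotone negative, contradicting its described peak-then-decline shape.
The skin-basis FERARI sigmoids are stored mapping skin-basis anthocyanin
(x, up to ~20 mg/g) to the index, the only orientation consistent with
their printed asymptotes of ~1.5.

## Economic appraisal

Annual net cash flow = avoided cost of destructive sampling:

* grape destroyed: (ripening_samples·w_sample + harvest_bunches·w_bunch)·p,
  with sample weight 0.05–0.2 kg, bunch weight 0.1–0.4 kg, price
  0.45–0.60 EUR/kg taken at the lower/upper/mean of their ranges per
  scenario;
* labor: (ripening·t_rip + bunches·t_harv − (ripening+bunches)·t_mx)·rate/60
  at 8 EUR/h. Each destructive sample or bunch is replaced by exactly one
  optical measurement point; the two-hectare preset uses 11/4.5/5 minutes,
  the 30-hectare estate preset 20/9/9.5;
* lab analyses: 20 EUR per avoided anthocyanin sample, counting each of
  the 12 harvest bunches per cultivar as one lab sample (the protocol is
  ambiguous about pooling; this reading reproduces the published appraisal
  within a few percent). The 5 EUR TSS fee is stored but excluded from
  savings — TSS is assumed read with a refractometer the grower owns
  either way, which is also why the appraisal concerns red cultivars only.

Sampling protocol: 6 dates × 5 samples × n cultivars for ripening, plus
3 bunches × 4 vines per cultivar at harvest (90 ripening samples/year and
15 samples/date at n = 3).

NPV discounts end-of-year cash flows at 2% with integer exponents;
maintenance (1,000 EUR) is charged at every 3rd year up to and including
the final year — the natural reading of "every 3 years" (a 6-year life
contains two services), and the convention under which the breakeven
lifetimes are invariant to scaling all sampling times by a common factor,
as the sensitivity analysis requires. Breakeven is a linear search over
integer lifetimes (default cap 50 years).

Monte Carlo: the labor rate and the three sampling times are drawn from
independent symmetric uniform distributions with ±20% relative half-width
(the stochastic variables are named in the source analysis but their
distributions are not, so only expected values — not spreads or
significance — should be compared to the published table). The cash flow
is linear in the rate and in each time separately, so the expectation
equals the deterministic value; degenerate (zero-width) distributions
reproduce it bit-for-bit. Summaries carry mean, sd, a one-sample
t-statistic against zero, and the seed.

Problem sizes used by the tests and the acceptance script: seasons of
8 dates × 3 replicates, calibration refits at n = 27, 200 replicates for
the noisy-recovery study, 1000 Monte Carlo draws — the sizes the original
analysis states.

## Known limitations

Single-season, single-site calibrations; no prediction intervals or
bootstrap uncertainty on fitted curves; no revenue-side, tax, inflation or
financing modelling in the appraisal; farm sizes other than the two
presets require a user configuration; the below-threshold SFR_R band is a
qualitative stand-in for scatter that was only described, not tabulated.
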