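# Methods

## The measurement chain

A gradient run yields 20 fractions; each fraction is spiked with a constant
amount of exogenous cross-species total RNA, RNA is isolated, reverse
transcribed, and assayed by qPCR for the target gene(s) and the spike-in
reference amplicon (RLP24). The analysis chain implemented here is

1. **Cq → relative quantity.** RQ_i = E^(Cq_min − Cq_i), with *E* the
   per-cycle amplification efficiency and the within-profile minimum Cq as
   calibrator. Vendor software uses an unspecified calibrator for its
   "relative quantity" output; any positive global rescaling cancels in the
   percentage step, so the choice cannot affect downstream statistics. The
   minimum-Cq convention was chosen for boundedness (RQ ≤ 1). Per-gene
   efficiencies may be supplied; the default E = 2.0 assumes 100%
   efficiency.
2. **Spike-in normalization.** NRQ_i = RQ_i(target) / RQ_i(spike-in),
   per fraction. If the spike-in experienced loss factor L_i in fraction *i*
   and the target the same L_i, the factor cancels exactly. A zero or
   missing spike-in quantity where the target was measured is an error (the
   fraction cannot be corrected), reported with the fraction number.
3. **Percent distribution.** p_i = 100·v_i/Σv_j over the analysis window,
   fractions 2–16 inclusive by default (the 40S/60S/80S/polysome region;
   fraction 1 is free mRNPs and 17–20 are routinely unusable in heavy
   sucrose). Percentages are computed over the window directly, not over all
   20 fractions: the statistic is a percentage of the *analyzed* signal, and
   this keeps F_W invariant to signal outside the window. An explicit
   fraction subset (e.g. even fractions 2,4,…,16) is supported for
   assays run on alternate fractions; F_W then uses the actual fraction
   numbers of the subset.
4. **Missing data.** Undetermined Cq is carried as missing, never imputed as
   zero. Missing window fractions are renormalized out: zero-filling would
   drag F_W toward the observed fractions' mean, while renormalization
   preserves percentage-of-total semantics among what was observed.
5. **F_W and ΔF_W.** F_W = Σ f_i p_i/100 is bounded by the window ends and
   strictly increases when mass moves to a heavier fraction. ΔF_W =
   F_W(treated) − F_W(control) is computed per replicate, because the paired
   test downstream needs per-replicate deltas.
6. **Statistics.** One-tailed paired Student t on per-replicate ΔF_W between
   two arms: t = d̄/(s_d/√n), sample SD (n−1), Student t with n−1 df. The
   tail is an explicit parameter; the default tests the knockdown/test arm
   for the larger shift. The pairing diagnostic is the Pearson correlation
   of the paired deltas with a one-tailed p from t = r√((n−2)/(1−r²)) on
   n−2 df; r = ±1 is degenerate and reported with the limiting p of 0.
   Zero-variance differences are flagged (`degenerate_variance`) with the
   limiting p (0, 1, or 0.5) rather than NaN. No multiple-testing
   correction is applied; reports carry the count of tests run. Exact
   p-values are printed rather than significance stars.

## The simulator

`synthetic_data` generates Cq tables with known ground truth:

- **Baseline distributions.** Each target gene gets a two-component discrete
  profile over fractions 1–20: Gaussian-shaped bumps at a light/monosome
  peak (default fraction 5) and a heavy/polysome peak (default fraction 12),
  mixed with weight 0.45 on the heavy component, width 1.5 fractions. These
  defaults put the control-state F_W near 8.2, mid-window, leaving headroom
  for shifts in either direction.
- **Treatment shift.** The treated condition's profile is produced by
  deterministic mass transport: mass moves from the lightest occupied window
  fractions into the heaviest window fraction (mirrored for negative
  shifts), the final donor split fractionally, until the window F_W has
  moved by exactly the requested delta. This is the simplest mechanism with
  an exactly controllable ΔF_W; it makes no claim of kinetic realism. A
  delta whose target F_W exceeds the window maximum is an error. Fractions
  fully emptied by the transport contain no template and therefore read out
  as undetermined Cq — the pipeline's missing-data path is exercised by
  design.
- **Per-fraction isolation loss.** Each (replicate, condition, fraction)
  draws a multiplicative loss L = exp(N(0, loss_sigma²)). The default
  loss_sigma = 0.5 (≈ 53% coefficient of variation) represents the visibly
  uneven fraction-to-fraction recovery that an equal-amount spike-in reveals
  in practice; no quantitative characterization of that spread is available,
  so this is a modeling choice. Target and spike-in in the same fraction
  share the loss — the identifiability assumption that makes the correction
  valid. `loss_correlation < 1` mixes in an independent log-normal component
  for the spike-in so tests can probe violation of that assumption.
- **Spike-in.** A constant quantity (default 320 arbitrary units, the analog
  of 320 ng of yeast total RNA per 500 µL fraction) present in every
  fraction.
- **Cq readout.** Cq = anchor − log_E(quantity) + N(0, cq_sigma²), the
  standard exponential-amplification inversion; the anchor (default 18
  cycles for unit quantity) only positions the Cq scale. Default
  cq_sigma = 0.2 cycles is typical well-to-well SYBR qPCR repeatability.
  Zero quantity maps to undetermined (missing) Cq.
- **Replicate effects.** A per-replicate perturbation of the treatment
  shift, N(0, replicate_effect_sd²) with default 0.2 fraction-units, shared
  across arms simulated together. It models day-to-day variation in the
  biology (stress-response strength) as opposed to the technical
  fraction-level loss. This term is what makes a *paired* design
  meaningful: arms processed in parallel share it, so pairing removes it,
  and the pairing correlation of replicate deltas becomes informative.
  Spike-in normalization removes the technical loss but not the replicate
  effect — which is exactly why normalized deltas correlate strongly across
  arms while raw deltas, drowned in loss noise, do not.
- **Determinism.** One `numpy` Generator seeded from the config or call
  argument; identical seeds give byte-identical tables. No global RNG state.

### What the simulator does and does not emulate

It reproduces the statistical structure the spike-in correction addresses:
multiplicative per-fraction loss shared between target and spike-in,
constant spike-in input, efficiency-based Cq readout with Gaussian cycle
noise, replicate-level biological variation. It does **not** emulate
absorbance traces, reverse-transcription competition between species,
primer cross-reactivity, RNA degradation, pipetting error in the spike-in
amount itself, or fraction-dependent RT efficiency. Passing recovery tests
therefore show the analysis is correct *under the stated error model*, not
that real experiments contain no other error sources — in particular, error
in the spike-in addition itself propagates into the correction and is not
represented here.

## Key numerical choices

- Exactness: with Cq noise off, the composed pipeline reproduces true F_W to
  ~1e-14 (float round-trip through exp/log); tests assert 1e-9.
- `apply_shift` tolerates a 1e-9 slack at the window boundary before
  declaring a shift unreachable, and guarantees the achieved F_W within
  1e-6 of target (in practice exact to float precision).
- Percent distributions validate Σp = 100 within 1e-9.
- The recovery diagnostic flags fractions whose spike-in RQ deviates from
  the within-sample median by more than a 2-fold threshold (configurable)
  and reports the within-sample CV (sample SD, n−1).

## Study sizes

The validation studies use 500 simulated experiments for shift recovery and
for the two-arm normalization benchmark, and 10,000 draws for null
calibration of the one-tailed test; the cancellation check runs 12
experiments at each of four loss levels (0, 0.3, 0.7, 1.2). These sizes give
Monte-Carlo standard errors well below the margins being tested (e.g.
±0.004 on a 0.05 rejection rate) while keeping the full validation run in
tens of seconds.

## Known limitations

- The t-test assumes approximately normal per-replicate differences; with
  n = 3 replicates the test is exact only under normality, though the
  simulated deltas are close to normal and calibration holds empirically.
- The pairing-correlation p-value with n = 3 rests on 1 df and is a blunt
  diagnostic; it is reported because practitioners use it, not because it is
  powerful.
- Efficiency is treated as known per gene; no dilution-series estimation is
  included.
- The comparison report's "more discernible" flag is a p-value comparison
  between modes on the same data, a descriptive statement rather than a
  formal test of methods.
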