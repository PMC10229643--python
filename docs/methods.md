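# Methods

## Problem and pipeline

The package implements closed-loop optimization of a cell-culture medium.
The basal recipe (EMEM) fixes a baseline concentration for each of 31
components; 29 are tunable (phenol red and penicillin–streptomycin are
held fixed). A medium is represented as a vector of *fold-of-baseline*
values, one per component, restricted to a per-component schedule of
log-spaced levels. Culture quality is read out as blank-subtracted CCK-8
absorbance (A450), a proxy for total cellular NAD(P)H, sampled at 48, 96,
144 and 168 h.

One campaign consists of:

1. **Initial design.** One-factor-at-a-time (OFAT): every tunable
   component is varied to each of its non-baseline levels while all other
   components stay at baseline, plus the all-baseline control. Under the
   default schedules ({0, 0.1, 1, 10, 100}-fold for most components,
   {0, 0.1, 1, 10} for the osmotically dominant ones, {0.01, 0.1, 1} of
   10 %v/v for serum) this is 112 media.
2. **Surrogate.** A gradient-boosted regression-tree ensemble
   (`GradientBoostingRegressor`) regresses the per-medium mean A450 at the
   campaign's objective timepoint (168 h in *regular* mode, 96 h in
   *time-saving* mode) on the fold vector. Hyperparameters are chosen by
   grid search under inner 5-fold CV minimizing MAE; ties resolve to the
   lowest learning rate, then the lowest depth. The full-scale grid is
   learning rate 0.001 + 0.005·j (j = 0..99, i.e. values ≤ 0.5, ending at
   0.496) × depth 2–5 at 300 boosting stages (400 settings).
3. **Selection.** A fresh candidate pool is sampled each round from the
   level grid (default cap 10⁷), the surrogate scores it, and the top k
   (default 19) previously untested media are selected greedily —
   exploitation only, no uncertainty term. Prediction ties break by
   ascending lexicographic fold vector so selection is deterministic.
4. **Measurement and augmentation.** Selected media are measured (through
   the synthetic oracle, or a user callback when driving real
   experiments) at all timepoints and appended to the training set; the
   loop repeats for a fixed number of rounds (default 4).

Accuracy is reported by 5×5 nested cross-validation: an outer seeded
5-fold split for scoring wraps the inner 5-fold grid search, so outer test
points never influence hyperparameter choice. Folds are assigned by a
seeded shuffle followed by contiguous blocks (sizes differ by at most 1).
MAE, R² and RMSE are computed per outer fold. Feature importance is
impurity-reduction (Gini) importance taken from the five outer-fold
models, averaged within a replicate, normalized to sum to one, and
reported as mean ± sd over five independently seeded replicates.

## Candidate pool structure

The unrestricted level grid of this space has ~6·10¹⁹ points, and a
uniform sample of it is almost entirely media that alter most of the 29
components at once — far outside what the OFAT data can inform, where a
greedy learner mostly probes its own blind spots. The campaign therefore
samples its pools from the media that alter at most `max_changes = 4`
components from baseline (~6·10⁶ media, matching the order of magnitude
of the pool used in practice for this design). Sampling is exactly
uniform over that bounded pool: the number of altered components is drawn
proportional to the stratum sizes N_k (elementary symmetric polynomials
of the per-component level counts), the altered subset by weighted
sequential inclusion, and the levels uniformly. `sample_candidates` also
provides the unrestricted independent-uniform mode (`max_changes=None`),
which is the default for the function itself and reduces to exhaustive
grid enumeration minus exclusions whenever the grid fits the cap.

## The synthetic culture oracle

The oracle stands in for the wet lab so optimum recovery, accuracy gain
and importance recovery are testable. It is a phenomenological model, not
a metabolic one:

- **Growth.** Logistic kinetics n(t) = K·n0·e^{rt}/(K + n0(e^{rt} − 1))
  from n0 = 10⁴ cells/ml. Baseline rate r0 = 0.0405 h⁻¹ and capacity
  K0 = 10⁶ cells/ml put the baseline culture at ~90 % of K by 168 h —
  saturation near the last sampling time.
- **Dose responses.** Each active component contributes a multiplier
  profile of its fold value — Gaussian in log₁₀(fold) around an optimum
  (`log_quadratic`, gentle tails, or `window` with near-zero tails for
  ions where both excess and deficiency are harmful), or Michaelis–Menten
  `saturating` for nutrients. Profiles are normalized to 1 at fold 1, so
  the all-baseline medium reproduces (r0, K0) exactly, and capped at 2.
  The value at fold 0 is an explicit `essentiality` parameter (log
  profiles are undefined at 0); 0 means strictly required.
- **Rate vs capacity.** Each profile acts on the rate as m^r_exponent and
  on the capacity as m^k_exponent. Serum growth factors are rate-heavy
  (r_exponent 1.0, k_exponent 0.2); carbon/nitrogen sources are
  capacity-heavy (0.3/1.0); randomly drawn actives get r_exponent ~
  U(0.2, 1) with k_exponent = 1.1 − r_exponent. This decoupling is what
  makes the 48 h readout (pure exponential phase, rate-driven) a worse
  rank predictor of the 168 h endpoint (capacity-driven) than the 96 h
  readout (mixed phase) — the ordering that justifies the time-saving
  mode.
- **Osmotic arrest.** Salt folds above baseline accumulate a weighted
  excess (NaCl dominating); beyond a threshold the rate is multiplied by
  exp(−α·excess), so jointly doubling the salts strictly slows growth and
  10× NaCl effectively arrests it.
- **Assay.** A450 = assay_scale × NAD(P)H-factor × cells(t) + blank.
  Designated vitamins multiply the NAD(P)H-per-cell factor without
  touching growth, so some media raise A450 while cell counts do not —
  the readout is a biomass *proxy*, and the oracle reproduces that
  imperfection. Replicates get multiplicative lognormal noise (σ = 0.05)
  and additive Gaussian noise (σ = 0.02 A450); the additive term is
  comparable to the 48 h signal, as for real plates where early readings
  sit near the blank. Blank subtraction removes the noise-free blank
  mean, so blank-subtracted values can be slightly negative; they are
  kept, not clipped, and the learner must tolerate them.
- **Default active set.** 10 of 29 components are active: serum (optimum
  at fold 0.1, an order of magnitude below the 10 %v/v convention), NaCl
  and CaCl₂ windows centred at baseline, saturating glucose and
  glutamine, two NAD(P)H vitamins, and three further components drawn
  reproducibly from the seed with off-baseline optima (fold 0.1 or 10).
  The remaining 19 are inert. All magnitudes (widths, benefits, noise
  levels) are free synthetic choices; only the qualitative structure
  above is anchored to observed cell-culture behaviour.

Per-medium measurement seeds derive from the dataset seed plus a stable
hash (CRC32) of the medium id, so a dataset is bit-identical regardless
of the order media are simulated in.

**What the oracle does not model:** metabolism (no flux balance), death
phase or cell-cycle structure, plate-position and evaporation effects,
replicate-correlated batch effects, and any real dose–response magnitudes.
Passing the campaign benchmarks therefore shows the *loop* works on a
landscape with realistic structure (sparse active set, interior optima,
two interaction mechanisms, proxy readout), not that it would achieve any
particular gain on real cells.

## Study conditions and problem sizes

Campaign benchmarks and the acceptance script run the study conditions at
desk scale, chosen once: the OFAT initial design (112 media, triplicate),
4 rounds × batch 19, candidate pools of 10,000 media with `max_changes`
4, a reduced hyperparameter grid (learning rate {0.01, 0.1} × depth
{2, 3}, 100 boosting stages), 5–10 campaign seeds, and 50 seeds for the
flat-landscape null. The full-scale settings (400-setting grid, 300
stages, 10⁷ pools) remain the library defaults and are exposed through
`HyperParamGrid.full_scale()` and `CampaignConfig`.

## Numerical and design choices

- Combination identity (deduplication, exclusion of tested media) is the
  fold vector rounded to 12 significant digits; folds are also written to
  disk at that precision, so round-trips preserve identity.
- Inner grid-search scoring is MAE (the headline accuracy metric); the
  selection criterion inside the grid search is otherwise unspecified by
  convention, and MAE keeps it consistent with the reported metric.
- Importance "five replicates" are five re-runs of the outer-CV fit
  procedure with derived seeds (not the five folds of a single run),
  which yields a between-run sd rather than a between-fold sd.
- Quantiles in round summaries use inclusive linear interpolation
  (`numpy.quantile` default), stated because boxplot conventions vary.
- "Better than baseline" uses strict inequality on per-medium mean
  blank-subtracted A450; the reference is the mean over the designated
  all-baseline control rows.
- Composition comparisons use the two-sided Mann–Whitney U test: an exact
  permutation null (dynamic program over tie-averaged ranks, ranks
  doubled to stay integral) when both groups have ≤ 10 media, scipy's
  tie-corrected normal approximation otherwise.
- The random-selection control runs the identical loop and budget but
  skips surrogate fitting, since its predictions would be discarded.
- Degenerate inputs: a space whose tunable components have only the
  baseline level yields the `{baseline}` design; an all-excluded pool
  raises; constant-target datasets fit to the constant; media with
  non-positive denominators get flagged missing changing ratios rather
  than infinities.

## Known limitations

- The OFAT count (112) reflects the default schedules; published
  campaigns of this design used more initial media (232), a property of
  their (unpublished here) level schedules rather than of the generator.
- Greedy exploitation on the *unbounded* grid degrades after early wins
  (the surrogate's blind spots are unbounded); the Hamming-bounded pool
  is a structural mitigation, not a cure — there is still no uncertainty
  term, by design.
- Nested CV at desk scale has high fold-to-fold variance on 50-media
  datasets; learning-curve claims are made on seed means only.
- The exact Mann–Whitney dynamic program is O(n1 · Σranks) per component
  and is only used for group sizes ≤ 10.
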