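# Methods

This note documents the model's assumptions, the parameters that matter,
and the design choices made where the design was genuinely open. It is the
companion to the README's overview; nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model structure and assumptions

The simulation is a discrete-time agent-based model with meal-level steps
(breakfast, lunch, dinner; five weekdays and two weekend days per week;
step 0 is a Monday breakfast). Two social layers exist: the household
(complete mixing at every home meal) and the venue (workplace or school,
mixing only at weekday lunches, in randomly re-drawn eating groups). There
are deliberately **no** interactions between households, no informal
social ties, no injunctive norms, and no memory beyond the fixed-length
running mean — descriptive-norm conformity within these two contexts is
the only social mechanism.

Key simplifications inherited from the modelled system:

- A meal is fully described by one DQI score; whole-diet index values are
  used as per-meal scores without rescaling.
- Household meals are unanimous: members eat the single meal nearest the
  mean of their internal preferences, and all record the same value.
- Agents who eat alone simply realise their own preference (their norm is
  unchanged in expectation).
- Behavioural parameters (σ_i, w_i) are fixed for life at initialisation.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| households | 1000 | — | ~1% of a mid-sized UK city |
| household type mix | 30.5/54.4/2.6/12.4 | % | (working, children) cross; printed shares sum to 99.9 % and are normalised |
| adults per household | 1 or 2, P(2)=0.6 | — | E = 1.6 adults/household |
| children per child household | 1–3, w = (0.45, 0.30, 0.25) | — | E = 1.8, ≈600 children per 1000 households |
| second adult works | 0.7 | prob. | in working-type, 2-adult households |
| workplaces | 232×2, 132×5, 24×7 | capacity × count | capacity-proportional assignment |
| schools | 230×1, 89×3 | capacity × count | primary vs secondary by aggregate capacity |
| σ_i (preference SD) | N(13, 2.5), floor 0.1 | DQI | per-agent meal-to-meal variability |
| w_i (group weight) | Triangular(0, 0.39, 1) | — | weight on the group norm at venue lunches |
| H (history length) | 45 | meals | ≈ two weeks; running-mean window |
| meal pool | N(37.4, 18.7) trunc. [0,100], 3000 meals | DQI | emulates the survey DQI distribution |
| initial diets | same distribution | DQI | history pre-filled H times with the draw |
| menu size | 10 | meals/venue-day | uniform with replacement from eligible meals |
| lunch group size | 6 | agents | venue partitioned daily; remainder group smaller |
| phases | 0–100 / 101–200 / 201–500 | steps | status quo / all-home / return |
| standards activation | schools 0, workplaces 200 | step | `strict_methods` delays schools to 201 |
| iterations | 20 | runs | each re-synthesises population, pool, states |

Where the source material gives two values for the preference-variability
mean (13 in the parameter table, 13.5 in the text) the default follows the
parameter table; both are accepted via configuration
(`sigma_mean`). Similarly, whether school standards are active during the
nominal "no standards" opening phase is contradictory in the source
narrative; the default activates them at step 0 (matching the reported
two-step response of the adult index), with `strict_methods` providing the
literal reading.

## Numerical and procedural choices

- **Running mean** is maintained incrementally over a ring buffer
  (error < 1e-9 over a run; a direct recomputation method exists for
  verification). The buffer is pre-filled with the initial draw, so new
  meals carry weight 1/H from step 0. A growing-window variant (mean over
  the meals seen so far) was evaluated and changes end-of-run statistics
  by well under 1 DQI unit, so the simpler pre-filled contract is kept.
- **Clipping** to [0, 100] is applied at every stochastic draw; the DQI
  scale is bounded by definition.
- **Nearest-meal ties** resolve to the higher-DQI item: deterministic, and
  biased toward the intervention direction by the smallest possible
  amount; a random tie-break is available.
- **Group norm SD** uses the sample (n−1) estimator; a single co-eater
  gives SD 0. The agent's own preference is included among "co-eaters"
  (configurable to leave-one-out).
- **Mixture sampling** is by component selection (Bernoulli(w_i) between
  group and personal norms), which samples the mixture distribution
  exactly.
- **Venue allocation** is an independent capacity-weighted draw per agent
  rather than exact packing, so realised venue sizes fluctuate around
  capacity shares with the dispersion real allocation data show.
- **Isolation** is re-drawn daily: round(f × n_workers) workers sampled
  without replacement sit out that day's workplace lunch and follow
  household rules instead.
- **Seeding**: each (configuration, iteration) derives an independent
  `SeedSequence` from the base seed, the CRC-32 of the configuration name
  and the iteration index; identical configuration + seed gives
  bit-identical traces.
- **Infeasible standards** (no pool meal meets the threshold) raise an
  explicit error naming the threshold rather than silently emptying menus.

## Analysis conventions

Per-agent "diet quality" at a step is the *running mean* (habitual diet),
not the single meal chosen at that step; single meals are far too noisy to
produce the smooth per-agent trajectories the summaries describe. The
dose-response slopes are ordinary least squares over per-iteration
end-of-run summaries (medians for the standards sweep, means for the
isolation sweep), with normal-theory 95% intervals pooling iterations as
independent observations. The child-presence × time interaction is fitted
per iteration on adult running means over steps 0–300 (time unit = model
step) and averaged across iterations. Stratum SDs use the n−1 convention;
empty strata are omitted, not reported as zero.

## What the synthetic data does and does not emulate

The generator reproduces the *printed summary parameters* of the source
surveys — the truncated-normal DQI distribution (median ≈ 38, IQR ≈
26–51), the per-person weekly variability distribution and the household /
venue marginals — not the surveys' microdata. Real diets have
autocorrelated, occasion-specific structure (weekday/weekend menus, meal
deals, eating out) that a fixed pool of i.i.d. DQI scores cannot show, and
real social networks extend beyond the two modelled layers. Passing tests
therefore demonstrate that the *mechanism* behaves as specified under the
stated study conditions, not that the model is calibrated to any real
population's trajectory.

## Problem sizes

Tests and the acceptance script run the full study scale: 1,000
households (~2,200 agents), 500 steps, 20 iterations per condition, five
standard levels and six isolation fractions (220 simulation runs in
total). The vectorised engine completes a run in well under a second, the
whole acceptance computation in about a minute on one CPU.

## Known limitations

- Under full worker isolation the only intervention pathway is school →
  household spillover; adults in child-free households are structurally
  unreachable and the population mean plateaus accordingly. Published
  results for this scenario class report a somewhat higher full-isolation
  endpoint and a roughly 2× faster child-presence interaction, which would
  require an additional transmission pathway (or faster early adaptation)
  that the stated mechanism does not contain; the discrepancy is reported
  as computed rather than tuned away.
- Lunch group size, menu size, household size distributions and
  second-adult employment are not identified by the source material;
  defaults are fixed a priori (table above) and exposed as configuration.
- The model offers no within-household heterogeneity at home meals: one
  shared meal per household per step.
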