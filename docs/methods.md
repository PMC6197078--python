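# Model and methods

## The dynamical system

The simulator advances a tumor state on an integer day grid, `t = 0`
being the first irradiation day.  Volumes are percentages of the initial
total volume, so every course starts at `V_a(0) = 100`, `V_n(0) = 0`,
and the carrying capacity at the patient's `k̂`.

One day's update, in order:

1. **Oxygenation** from the start-of-day state:
   `PO₂ = 100 (k − V_a)/k`, clamped to `[0, 100]`.  The clamp matters
   late in a course, when vascular damage can drive `k` below `V_a`;
   the clamped value reads as full hypoxia.
2. **Radiosensitivity**: `α = α_min + (PO₂/100)(α_max − α_min)` with
   `α_min = 0.001`, `α_max = 0.3 Gy⁻¹`.  These bounds put the surviving
   fraction of a standard 1.8 Gy fraction (α/β = 10 Gy) strictly inside
   (0.5, 1).
3. **Surviving fractions** for the day's dose `d` (1 on rest days):
   `SF = exp(−α γ d (1 + d/(α/β)))` with `(γ, α/β) = (1, 10 Gy)` for
   the tumor and `(γ_v, 3 Gy)` for the vasculature.  The same
   oxygen-dependent α is used for both tissues; `γ_v < 1` encodes that
   impairing vessels takes multiple cell kills.
4. **Growth then kill**: `V_a(t+1) = [V_a + ρ ln(k/V_a) V_a]·SF_t`
   (discrete Gompertz step, natural logarithm).  The growth factor
   `1 + ρ ln(k/V_a)` is floored at 0; the floor is unreachable for the
   fixture cohort and only guards pathological inputs.
5. **Necrosis**: on irradiation days a cohort of size
   `V_a(t)(1 − SF_t)` (the pre-growth volume, see below) is appended,
   tagged with its creation day.
6. **Vascular damage**: `k(t+1) = k·SF_v`.

Weekends are ordinary no-dose days: growth and clearance continue,
nothing else happens.  The endpoint `t_e` is the day after the last
fraction; a `horizon` argument extends the simulation past the course
end for follow-up studies.

## Necrotic clearance: two laws

Each cohort is reabsorbed as a function of its age `L` (days since the
creating fraction).  Two laws are implemented:

* `exponential` — plain half-time decay, weight `2^(−L/T½)`.  One
  half-time after creation exactly half the cohort remains.
* `compound` (default) — the elapsed-lag factor is re-applied on every
  day, i.e. the daily update multiplies each cohort by `2^(−age/T½)`,
  compounding to the weight `2^(−L(L+1)/(2T½))`.  Clearance accelerates
  with cohort age.

The exponential law is the natural reading of a half-time; the compound
law is what a recursive daily implementation of the same factor
produces.  The two differ enormously at the end of a course (cumulative
necrosis of tens of percent versus a few percent).  We ship `compound`
as the default because it is the law under which the simulator
reproduces the published final *total* volumes of the reference cohort
across all 42 (patient × dose) cells — the exponential law overshoots
them by up to ~55 percentage points.  The final *active* volumes are
unaffected by this choice (necrosis does not feed back on `V_a`).
`necrotic_volume()` defaults to the exponential law, matching its
half-time semantics; the simulator's `ModelOptions.clearance` selects
the law used for trajectories.

A second documented switch, `mass_conserving`, sources the cohort from
the *grown* volume `G(t)(1 − SF_t)` instead of the pre-growth
`V_a(t)(1 − SF_t)`, so that active + new necrotic mass equals the grown
volume exactly.  The default follows the pre-growth form.

## Schedules and BED

Schedules are ordered `(day, dose)` lists, at most five fractions per
seven-day window, day 0 a Monday.  `BED = Σ d_i (1 + d_i/10)` is the
isoeffect currency; constant-dose courses pick the fraction count
minimizing `|BED − 60|` (ties to fewer fractions), which recovers the
canonical 28 × 1.8 Gy course (BED 59.47).  Ramped courses run
0.5 → 4.5 Gy in 0.25 Gy steps (17 fractions, mean 2.5 Gy, BED 55.7,
accepted as ≈ 60) in either direction; both directions share the same
dose multiset and hence the same BED.

## Study operations

* **Dose grid**: arms at 1, 1.5, 1.8, 2, 2.5, 3 Gy per fraction.  Best
  dose per patient = argmin of the endpoint volume (active by default;
  ties to the lower dose).  Doses of 1.8/2 Gy are labelled `strd`,
  below `hyper`, above `hypo`.
* **Dose–response correlation**: Pearson (`scipy.stats.pearsonr`)
  between the six arm doses and the six final volumes.  Spearman would
  be equally defensible; Pearson reproduces the published column to
  three decimals, which settles the choice.
* **Minimum-BED criterion**: the course is simulated day by day; on the
  first day the active volume is observed below the threshold (20% =
  80% regression), the BED of the fractions delivered before that
  observation is reported.  The fraction that caused the crossing is
  included; nothing after it is.  Non-crossing courses are a legal
  outcome, reported as `None`.
* **PSI**: initial volume over carrying capacity, `100/k̂` for a
  normalized course.
* **Ramp comparison**: per patient `Δ = |V_a↑(t_e) − V_a↓(t_e)|`;
  summarized as the cohort mean of Δ (percentage points of the initial
  volume) and the cohort mean of `Δ / ((V_a↑ + V_a↓)/2)` (relative to
  the final volume itself, in %).

## Monte Carlo fitting

Plain uniform random search inside the published training box
(ρ ∈ [0.01, 0.2] /day, T½ ∈ [2, 30] d, k̂ ∈ [100, 300] %,
γ_v ∈ [0, 1]); the loss is the RMSE between simulated and observed
total volume at the observation days.  Draws are simulated in a
vectorized batch that is bit-for-bit checked against the scalar
simulator in the test suite; 50,000 draws over a 28-fraction course
take on the order of a second.  Sampling is deterministic given the
seed, and with a fixed seed a smaller budget is a prefix of a larger
one, making the best loss monotone in the budget.

The fitter returns the top-k draws, not just the argmin: with only a
total-volume series, `T½` and `γ_v` are weakly identified (distinct
pairs produce near-identical fits), and the ranking exposes that
instead of hiding it.  The growth rate ρ, in contrast, is well pinned
by dense observations — the recovery test requires it within ±20% of
truth from noise-free weekly data.

## Synthetic data

`generate_series` draws observations from a simulated course and
applies multiplicative Gaussian noise (volumes span two orders of
magnitude over a course, so additive noise would be misscaled), clipped
positive, with the day-0 observation pinned at 100 (it is the
normalization reference, not a measurement).  What it emulates:
sparse, positive, schedule-conditioned total-volume measurements.  What
it does not: imaging segmentation bias, inter-observer variability,
measurement cadence tied to clinic visits, or any misspecification of
the growth law itself — parameter-recovery results on these series
therefore demonstrate the fitter's correctness, not clinical
identifiability.

## Reproduction quality and known discrepancies

Scale of everything here is desk-size: seven 4-parameter patients,
≤ 8 schedules, ≤ 80 daily steps; the full suite runs in seconds.

* Final active volumes: all 42 grid cells within 0.005 percentage
  points of the published grid; best doses and categories exact.
* Final total volumes: within 0.8 percentage points under the compound
  clearance law (mean 0.19).
* c(d, V_a): all seven patients to three decimals.  c(d, V_t) is *not*
  reproduced as closely (residual V_n differences of tenths of a point
  get amplified in a six-point correlation); no headline conclusion
  rests on it.
* Minimum-BED table: 14 of 16 crossing cells exact; the two cells where
  `V_a` grazes the 20% threshold (B and D at 1.8 Gy) differ by ±1
  fraction — and in opposite directions, so no single crossing
  convention can match both.  One of them (D, 1.8 Gy: 10.6 vs 12.7 Gy)
  exceeds a ±10% band; we left it rather than special-case it.
* The published text states that the active- and total-volume criteria
  select the same best dose for all patients but B; the published
  table's own bold minima contradict this for F and G (margins of
  ~0.3 pp), and the simulator reproduces the table, not the text.

## Limitations

No spatial or cell-cycle resolution; no healthy-tissue toxicity or
NTCP modeling (the minimum-BED criterion is a proxy for sparing); the
radiobiological constants are dose-range-limited (0.5–4.5 Gy per
fraction); seven virtual patients support no population statistics; and
the model was originally identified from standard-course data only, so
simulations of strongly altered regimens are extrapolations of the
fitted dynamics, not validated predictions.
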