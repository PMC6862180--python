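# Methods

This note documents the scientific content of `emsopt`: the simulation
model, the statistical machinery, the default parameterization and its
calibration rationale, and the known limits of each.

## 1. Discrete-event simulation of the ED

The simulator (`simulate.py`) advances an event calendar (binary heap)
over a configurable horizon, in minutes.

**Arrivals.** Patients arrive in a homogeneous Poisson stream.
Interarrival gaps are drawn by inverse transform,
x = −ln(1 − θ)/λ with θ ~ U(0, 1) and λ in patients per day, converted
to minutes.  Daily arrival counts are therefore Poisson with mean λ;
the unit tests verify mean and variance/mean ratio over 1000 simulated
days.  Default noise-factor levels: 350 (regular day) and 425 (holiday)
patients/day.

**Triage.** Each patient draws an acuity level 1–5 (1 most urgent) from
a fixed mix, default (0.02, 0.08, 0.45, 0.35, 0.10).

**Flow.** Registration (parallel clerks) → possible diversion (below) →
physician queue → examination → zero or more checkup rooms → disposition.
Levels 1–3 always have strict priority over 4–5 in the physician queue;
within levels 4–5 the order is set by control factor D (shortest
expected examination first / registration order / all 4s before 5s).
Checkup rooms (urinalysis, CT, X-ray) also serve a competing Poisson
stream of non-ED outpatient jobs; control factor B sets the visiting
order and whether ED patients pre-empt the outpatient queue.  Admitted
patients (Bernoulli by triage level) occupy an ED bed and board until
the hourly bed-release policy (factor C) frees beds: when the boarded
fraction exceeds 15/20/25%, 5/10/15 boarders per hour are released
(strict inequalities).

**Diversion (factor A).** At the end of registration, triage-4/5
patients are persuaded toward outpatient clinics when *yesterday's*
mean EDWIN^C exceeded a threshold.  Factor A is continuous on [1, 3]
with anchor thresholds 1.5/2.0/2.5 at levels 1/2/3 and linear
interpolation between them (e.g. A = 2.8 → threshold 2.4).  Persuasion
succeeds with probability `p_divert` (default 1).  The first simulated
day uses a configurable starting signal (default 2.0, i.e. diversion
active) to avoid a cold-start backlog; the first `warmup_days` are
excluded from all reported means.

**Metrics.** EDWIN^C = Σ nᵢ·(6 − i) / (Nₐ·(Bt − BA)) is sampled hourly;
when all beds are boarded (Bt − BA ≤ 0) the last finite value is
carried forward rather than dividing by zero.  Crowding bands: < 1.5
good, 1.5–2 busy, > 2 crowded (boundaries count as busy).  ST is each
patient's total waiting plus service time, in minutes.

### Calibration of the default scenario

The service-time and routing defaults are *synthetic study conditions*
chosen by queueing capacity analysis, not estimates of any hospital:

- examination: lognormal, mean 3.5 min, sd 2 — with one physician the
  examination stage has capacity ≈ 411 patients/day, so utilization is
  ≈ 0.85 at 350/day and ≈ 1.03 at 425/day: the system is stressed but
  not explosively unstable, and adding the second physician (the signal
  factor) produces a clear, monotone improvement;
- registration: lognormal 5 ± 2 min on 2 clerks; checkup rooms 10 ± 5
  (urine), 20 ± 10 (CT), 10 ± 4 (X-ray) with need probabilities 0.25,
  0.12, 0.20 and 20 outpatient jobs/day/room;
- admission probabilities (0.6, 0.4, 0.2, 0.08, 0.04) by triage level,
  30 beds — boarding inflow stays below the release capacity of the
  *mildest* factor-C level so that BA cannot permanently pin Bt.

Under these defaults the hourly EDWIN^C ranges roughly 0.4–2.7 across
the design and mean ST 25–85 min, spanning all three crowding bands and
responding monotonically to the signal, noise and diversion factors.
The package's optimization results are therefore properties of this
calibrated generator; they are not expected to match numbers derived
from any hospital's confidential service-time data.

**Realism limits.** Stationary arrivals (no time-of-day profile), no
patient abandonment or re-entry, exponential outpatient competition,
single-class physicians, Bernoulli admissions independent of congestion,
and an hourly (not event-driven) bed-release and crowding sample.

## 2. Dynamic Taguchi analysis

Control factors A–D occupy an L9(3⁴) orthogonal array, crossed with the
signal factor M ∈ {1, 2} physicians and the noise factor λ ∈ {350, 425}
— 36 cells, each simulated with independent replications (20 at desk
scale, 1000 at full scale).

Per L9 row a zero-intercept ideal function y = βM is fitted by least
squares: β = ΣMy/ΣM², MSE = SSE/(n − 1) (ddof configurable).  The
signal-to-noise ratio is SN = 10·log₁₀(β/MSE) dB; the conventional
variant β²/MSE is available via `sn_variant="conventional"`.  Because
β/MSE requires β > 0, a negative slope uses |β| by default (the sign is
recorded) or raises when configured strictly.  With `pool_noise` (the
default) the responses entering each fit are the per-(M, λ) cell means,
so noise-to-noise variation loads the MSE — the robustness reading of a
dynamic design.  Main effects average SN per factor level; the selected
setting takes the level with maximal mean SN (ties break to the lower
level) and the additive model predicts its SN.

## 3. Desirability and the surrogate

Cell-mean responses are rescaled to [0, 1] with linear ramps whose
bounds default to the observed cell-mean extrema (optionally widened by
a margin): d1 ramps *up* in EDWIN^C (the index's numerator grows with
the ED's served workload; an `stb` switch flips the orientation) and d2
ramps *down* in ST.  The scalar objective is TP = d1·d2², weighting the
time response more strongly.

The surrogate is a 6-h-2 fully connected network — inputs (M, λ, A, B,
C, D) affine-scaled to [0, 1], sigmoid activations — trained by
full-batch backpropagation with momentum 0.65 and a bold-driver
learning rate (×1.05 after an improving step, ×0.5 after a worsening
one, clamped to [0.01, 0.5]) for 10,000 iterations.  The 36 cells split
29 : 7 train/test by a seeded shuffle (train count rounds half-up).
One model per h ∈ {2..8} is trained and the smallest *test* RMSE wins.
Tests verify that the search recovers a planted smooth response to
within 3σ at σ = 0.02.

## 4. Genetic algorithm and sensitivity

A chromosome is (A, B, C, D) with A continuous in [1, 3].  Fitness is
the surrogate's TP aggregated over the four (signal, noise)
combinations — mean by default; `worst` and `nominal` aggregations are
available.  Operators: tournament selection (k = 3), blend crossover on
A with uniform swap on B–D (rate 0.5), Gaussian perturbation σ = 0.1 on
A with level re-draw on B–D (rate 0.08), elitism of one; 1000
generations × population 80 by default.  The best-so-far history is
non-decreasing by construction.  Tests verify recovery of a planted
mixed-space optimum against an exhaustive grid oracle in ≥ 95% of
seeded runs.

The OFAT sensitivity sweep varies one factor at a time around the
optimum — A over 1.0, 1.2, …, 3.0 and B–D over their levels — and
reports the adjusted TP% = (TP_level − TP_opt)/TP_opt × 100, rounded
half-away-from-zero to two decimals via `decimal.Decimal`.

## 5. Numerical and reproducibility choices

- All randomness flows from NumPy `Generator`s.  A master seed is split
  with `SeedSequence([master, stage_index])` into per-stage substreams,
  and each simulation replication uses `SeedSequence([master, cell,
  rep])`; all emitted seeds are reduced mod 2³¹.  Re-seeding one stage
  never perturbs another.
- Sigmoid arguments are clipped to ±60 to avoid overflow; surrogate
  queries outside the trained input ranges are clamped with a
  `RuntimeWarning`.
- Lognormal service distributions are parameterized by their own mean
  and standard deviation (converted internally to the underlying normal
  μ, σ); exponential and deterministic families are also supported.
- Division-by-zero states (no free beds, zero-MSE fits, constant
  responses for the desirability bounds) raise typed exceptions rather
  than returning infinities.

## 6. Limitations

- Desk-scale replication counts (20) leave visible Monte-Carlo noise in
  cell means; full-scale runs (1000) are the study condition.
- The surrogate is only trusted inside the trained factor box; the GA
  is restricted to that box by construction.
- The additive main-effects model ignores factor interactions, which an
  L9 array cannot resolve; the GA/surrogate stage partially compensates
  by searching the continuous space.
- TP depends on the desirability bounds, which default to observed
  extrema and therefore vary with the simulated sample.
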