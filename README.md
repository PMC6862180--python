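# emsopt

Simulation–optimization of emergency-department (ED) crowding.

`emsopt` models an ED's patient flow with a discrete-event simulator,
screens four operational control factors with a dynamic Taguchi design,
compresses the simulated response surface into a neural-network
surrogate over two desirability scores, and searches the mixed
continuous/discrete factor space with a genetic algorithm.  A
one-factor-at-a-time (OFAT) sensitivity sweep around the optimum closes
the loop.

## The model in one paragraph

Patients arrive in a Poisson stream (exponential interarrivals sampled by
inverse transform), are triaged on a five-level acuity scale (level 1
most urgent), pass registration, a physician examination, optional
checkup rooms (urinalysis, CT, X-ray) shared with competing outpatient
demand, and are then discharged or admitted to an ED bed to board.
Crowding is scored hourly with EDWIN^C, a work index
Σ nᵢ·tᵢ / (Nₐ·(Bt − BA)) with weights 6 − i so that more-urgent patients
count more; the per-patient outcome is the system time ST (total waiting
plus service minutes).  Four control factors are optimized:

| Factor | Meaning | Levels |
|---|---|---|
| A | crowding threshold at which triage-4/5 walk-ins are persuaded to outpatient clinics (driven by yesterday's EDWIN^C) | continuous 1–3, thresholds 1.5/2.0/2.5 with linear interpolation |
| B | checkup-room routing (fixed sequence / free-room-first / random, with or without ED priority) | 1, 2, 3 |
| C | beds released per hour when the boarded fraction exceeds 15/20/25% | 1, 2, 3 |
| D | sequencing of triage-4/5 patients for examination (shortest-exam-first / registration order / all 4s before 5s) | 1, 2, 3 |

The number of physicians on duty (1 or 2) is the *signal* factor and the
daily arrival rate (350 regular / 425 holiday patients per day) is the
*noise* factor of the dynamic Taguchi design: an L9 inner array for
A–D crossed with signal × noise gives 36 cells, each simulated with
replications.  Per L9 row a zero-intercept ideal function y = βM is
fitted and scored as SN = 10·log₁₀(β/MSE) dB.  Cell means are rescaled
to desirabilities d1 (EDWIN^C) and d2 (ST), a 6-h-2 sigmoid network
(h ∈ 2..8, picked by test RMSE) learns (d1, d2), and the GA maximizes
the total performance TP = d1·d2².

## Quick start

Run the complete workflow at desk scale (20 replications, 3-day
horizon; about a minute on one CPU):

```bash
emsopt full --seed 1 --out-dir out --profile desk
```

This writes `responses.csv` (36 cells × 20 replications),
SN/main-effects tables, the trained surrogate, the GA optimum and the
four sensitivity tables, plus a `report.json` that echoes the resolved
configuration and every per-stage seed.  With seed 1 at desk scale the
run reports:

- Taguchi level selection: (A, B, C, D) = (2, 1, 1, 1) by EDWIN^C and
  (1, 1, 1, 1) by ST.
- Surrogate: structure 6-7-2, train RMSE 0.040, test RMSE 0.088.
- GA optimum: A = 1.0, B = 3, C = 3, D = 1 with TP = 0.186.
- Sensitivity (adjusted TP% vs. the optimum): moving factor A from 1.0
  to 3.0 drops TP by 19.84%; B from 3 to 1 by 25.17%; C from 3 to 1 by
  30.18%; D from 1 to 3 by 25.66%.

The `--profile full` flag switches to 1000 replications over a 7-day
horizon.  Numbers above are properties of this package's calibrated
simulator, not of any particular hospital; see `docs/methods.md`.

Single commands:

```bash
# one scenario, three replications
emsopt simulate --seed 3 --replications 3 --out-dir sim_out
# -> 3 replication(s): mean ST 24.9 min, mean EDWIN^C 0.457

# score one census snapshot
emsopt metrics --counts 2 3 0 0 0 --physicians 2 --beds 20 --admitted 10
# -> EDWIN^C = 1.1000 (good)

# print the 36-cell crossed design
emsopt design
```

Stages can be re-run independently (`emsopt taguchi --no-simulation`,
`emsopt surrogate`, `emsopt optimize`, `emsopt sensitivity`) against the
cached artifacts of earlier stages; a missing artifact raises an error
naming the file.

## Configuration

Everything is configurable from YAML (unknown keys are rejected with
their path):

```yaml
profile: full           # desk (20 reps, 3 days) | full (1000 reps, 7 days)
scenario:
  factor_A: 2.8
  beds_Bt: 30
  service_dists:
    exam: {family: lognormal, mean: 3.5, sd: 2}
ga:
  generations: 1000
  population: 80
```

```bash
emsopt full --config my.yaml --seed 7 --out-dir out
```

## Reproducing results

Every run is deterministic given `--seed`: one master seed is split into
per-stage substreams (and per-replication seeds) with NumPy
`SeedSequence` counters, so re-seeding the GA never perturbs the
simulated responses.  Re-running with the same seed produces
byte-identical `report.json` bodies.  The acceptance script recomputes
the arrival-model target from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
# {"t2": {"value": 350.239, "n": 1000}}
```

## Layout

- `src/emsopt/simulate.py` — event-calendar ED simulator
- `src/emsopt/metrics.py` — EDWIN / EDWIN^C, crowding bands, system time
- `src/emsopt/taguchi.py` — L9 design, ideal-function fit, SN analysis
- `src/emsopt/desirability.py` — d1/d2 ramps and TP = d1·d2²
- `src/emsopt/surrogate.py` — 6-h-2 network, architecture search
- `src/emsopt/ga.py` — mixed-space genetic algorithm
- `src/emsopt/sensitivity.py` — OFAT adjusted-TP% tables
- `src/emsopt/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — scientific account of the model and its defaults
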