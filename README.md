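# shoalspect

Analytics for cooperative predator inspection in fish shoals tracked from
overhead video.  Given per-individual (x, y) trajectories of groups of 5,
10 or 20 fish in a 1.5 m x 1.5 m arena facing a concealable model
predator, the package

- quality-filters tracks (removes detections implying speeds above
  50 cm/s or jumps above 50 cm) and labels the two 7-minute analysis
  phases around the screen lift;
- scores per-fish inspection behaviour (events within 30 cm of the model:
  count, duration, time share, mean and closest distance) and refuge use
  (proportion of a phase the fish was invisible to the tracker);
- measures group cohesion (median inverse Voronoi-cell area, clipped to
  the arena) and shoaling sub-groups (DBSCAN, 6 cm reachability,
  chain-rule-equivalent) as per-minute series;
- fits Bayesian GLMMs (Poisson / Beta / Gamma, trial random intercepts,
  optional Gaussian-process smooth over minutes) with Savage-Dickey Bayes
  factors, 89% highest-density intervals and back-transformed marginal
  effects for the group-size contrasts, plus a Poisson GLM of inspectors
  per joint inspection;
- solves volunteer's dilemma models (baseline mixed ESS and cost/synergy
  extensions) that generate the predictions such experiments test; and
- generates ground-truthed synthetic trajectories and behaviour tables
  emulating the study design, used throughout the test suite.

The core theoretical quantity is the baseline mixed evolutionarily stable
strategy of the volunteer's dilemma: with benefit b, volunteering cost
c < b and group size n, each individual volunteers with probability
p = 1 - (c/b)^(1/(n-1)), so both p and the probability that anyone
volunteers decline with n — the "group size paradox" that the behavioural
analysis puts to an empirical test.

## Worked example

```python
import shoalspect as ss
from shoalspect.simulate import TrialScenario, generate_trajectories

arena = ss.ArenaConfig()
scenario = TrialScenario(n_trials_per_size={5: 1, 10: 1, 20: 1}, seed=3)
traj, meta, truth = generate_trajectories(scenario, arena)

lifts = dict(zip(meta.trial_id, meta.screen_lift_frame))
traj = ss.TrackFilter(arena, screen_lift_frames=lifts).fit_transform(traj)

scorer = ss.BehaviorScorer(arena)
behaviour = scorer.fit_transform(traj)
print(behaviour.groupby("trial_id")["n_inspections"].mean())
```

```
trial_id
T01    5.0
T02    1.7
T03    8.0
Name: n_inspections, dtype: float64
```

The three trials are the 5-, 10- and 20-fish groups; with the default
scenario the large group inspects most often (8.0 events per fish over
the 7-minute exposure vs 5.0 and 1.7), mirroring the qualitative pattern
the experimental design is built to detect.  Merged inspecting parties and
the inspectors-per-inspection GLM:

```python
groups = scorer.group_inspections_
print(ss.fit_inspectors_glm(groups, meta)[["group_size_label", "estimate_log", "mean_inspectors"]])
```

```
  group_size_label  estimate_log  mean_inspectors
0            small      0.083382         1.086957
1     intermediate      0.268264         1.307692
2            large      1.032123         2.807018
```

Estimates are log mean inspectors per joint inspection; larger groups
field larger inspecting parties.  The theory side:

```python
import shoalspect as ss
curve = ss.predict_group_size_curve("baseline", None, [5, 10, 20], cost_volunteer=0.3)
print(curve[["n", "p_volunteer", "p_good"]].round(4))
```

```
    n  p_volunteer  p_good
0   5       0.2599  0.7780
1  10       0.1252  0.7376
2  20       0.0614  0.7184
```

Individual volunteering probability and the chance that anyone inspects
both fall with group size — the baseline prediction that the empirical
result contradicts; `variant="groupsize_cost"` or `"synergy"` produce the
reversed orderings discussed as model extensions.

A `shoalspect` command-line tool wraps the same steps
(`simulate`, `ingest`, `score`, `cohesion`, `fit`, `inspectors`,
`predict-vd`); run `shoalspect --help`.

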