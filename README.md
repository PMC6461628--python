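# inflamnet

Data-driven network analysis of inflammatory-mediator time courses.

Acute inflammatory states — pediatric acute liver failure after
acetaminophen overdose is the motivating setting — are driven by dozens of
interacting cytokines, chemokines and damage-associated molecules (HMGB1,
nitric oxide products) measured serially in serum or culture supernatant.
Individual mediator trajectories rarely separate patient groups; the
*structure of co-movement* among mediators often does.  `inflamnet` gives
analysts of multiplexed (Luminex-style) panel data two complementary
network views of such cohorts:

* **Dynamic Network Analysis (DyNA).**  For each consecutive time window
  (e.g. days d0–d1, d1–2, …, d6–7, or hours 1–3, 3–6, 6–24), mediators *i*
  and *j* are connected when the Pearson correlation of their pooled
  within-window observations satisfies |r| ≥ a stringency threshold
  (default 0.7); edges carry the sign of r, so anti-correlated pairs are
  counted separately.  Each window's network is summarised by its
  **complexity**

      complexity = (N₁ + N₂ + … + Nₙ) / (n − 1) = 2|E| / (n − 1),

  where Nᵢ is the number of connections of mediator *i* and *n* the number
  of mediators assayed, and a group's **total connections** is Σ over
  windows of |E|.

* **Dynamic Bayesian network (DBN) inference.**  A first-order directed
  model over discretized mediator levels — each mediator at time *t* may
  depend on mediators at *t − 1*, its own lag included — is learned by
  BDeu-scored greedy parent-set search, with per-edge confidence from
  subject-level bootstrap resampling.  Mediators that *drive their own
  expression* (self-feedback loops) are reported as the network's central
  nodes.

A synthetic-cohort generator with planted network structure (hub mediators
with self-feedback, signed couplings, per-window coupling changes,
log-normal assay noise, missing samples, minimum-samples inclusion rule)
makes every stage testable end-to-end with known ground truth.

## Worked example

```python
from inflamnet import (generate_paperlike_presets, generate_cohort, filter_min_samples,
                       complexity_trajectory, total_connections, negative_fraction,
                       infer_dbn, self_feedback_nodes, HUMAN_DAILY_SCHEDULE)

human, _ = generate_paperlike_presets(seed=1)
panel = filter_min_samples(generate_cohort(human).panel, min_times=3)
for group in panel.group_names:
    traj, nets = complexity_trajectory(panel, group, HUMAN_DAILY_SCHEDULE)
    neg, tot, frac = negative_fraction(nets)
    print(f"{group:18s} total={total_connections(nets):4d} "
          f"peak complexity={max(c for _, c, _ in traj.points):5.1f} "
          f"negative={neg}/{tot}")

model = infer_dbn(panel, "non-survivor", n_boot=25, seed=1)
print("central nodes (self-feedback):", self_feedback_nodes(model, min_confidence=0.5))
```

prints

```
APAPo+NAC          total= 533 peak complexity=  6.0 negative=0/533
non-APAPo+NAC      total= 554 peak complexity=  6.5 negative=6/554
non-APAPo non-NAC  total= 147 peak complexity=  1.6 negative=0/147
non-survivor       total= 767 peak complexity= 13.8 negative=1/767
central nodes (self-feedback): ['HMGB1']
```

The synthetic human cohort (four groups of 13 / 8 / 40 / 12 subjects,
sampled daily over 8 days) plants the densest mediator coupling in the
non-survivor group and the sparsest in the non-APAPo non-NAC group, and
the analysis recovers exactly that signature: non-survivors accumulate the
most connections across the seven windows and the highest peak complexity,
while the sparsest group never rises above complexity 5.  The DBN finds
the planted HMGB1 self-feedback loop — the hub "driving its own
expression" — as the central node of the non-survivor network.

The same pipeline runs from the shell:

```sh
inflamnet simulate --preset human --seed 1 --outdir synthetic
inflamnet run --input synthetic/panel.csv --schedule human-daily --outdir run
inflamnet compare --rundir run
```

`run/` then holds per-group, per-window edge lists, complexity and totals
tables, HMGB1-focused subnetworks, DBN edge/confidence tables and a
manifest that reproduces the run exactly.

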