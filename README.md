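# reomap

Analysis of hippocampal CA1 place-cell recordings from two-context spatial
reorientation experiments — for systems neuroscientists studying how one
population of neurons simultaneously encodes *heading* (which way the
animal thinks it is facing) and *context* (which of two look-alike chambers
it is in).

A disoriented animal returned to a rectangular chamber can align its
internal map with the geometry in either of two congruent orientations
(0° or 180°).  Across two chambers that differ only in visual features,
place cells split into **feature-insensitive (FI)** cells, whose fields
rotate with the ensemble but keep the same location in both contexts, and
**feature-sensitive (FS)** cells, whose fields remap across contexts.  The
package implements the full analysis chain around this phenomenon:

* occupancy-normalized rate maps (1 cm bins, σ = 3 cm smoothing, 2 cm/s
  speed filter, 0.05 s occupancy mask) and their anisotropic compression to
  a 20 × 20 square;
* **best-match rotation** (BMR): argmax over θ ∈ {0°, 90°, 180°, 270°} of
  the pixel-wise Pearson correlation r(rot_θ(map_i), map_j), with ensemble
  coherency ranked across simultaneously recorded cells (chance 25%);
* **center-out angles** of 95th-percentile place fields, circular pairwise
  differences, and angle doubling (θ → 2θ mod 360°) for axial statistics;
* **context similarity**: max over {0°, 180°} of the correlation between a
  cell's geometry-aligned average maps of the two contexts, with FS ≤ 0.3,
  and the decile/asymptotic-regression procedure
  (y(x) = a − (a − b)e^(−cx)) that selects this threshold from data;
* population-vector **normalized dot products** and leave-one-out context
  prediction from firing location;
* linear-SVM decoding (C = 1, empirical class priors, leave-one-out) of
  heading from sin/cos center-out angles and of context/heading from mean
  firing rates, including cross-day transfer;
* **rate remapping** matrices |r̄_i − r̄_j| split within vs across contexts;
* Bernoulli **Bayes factors** for digging behavior,
  BF = [1/(b−a) ∫ₐᵇ θᶻ(1−θ)^(N−z) dθ] / [θ₀ᶻ(1−θ₀)^(N−z)],
  with θ₀ = 0.5 (rewarded axis) or 0.25 (rewarded corner), group
  BF = ∏ᵢ BFᵢ, and the ln 3 evidence bounds;
* a **synthetic-session generator** with full ground truth (cell classes,
  ensemble orientations, rate gains, dig–orientation coupling) that
  emulates the study design: 12 alternating-context trials/day over 3 days,
  coherence and across-context rate gain growing with learning.

See `docs/methods.md` for the models, assumptions, and parameter defaults.

## Worked example

```python
import reomap
from reomap.session import compute_session_tables
from reomap.behavior import bayes_factor_by_animal

cfg = reomap.SimConfig(n_animals=2, n_days=1, n_fi_cells=16, n_fs_cells=4,
                       coherence_by_day=(0.9,), rate_gain_by_day=(1.5,),
                       dig_probs_by_day=((0.5, 0.3, 0.1, 0.1),), seed=7)
bundles = reomap.generate_study(cfg)
tables = compute_session_tables(bundles[0])

classes = reomap.classify_cells(tables)
print(classes["cell_class"].value_counts().to_dict())
print("mean similarity FI:", classes.query("cell_class=='FI'")["similarity"].mean())
print("mean similarity FS:", classes.query("cell_class=='FS'")["similarity"].mean())

print("heading accuracy:",
      reomap.predict_heading_from_alignment(tables.angles, tables.dig1))
print("context-from-rate accuracy:",
      reomap.predict_from_rates(tables.mean_rates, tables.contexts,
                                tables.dig1, "context",
                                field_presence=tables.field_presence))

res = bayes_factor_by_animal([t for b in bundles for t in b.trials], "cg")
print("group log BF:", res.log_bf_group, "->", res.group_decision)
```

Output:

```
{'FI': 17, 'FS': 3}
mean similarity FI: 0.961
mean similarity FS: -0.095
heading accuracy: 0.9
context-from-rate accuracy: 1.0
group log BF: 6.03 -> alt
```

Reading it: 17 of 20 cells classify as FI with near-perfect across-context
similarity (0.96); the recovered FS cells sit far below the 0.3 threshold
(−0.10).  One planted FS cell lands on the FI side — its context-B field
happened to fall close to a geometric image of its context-A field, the
known identifiability limit of the alignment procedure.  The dig side is
decoded from map alignment on 90% of held-out trials (chance 50%), the
chamber identity is decoded perfectly from mean rates at a 1.5× rate gain,
and the group Bayes factor (log BF = 6.0 > ln 3 ≈ 1.1) gives substantial
evidence that these synthetic animals dig on the rewarded axis above
chance.

A full multi-stage run (simulation → maps → behavior → BMR/coherency →
context similarity → decoding → rate remapping → report) with CSV/JSON
outputs and a config-hashed manifest:

```bash
reomap run --out runs/demo --seed 1
reomap simulate --out data/ --seed 2          # session bundles as CSV
reomap behavior-bf --model cg --trials runs/demo/trials.csv
```

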