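# engramkit

Quantitative analysis of chemogenetic engram-reactivation experiments:
recognition-memory scoring, c-Fos/mCherry ensemble-reactivation statistics,
and dendritic spine morphometry — with synthetic-data generators that give
every stage a known ground truth.

## Who this is for

Labs running activity-dependent tagging experiments (TRAP-style Fos-promoter
labeling plus DREADD reactivation) typically collect three kinds of data:
manually scored object-exploration logs, per-slice immunofluorescence cell
counts (DAPI⁺, c-Fos⁺, mCherry⁺, double-positive), and per-spine
morphometric tables exported from 3-D filament reconstructions.  engramkit
turns each into the standard derived statistics, with animals as the
statistical unit throughout, and ships generators that simulate all three
input classes from known parameters so the whole chain is testable without
any imaging data.

## The statistics

**Discrimination index.** For a recognition trial with exploration times
t_novel and t_familiar,

    DI = (t_novel − t_familiar) / (t_novel + t_familiar)  ∈ [−1, 1],

with a one-sample t-test of per-animal DIs against chance (0).  DI is
*undefined* (not 0) when total exploration is zero; such trials are
excluded from group means and flagged.

**Reactivation above chance.** Per slice with counts D (DAPI⁺), C (c-Fos⁺),
M (mCherry⁺) and O (double-positive):

    co-localization %  = 100 · O / M
    chance             = (C/D) · (M/D)
    enrichment         = (O/D) / chance,

so enrichment = 1 when c-Fos and mCherry labels are independent.  Slice
values are averaged within animal (unweighted, 4–5 sections per animal).
c-Fos densities after encoding are also expressed as fold change over the
mean density of the matched home-cage control group.

**Spine morphometry.** After refinement (drop neckless artifacts and spines
below the 0.4 µm minimum reconstructable diameter), each spine gets:

- *geometry* — surface area and volume of a conical frustum from the
  attachment radius r_a to the terminal radius r_t over height
  h = length − r_t, plus the terminal hemisphere, minus the attachment
  hemisphere:
  V = (πh/3)(r_a² + r_a·r_t + r_t²) + (2/3)π(r_t³ − r_a³),
  A = π(r_a+r_t)√(h² + (r_a−r_t)²) + 2π(r_t² − r_a²);
- *class* — one of thin / long thin / mushroom / stubby / filopodia from
  length, head max diameter and the length-to-width ratio (LWR), applied
  with fixed precedence: mushroom (head ≥ 0.6 µm) → stubby (LWR ≤ 1) →
  filopodia (length > 2 µm) → long thin (1–2 µm) → thin (≤ 1 µm);
- *density* — per-class counts per 20 µm of dendrite segment;
- *cluster* — z-score → PCA → k-means on a 16-feature matrix
  (`engramkit.FEATURE_COLUMNS`), k fixed (default 5) or chosen by the
  elbow method, reported against the rule classes as a cluster-by-class
  contingency table.

## Worked example

```python
import engramkit as ek
import pandas as pd

# behavior: score a simulated recall trial
log = ek.gen_trial_log(ek.BehaviorGenConfig(preference_novel=0.75, n_bouts=30, seed=1))
s = ek.summarize_trial(log)
print(f"DI = {s.di:.3f}")

# ensembles: recover the reactivation enrichment of a tagged population
counts = pd.concat(
    [ek.gen_slice_population(
         ek.EnsembleGenConfig(n_slices=5, cells_per_slice=2000,
                              p_react_tagged=0.42, p_active_untagged=0.08275,
                              seed=ek.child_seed(1, a)),
         animal_id=f"m{a}")
     for a in range(6)], ignore_index=True)
print(f"overlap/chance = {ek.aggregate_animal(counts)['enrichment'].mean():.3f}")

# spines: refine, classify, cluster
table = ek.gen_spine_table(ek.SpineGenConfig(n_spines=1500, neckless_fraction=0.1, seed=1))
kept, report = ek.refine_spines(table)
kept["class_label"] = ek.classify_spines(kept)
model = ek.SpineClusterer(n_clusters=5, random_state=0).fit(ek.compute_feature_matrix(kept))
print(ek.cluster_class_crosstab(model.labels_, kept["class_label"]))
```

prints

```
DI = 0.285
overlap/chance = 4.190
         thin  long_thin  mushroom  stubby  filopodia
cluster
0         361          0         0      45          0
1           0        441         0       0          0
2           0          0       141       0          0
3           0          0         0       0        216
4           0          0       138       0          0
```

The trial simulated with a 75% novel-object preference scores DI ≈ 0.285;
six synthetic animals tagged at 5% with conditional reactivation
probabilities 0.42 (tagged) vs 0.08275 (untagged) recover an
overlap-over-chance of 4.19 against the ground-truth value 4.216; and the
unsupervised clusters align almost perfectly with the five morphological
classes (thin and stubby merge into one cluster, mushroom splits in two —
exactly the kind of structure the cluster-by-class heatmap is meant to
reveal).

A full simulate–analyze–recover run is one command:

```bash
engramkit demo --out demo_run --seed 4
```

which writes per-animal audit tables, group tables and a hash manifest, and
reports the recovery of the generative enrichment for an enriched and a
chance-level group.

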