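"""Discover stereotyped foraging modules from excursion features.

Featurizes every valid excursion with the 52-measure catalog,
standardizes the matrix, and selects the number of modules by split-half
reproducibility (Ward clustering, Hungarian-matched Jaccard stability).
On the toy cohort restricted to one phase, the two planted archetypes are
recovered exactly at a high stability threshold.
"""

from sklearn.metrics import adjusted_rand_score

import foragekit as fk
from foragekit import features as feat
from foragekit import modules as mod
from foragekit import segmentation as seg

cfg = fk.make_default_config("two_archetype_toy", seed=1)
traj, meta, _, truth = fk.simulate_cohort(cfg)
geom = fk.ArenaGeometry()
ann = seg.annotate_zones(traj, geom)
exc = seg.segment_excursions(ann, geom)
fm = feat.feature_matrix(exc, ann, geom)

keep = fm["phase"] == "Exploration"
std, record = feat.standardize(fm.loc[keep, list(feat.MEASURE_NAMES)])
print(f"{keep.sum()} Exploration excursions × {std.shape[1]} informative "
      f"measures ({len(record.dropped)} constant columns dropped)")

catalog = mod.select_module_count(std.to_numpy(), range(2, 7), n_splits=20,
                                  stability_threshold=0.95, seed=0)
keys = fm.loc[keep, ["mouse_id", "phase", "index"]].copy()
keys["module"] = catalog.assignment
merged = keys.merge(truth.excursions, on=["mouse_id", "phase", "index"])
ari = adjusted_rand_score(merged["archetype"], merged["module"])

print(f"chosen K = {catalog.K} modules "
      f"(per-module split-half stability {catalog.reproducibility.round(3)})")
print(f"adjusted Rand index vs planted archetypes: {ari:.3f}")
print("K=2 with ARI 1.0 means the two planted excursion types were "
      "recovered exactly; stability ~1 means every random half-split of "
      "the data reproduces the same two modules.")
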