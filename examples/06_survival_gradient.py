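"""Recover the injury survival gradient with the full pipeline.

Simulates a small cohort (3 control sections, 2 injured individuals at
each of 0.6/0.8/1.0/1.2 mm caudal to the epicenter), identifies neurons
from probability maps, registers the atlas (identity here), pivots to a
sections × regions count matrix and expresses injured counts as
percentages of the control median.  The printed medians should fall
near the generating gradient: ~2.3% at 0.6 mm rising ~20 percentage
points per 0.2 mm to a ~40% plateau.
"""

import pandas as pd

import cordquant as cq
from cordquant.pipeline import identity_landmarks

atlas = cq.build_toy_atlas((2000, 1500), 10)
config = cq.SimulationConfig(seed=0)

transform = cq.fit_tps(identity_landmarks(atlas))
warped = cq.warp_regions(atlas, transform, densify_um=25.0)

design = [("control", None, 3)] + [("injury+vehicle", d, 2)
                                   for d in (0.6, 0.8, 1.0, 1.2)]
sections = cq.simulate_cohort(atlas, config, design, seed=2026)

rows, meta = [], []
for image, truth in sections:
    prob = cq.simulate_probability_map(truth, image, miscalibration=0.1,
                                       seed=len(rows) + 1)
    det = cq.probmap_to_detections(prob, image.pixel_size,
                                   section_id=image.section_id)
    rid = cq.assign_to_regions(det, warped)
    rows.extend({"section_id": image.section_id, "region_id": r} for r in rid)
    meta.append({"section_id": image.section_id, "individual": image.section_id,
                 "condition": image.condition, "distance_mm": image.distance_mm})

rc = cq.region_counts(pd.DataFrame(rows), pd.DataFrame(meta),
                      region_order=atlas.region_ids)
profile = cq.survival_percent(rc)
print(f"control reference: median {profile.control_total:.1f} neurons/section\n")

dp = cq.distance_profile(profile)
inj = dp[dp.condition == "injury+vehicle"]
print("median whole-section survival vs distance to epicenter:")
print(inj[["distance_mm", "median_total_survival_pct", "increment_pct"]]
      .to_string(index=False))

groups = [
    profile.total_survival[rc.meta.distance_mm == d].to_numpy()
    for d in (0.6, 0.8, 1.0, 1.2)
]
h, p = cq.kruskal_wallis(groups)
print(f"\nKruskal-Wallis across distances: H = {h:.2f}, p = {p:.3g}")
print("(generating curve: 2.3%, 20%, 40%, 40% at 0.6, 0.8, 1.0, 1.2 mm)")
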