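"""Estimate displacement retardation from noisy synthetic profiles.

Averages the subjects of each group into mean profiles, fits GCV-smoothed
cubic splines, builds cumulative thickness curves and reads off the
horizontal displacement against the control curve — then compares with the
generator's analytic ground truth.
"""

import pandas as pd

import foveametry as fm

cohort = fm.generate_cohort(fm.default_synthetic_config(seed=0))
estimates = fm.estimate_cohort_retardation(cohort.profiles, smoothing="gcv")

truth = {(r.group, r.layer, r.eccentricity_um): r.true_retardation_um
         for r in cohort.ground_truth.itertuples(index=False)}
rows = []
for e in estimates:
    key = (e.group.value, e.layer.value, e.eccentricity_um)
    if e.ok and key in truth:
        rows.append({"group": key[0], "layer": key[1], "E_um": key[2],
                     "estimated_um": round(e.retardation_um, 1),
                     "true_um": round(truth[key], 1),
                     "error_um": round(e.retardation_um - truth[key], 1)})
df = pd.DataFrame(rows)
print(df.to_string(index=False))

# group summaries follow the 12-cell convention: the three displaced
# layers (GCL+IPL, INL, OPL) x four eccentricities in the foveal region
displaced = {ly.value for ly in fm.types.IRL_TYPE_LAYERS}
for grp in ("PG1", "PG2", "PG3"):
    s = fm.group_summary([e for e in estimates
                          if e.group.value == grp and e.ok
                          and e.layer.value in displaced])
    print(f"\n{grp}: mean retardation {s.mean_um_rounded} µm "
          f"(range {s.min_um:.0f}-{s.max_um:.0f} µm over {s.n_cells} cells)")
print("\nThe mean/range lines are the foveal-region (300-900 µm) summaries; "
      "errors of a few µm reflect the 2 µm segmentation noise in the cohort.")
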