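"""Screen for adulteration and estimate the syrup content.

Runs a reduced rice scenario, trains the class-weighted random forest
(pure vs adulterated) and the regression forest (syrup % v/v) on the
training honeys and evaluates on held-out honeys. Forests here are
small (300 trees, 12 honeys) to keep the example quick; at this scale
the per-level errors are noticeably larger than in the full 34-honey
configuration that scripts/acceptance.py runs.
"""

from honeyscreen import RfConfig, ci_small_design
from honeyscreen.pipeline import analyze_scenario, process_scenario

design = ci_small_design(
    seed=0,
    n_honeys=12,
    proportions=(5.0, 10.0, 20.0, 50.0, 80.0),
    rt_span={"HILIC_neg": (0.0, 160.0), "RP_pos": (0.0, 200.0)},
)
data = process_scenario(design, "rice")
report = analyze_scenario(
    data, n_test_honeys=3, split_seed=0, rf=RfConfig(num_trees=300, seed=0), with_pca=False
)

c, r = report.classification, report.regression
print(f"train/test samples: {report.n_train}/{report.n_test}  "
      f"test honeys: {report.test_honeys}")
print(f"\nclassification OOB error: {c.oob_error:.2f} %   "
      f"held-out accuracy: {c.test_accuracy:.1f} %")
print(c.confusion_table())
print(f"\nregression R^2 (Pearson^2): {r.r_squared:.3f}   RMSE: {r.rmse:.2f} % v/v")
print("mean absolute error by true level:",
      {f"{k:g}%": round(v, 2) for k, v in r.per_level_mae.items()})
print("\nThe tally lists correct/total held-out predictions per true syrup "
      "level; RMSE is in percentage points of syrup volume fraction.")
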