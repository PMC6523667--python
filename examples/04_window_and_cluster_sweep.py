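"""Window-length and electrode-cluster sweeps with report files.

Runs the two orchestrated experiments on a small cohort: accuracy as
a function of epoch length (here 5/8/12 s to keep the example quick;
the full grid is 5-12 s), and the region-wise analysis at 12 s over
the five anatomical clusters plus the whole montage. Writes the
result tables (CSV + JSON) to ./sweep_report/.
"""

from eegad import CohortSpec, generate_cohort
from eegad.evaluate import cluster_sweep, demographics, report, window_sweep

spec = CohortSpec(
    n_controls=3, n_mild=2, n_moderate=2, fs=160.0,
    duration_range_per_group={
        "CN": (70.0, 90.0), "mild": (70.0, 90.0), "moderate": (70.0, 90.0)},
    effect_size=0.4,  # softened contrast, as in example 03
    seed=5,
)
cohort = generate_cohort(spec)

wsweep = window_sweep(cohort, windows=(5, 8, 12),
                      problems=("CN/AD", "CN/moderate"), seed=1, folds=5)
print("accuracy (%) by window length:")
for (problem, window), m in sorted(wsweep.window_grid.items()):
    print(f"  {problem:14s} {window:2d} s: {m.accuracy:6.2f} "
          f"(kappa {m.kappa:.3f}, n={m.n_epochs})")

csweep = cluster_sweep(cohort, window_s=12, problems=("CN/AD",),
                       clusters=("whole", "anterior", "central", "posterior"),
                       seed=1, folds=5)
print("\nCN/AD accuracy (%) by electrode cluster at 12 s:")
for (_, cluster), m in sorted(csweep.cluster_grid.items()):
    print(f"  {cluster:10s}: {m.accuracy:6.2f} (kappa {m.kappa:.3f})")

wsweep.cluster_grid = csweep.cluster_grid
paths = report(wsweep, demographics(cohort), "sweep_report")
print("\nreport files:", ", ".join(str(p) for p in paths.values()))
print("\nLonger windows give the entropy estimators more samples per epoch, "
      "so accuracy\ntypically rises toward 12 s; the default profiles put "
      "the strongest contrast\nposteriorly.")
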