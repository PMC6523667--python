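"""Generate a small synthetic EEG cohort and inspect its demographics.

Builds a 7-subject cohort (3 controls, 2 mild AD, 2 moderate AD) with
short recordings at 200 Hz, prints the metadata table, and runs the
two cohort-level statistics: Welch's ANOVA on age (group means should
not differ much — the groups are age-matched by construction) and a
Kruskal-Wallis test on MMSE (groups must differ strongly: the score
ranges barely overlap).
"""

from eegad import CohortSpec, generate_cohort
from eegad.evaluate import demographics

spec = CohortSpec(
    n_controls=3, n_mild=2, n_moderate=2, fs=200.0,
    duration_range_per_group={
        "CN": (40.0, 55.0), "mild": (40.0, 55.0), "moderate": (40.0, 55.0)},
    seed=7,
)
cohort = generate_cohort(spec)

print("subject  group     age  MMSE  duration_s  artifacts")
for s in cohort:
    print(f"{s.subject_id:7s}  {s.group:8s} {s.age:5.1f}  {s.mmse:4d}"
          f"  {s.recording.duration:10.1f}  {len(s.recording.artifact_mask):9d}")

d = demographics(cohort)
print(f"\nWelch ANOVA on age:  F={d.welch_F:.3f}, "
      f"df=({d.welch_df[0]:.0f}, {d.welch_df[1]:.2f}), p={d.welch_p:.3f}")
print(f"Kruskal-Wallis on MMSE: H={d.kw_H:.3f}, p={d.kw_p:.4f}")
print("mean MMSE ranks:", {g: round(r, 2) for g, r in d.mean_ranks.items()})
print("\nThe expected pattern for an age-matched dementia cohort: the age "
      "test stays\nnon-significant while the MMSE groups separate cleanly "
      "(with 7 subjects the\np-value is borderline; at the canonical 10/8/6 "
      "cohort the mean ranks are\n19.5/10.5/3.5 and p < 0.001).")
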