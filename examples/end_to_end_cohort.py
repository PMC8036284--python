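"""Full pipeline on a synthetic cohort: phantoms to malignancy ranking.

Generates a labelled cohort (malignant-like: several drifting foci;
benign-like: one stable focus), measures the four ordinal features from
each nodule's contour trees, ranks the cohort by GDM2 distance from the
pattern object, and compares the 0.4-threshold call with the generated
labels.
"""

import warnings

from pculfdg import generate_cohort, run_cohort

warnings.filterwarnings("ignore", category=UserWarning)

cohort = generate_cohort(n_malignant_like=8, n_benign_like=6, seed=4)
table, summary, _ = run_cohort([(n.nodule_id, n.series, n.label) for n in cohort])

print(table[["nodule_id", "label", "v1", "v2", "v3", "v4", "distance",
             "group", "expected_label"]].to_string(index=False))
print(f"\ngroup sizes: {summary['group_sizes']}")
stats = summary["statistics"]
print(f"confidently grouped (I+IV): {stats['confident_pct']}%  "
      f"indeterminate (II+III): {stats['indeterminate_pct']}%")
print(f"label agreement at the 0.4 threshold: {summary['label_agreement_pct']}%")
print("Small distances mean the nodule's feature profile resembles the "
      "ideal malignant pattern (4,3,3,2).")
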