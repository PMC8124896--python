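"""Recompute published aggregate percentages from the packaged count tables.

The packaged fixtures store the raw counts of the multi-institutional
cohort's baseline tables; percentages are recomputed with the same
half-up one-decimal rounding the source used, so each printed value is an
exact worked example.
"""

from pnetrecur import load_count_fixture, percents_from_counts

table1 = percents_from_counts(load_count_fixture("table1"))
cohort = percents_from_counts(load_count_fixture("cohort"))

checks = [
    (table1, "nodes_positive", "yes", "all", "node-positive share"),
    (table1, "resection_type", "distal_pancreatectomy", "all", "distal pancreatectomy"),
    (table1, "grade", "G1", "all", "grade 1 tumors"),
    (cohort, "recurrence", "yes", "all", "crude recurrence"),
    (cohort, "er_status", "early", "all", "early recurrence (<=18 mo)"),
]
for frame, variable, category, group, label in checks:
    row = frame.query(
        "variable == @variable and category == @category and group == @group"
    ).iloc[0]
    print(f"{label:<28} {row['count']:>4}/{row['denominator']:<4} = {row['pct']}%")

# These percentages match the published table values digit for digit; they
# anchor the rounding rule (half-up, one decimal) and the per-variable
# complete-case denominators the summary machinery uses.
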