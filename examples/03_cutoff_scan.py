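"""Detect the early-recurrence cut-off by the minimum p-value scan.

Sweeps candidate RFS thresholds (6–48 months), tests post-recurrence
survival between the induced early/late arms at each, picks the minimum-p
candidate, and attaches the permutation-adjusted p that accounts for having
scanned many thresholds.
"""

from pnetrecur import (
    SyntheticConfig,
    generate_cohort,
    permutation_adjusted_p,
    scan_cutoffs,
    select_optimal,
)

records, truth = generate_cohort(SyntheticConfig(seed=7))
recurred = [r for r in records if r.recurrence]

scan = scan_cutoffs(recurred)  # grid 6..48 months, >=10 recurrences per arm
cutoff, p = select_optimal(scan)
adjusted = permutation_adjusted_p(recurred, n_perm=999, seed=7)

profile = scan.to_frame()
around = profile[profile.candidate_month.between(cutoff - 3, cutoff + 3)]
print(around.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\nselected cut-off: {cutoff:g} months (naive min p = {p:.3g})")
print(f"permutation-adjusted p: {adjusted:.3g}")
print(f"planted truth was: {truth.planted_cutoff:g} months")

# The naive minimum p overstates significance because the same data chose
# the threshold; the adjusted p stays honest and should still be small here
# because the planted survival divergence is real.
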