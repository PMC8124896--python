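# Cohort-level aggregates: crude recurrence, early/late split at the
# 18-month cut-off, first-recurrence pattern, lymphadenectomy share.
# Published pattern percentages mix denominators (127 vs 126); counts are
# stored as printed and percentages recompute over the count sum.
variable	category	group	count
recurrence	yes	all	127
recurrence	no	all	680
er_status	early	all	49
er_status	late	all	77
er_status	none	all	681
recurrence_pattern	local	all	53
recurrence_pattern	distant	all	66
recurrence_pattern	local_and_distant	all	8
lymphadenectomy	yes	all	719
lymphadenectomy	no	all	88
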