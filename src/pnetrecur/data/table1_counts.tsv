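# Aggregate baseline counts for the full resected-pNET cohort, by recurrence
# status.  "unknown" rows keep per-variable denominators aligned with the
# published group totals where percentages were reported over the full group.
variable	category	group	count
male	yes	all	406
male	no	all	401
male	yes	no_recurrence	344
male	no	no_recurrence	337
male	yes	recurrence	62
male	no	recurrence	65
asa	I	all	44
asa	II	all	355
asa	III	all	361
asa	IV	all	17
asa	I	no_recurrence	32
asa	II	no_recurrence	305
asa	III	no_recurrence	304
asa	IV	no_recurrence	15
asa	unknown	no_recurrence	25
asa	I	recurrence	12
asa	II	recurrence	50
asa	III	recurrence	57
asa	IV	recurrence	2
asa	unknown	recurrence	5
functional	yes	all	90
functional	no	all	717
functional	yes	no_recurrence	81
functional	no	no_recurrence	600
functional	yes	recurrence	9
functional	no	recurrence	118
location	head	all	246
location	body	all	238
location	tail	all	321
location	unknown	all	2
location	head	no_recurrence	189
location	body	no_recurrence	210
location	tail	no_recurrence	281
location	unknown	no_recurrence	1
location	head	recurrence	57
location	body	recurrence	28
location	tail	recurrence	40
location	unknown	recurrence	1
resection_type	pancreatoduodenectomy	all	246
resection_type	distal_pancreatectomy	all	451
resection_type	enucleation_central	all	64
resection_type	pancreatoduodenectomy	no_recurrence	188
resection_type	distal_pancreatectomy	no_recurrence	397
resection_type	enucleation_central	no_recurrence	56
resection_type	unknown	no_recurrence	40
resection_type	pancreatoduodenectomy	recurrence	58
resection_type	distal_pancreatectomy	recurrence	54
resection_type	enucleation_central	recurrence	8
resection_type	unknown	recurrence	6
severe_complication	yes	all	197
severe_complication	no	all	610
severe_complication	yes	no_recurrence	159
severe_complication	no	no_recurrence	522
severe_complication	yes	recurrence	38
severe_complication	no	recurrence	88
grade	G1	all	437
grade	G2	all	211
grade	unknown	all	159
grade	G1	no_recurrence	399
grade	G2	no_recurrence	158
grade	unknown	no_recurrence	124
grade	G1	recurrence	38
grade	G2	recurrence	53
grade	unknown	recurrence	35
lvi	yes	all	170
lvi	no	all	637
lvi	yes	no_recurrence	126
lvi	no	no_recurrence	555
lvi	yes	recurrence	44
lvi	no	recurrence	82
pni	yes	all	124
pni	no	all	683
pni	yes	no_recurrence	98
pni	no	no_recurrence	583
pni	yes	recurrence	26
pni	no	recurrence	100
margin	R0	all	687
margin	R1	all	120
margin	R0	no_recurrence	590
margin	R1	no_recurrence	91
margin	R0	recurrence	97
margin	R1	recurrence	29
t_stage	T1	all	348
t_stage	T2	all	241
t_stage	T3	all	154
t_stage	unknown	all	64
t_stage	T1	no_recurrence	334
t_stage	T2	no_recurrence	201
t_stage	T3	no_recurrence	106
t_stage	unknown	no_recurrence	40
t_stage	T1	recurrence	14
t_stage	T2	recurrence	40
t_stage	T3	recurrence	48
t_stage	unknown	recurrence	24
nodes_positive	yes	all	177
nodes_positive	no	all	630
nodes_positive	yes	no_recurrence	118
nodes_positive	no	no_recurrence	563
nodes_positive	yes	recurrence	59
nodes_positive	no	recurrence	67
era	1998-2005	all	113
era	2006-2010	all	278
era	2011-2016	all	416
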