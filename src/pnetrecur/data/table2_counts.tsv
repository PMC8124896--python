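# Aggregate baseline counts for recurred patients, split early (RFS <= 18
# months) versus late recurrence.  "unknown" rows align denominators with the
# published group totals (early n = 49, late n = 77).
variable	category	group	count
male	yes	early	21
male	no	early	28
male	yes	late	41
male	no	late	36
asa	I	early	3
asa	II	early	21
asa	III	early	22
asa	IV	early	1
asa	unknown	early	2
asa	I	late	9
asa	II	late	29
asa	III	late	35
asa	IV	late	1
asa	unknown	late	3
functional	yes	early	4
functional	no	early	45
functional	yes	late	5
functional	no	late	72
location	head	early	23
location	body	early	9
location	tail	early	16
location	unknown	early	1
location	head	late	34
location	body	late	19
location	tail	late	24
resection_type	pancreatoduodenectomy	early	21
resection_type	distal_pancreatectomy	early	21
resection_type	enucleation_central	early	6
resection_type	unknown	early	1
resection_type	pancreatoduodenectomy	late	37
resection_type	distal_pancreatectomy	late	33
resection_type	enucleation_central	late	2
resection_type	unknown	late	5
grade	G1	early	14
grade	G2	early	19
grade	unknown	early	16
grade	G1	late	24
grade	G2	late	34
grade	unknown	late	19
lvi	yes	early	18
lvi	no	early	31
lvi	yes	late	26
lvi	no	late	51
pni	yes	early	10
pni	no	early	39
pni	yes	late	16
pni	no	late	61
margin	R0	early	39
margin	R1	early	10
margin	R0	late	58
margin	R1	late	19
t_stage	T1	early	6
t_stage	T2	early	12
t_stage	T3	early	24
t_stage	unknown	early	7
t_stage	T1	late	8
t_stage	T2	late	28
t_stage	T3	late	24
t_stage	unknown	late	17
nodes_positive	yes	early	23
nodes_positive	no	early	26
nodes_positive	yes	late	36
nodes_positive	no	late	41
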