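# Synthetic alteration -> node-status map for the packaged p53-like network.
# p53 itself carries no alteration entry (wild-type-p53 cohort assumption).
alteration_id	node	status
ATM_inact	ATM	I
CHK2_inact	CHK2	I
WIP1_act	WIP1	A
WIP1_inact	WIP1	I
MDM2_act	MDM2	A
MDM2_inact	MDM2	I
MDMX_act	MDMX	A
MDMX_inact	MDMX	I
CYCG_act	CYCG	A
CYCG_inact	CYCG	I
PTEN_inact	PTEN	I
AKT_act	AKT	A
AKT_inact	AKT	I
p21_inact	p21	I
CYCE_act	CYCE	A
CYCE_inact	CYCE	I
E2F1_act	E2F1	A
BCL2_act	BCL2	A
BCL2_inact	BCL2	I
BAX_inact	BAX	I
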