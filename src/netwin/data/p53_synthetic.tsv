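# Synthetic stand-in for a 16-node p53 signaling network.  All weights and
# basal levels are hand-designed, NOT transcribed from any reference model;
# only the structural facts that drive the screening combinatorics are
# preserved: 16 nodes, and the six drug-target nodes AKT, BCL2, CYCE, MDM2,
# WIP1, ATM carrying 27 outgoing links in total (out-degrees 6, 3, 3, 3, 6, 6).
#
# Design: under DNA damage the control network rests in a stable alive
# attractor in which AKT sustains the three p53 guards (MDM2, MDMX, BCL2);
# p53 fires only when all three guards are simultaneously lost, upon which
# p53 -> PTEN silences AKT and the apoptotic state (BAX, CASP3 ON) is
# self-sustaining.
[nodes]
name	basal	role
DNA_damage	0	input
ATM	0	internal
CHK2	0	internal
p53	0	internal
WIP1	0	internal
MDM2	-1	internal
MDMX	1	internal
CYCG	0	internal
PTEN	0	internal
AKT	1	internal
p21	0	internal
CYCE	1	internal
E2F1	0	internal
BCL2	1	internal
BAX	-1	internal
CASP3	-1	output

[links]
source	target	weight
DNA_damage	ATM	2
ATM	CHK2	1
ATM	p53	1
ATM	MDMX	-1
ATM	BCL2	-1
ATM	E2F1	1
ATM	CYCE	-1
CHK2	p53	1
p53	WIP1	1
p53	CYCG	1
p53	PTEN	1
p53	p21	1
p53	BAX	2
WIP1	ATM	-1
WIP1	CHK2	-1
WIP1	MDMX	-1
WIP1	CYCG	-1
WIP1	p21	-1
WIP1	E2F1	-1
MDM2	p53	-2
MDM2	MDMX	1
MDM2	p21	-1
MDMX	p53	-2
CYCG	MDM2	1
PTEN	AKT	-2
AKT	MDM2	2
AKT	MDMX	1
AKT	p21	-1
AKT	CYCE	1
AKT	E2F1	1
AKT	BAX	-1
p21	CYCE	-1
CYCE	E2F1	1
CYCE	p21	-1
CYCE	BCL2	1
E2F1	CYCE	1
BCL2	p53	-2
BCL2	BAX	-2
BCL2	CASP3	-1
BAX	CASP3	2

[metadata]
death_readout	CASP3
version	2
model	synthetic-stand-in
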