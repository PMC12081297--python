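# indeltax channel asset ind89 version reconstructed-1.0
channel_id	division	motif_class	run_bin	flank5	flank3	L_bin	M_bin	order_index
ins1:C:r0:3A	ins1bp	C	0		A			0
ins1:C:r0:3G	ins1bp	C	0		G			1
ins1:C:r0:3T	ins1bp	C	0		T			2
ins1:C:r1:5A	ins1bp	C	1	A				3
ins1:C:r1:5G	ins1bp	C	1	G				4
ins1:C:r1:5T	ins1bp	C	1	T				5
ins1:C:r2	ins1bp	C	2					6
ins1:C:r3	ins1bp	C	3					7
ins1:C:r4	ins1bp	C	4					8
ins1:C:r5	ins1bp	C	5					9
ins1:C:r6	ins1bp	C	6					10
ins1:C:r7	ins1bp	C	7					11
ins1:C:r8	ins1bp	C	8					12
ins1:C:r9+	ins1bp	C	9+					13
ins1:T:r0:3A	ins1bp	T	0		A			14
ins1:T:r0:3C	ins1bp	T	0		C			15
ins1:T:r0:3G	ins1bp	T	0		G			16
ins1:T:r1:5A	ins1bp	T	1	A				17
ins1:T:r1:5C	ins1bp	T	1	C				18
ins1:T:r1:5G	ins1bp	T	1	G				19
ins1:T:r2	ins1bp	T	2					20
ins1:T:r3	ins1bp	T	3					21
ins1:T:r4	ins1bp	T	4					22
ins1:T:r5	ins1bp	T	5					23
ins1:T:r6	ins1bp	T	6					24
ins1:T:r7	ins1bp	T	7					25
ins1:T:r8	ins1bp	T	8					26
ins1:T:r9+	ins1bp	T	9+					27
del1:C:r1:5A	del1bp	C	1	A				28
del1:C:r1:5G	del1bp	C	1	G				29
del1:C:r1:5T	del1bp	C	1	T				30
del1:C:r2	del1bp	C	2					31
del1:C:r3	del1bp	C	3					32
del1:C:r4	del1bp	C	4					33
del1:C:r5	del1bp	C	5					34
del1:C:r6	del1bp	C	6					35
del1:C:r7	del1bp	C	7					36
del1:C:r8	del1bp	C	8					37
del1:C:r9+	del1bp	C	9+					38
del1:T:r1:5A	del1bp	T	1	A				39
del1:T:r1:5C	del1bp	T	1	C				40
del1:T:r1:5G	del1bp	T	1	G				41
del1:T:r2	del1bp	T	2					42
del1:T:r3	del1bp	T	3					43
del1:T:r4	del1bp	T	4					44
del1:T:r5	del1bp	T	5					45
del1:T:r6	del1bp	T	6					46
del1:T:r7	del1bp	T	7					47
del1:T:r8	del1bp	T	8					48
del1:T:r9+	del1bp	T	9+					49
ins:u1:c2	ins_ge2bp	u1	2					50
ins:u1:c3	ins_ge2bp	u1	3					51
ins:u1:c4+	ins_ge2bp	u1	4+					52
ins:u2:c2	ins_ge2bp	u2	2					53
ins:u2:c3	ins_ge2bp	u2	3					54
ins:u2:c4+	ins_ge2bp	u2	4+					55
ins:u3+:c2	ins_ge2bp	u3+	2					56
ins:u3+:c3	ins_ge2bp	u3+	3					57
ins:u3+:c4+	ins_ge2bp	u3+	4+					58
ins:nr:L2	ins_ge2bp	nr				2		59
ins:nr:L3	ins_ge2bp	nr				3		60
ins:nr:L4	ins_ge2bp	nr				4		61
ins:nr:L5	ins_ge2bp	nr				5		62
ins:nr:L6+	ins_ge2bp	nr				6+		63
del:u1:c2	del_ge2bp	u1	2					64
del:u1:c3	del_ge2bp	u1	3					65
del:u1:c4+	del_ge2bp	u1	4+					66
del:u2:c2	del_ge2bp	u2	2					67
del:u2:c3	del_ge2bp	u2	3					68
del:u2:c4+	del_ge2bp	u2	4+					69
del:u3+:c2	del_ge2bp	u3+	2					70
del:u3+:c3	del_ge2bp	u3+	3					71
del:u3+:c4+	del_ge2bp	u3+	4+					72
del:nr:L2	del_ge2bp	nr				2		73
del:nr:L3	del_ge2bp	nr				3		74
del:nr:L4	del_ge2bp	nr				4		75
del:nr:L5	del_ge2bp	nr				5		76
del:nr:L6+	del_ge2bp	nr				6+		77
mh:L2:M1	del_mh					2	1	78
mh:L3:M1	del_mh					3	1	79
mh:L3:M2	del_mh					3	2	80
mh:L4:M1	del_mh					4	1	81
mh:L4:M2	del_mh					4	2	82
mh:L4:M3	del_mh					4	3	83
mh:L5+:M1	del_mh					5+	1	84
mh:L5+:M2	del_mh					5+	2	85
mh:L5+:M3	del_mh					5+	3	86
mh:L5+:M4+	del_mh					5+	4+	87
complex	complex							88
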