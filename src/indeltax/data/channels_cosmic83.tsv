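# indeltax channel asset cosmic83 version reconstructed-1.0
channel_id	division	motif_class	run_bin	flank5	flank3	L_bin	M_bin	order_index
1:Del:C:0	del1bp	C	0					0
1:Del:C:1	del1bp	C	1					1
1:Del:C:2	del1bp	C	2					2
1:Del:C:3	del1bp	C	3					3
1:Del:C:4	del1bp	C	4					4
1:Del:C:5	del1bp	C	5					5
1:Del:T:0	del1bp	T	0					6
1:Del:T:1	del1bp	T	1					7
1:Del:T:2	del1bp	T	2					8
1:Del:T:3	del1bp	T	3					9
1:Del:T:4	del1bp	T	4					10
1:Del:T:5	del1bp	T	5					11
1:Ins:C:0	ins1bp	C	0					12
1:Ins:C:1	ins1bp	C	1					13
1:Ins:C:2	ins1bp	C	2					14
1:Ins:C:3	ins1bp	C	3					15
1:Ins:C:4	ins1bp	C	4					16
1:Ins:C:5	ins1bp	C	5					17
1:Ins:T:0	ins1bp	T	0					18
1:Ins:T:1	ins1bp	T	1					19
1:Ins:T:2	ins1bp	T	2					20
1:Ins:T:3	ins1bp	T	3					21
1:Ins:T:4	ins1bp	T	4					22
1:Ins:T:5	ins1bp	T	5					23
2:Del:R:0	del_ge2bp		0			2		24
2:Del:R:1	del_ge2bp		1			2		25
2:Del:R:2	del_ge2bp		2			2		26
2:Del:R:3	del_ge2bp		3			2		27
2:Del:R:4	del_ge2bp		4			2		28
2:Del:R:5	del_ge2bp		5			2		29
3:Del:R:0	del_ge2bp		0			3		30
3:Del:R:1	del_ge2bp		1			3		31
3:Del:R:2	del_ge2bp		2			3		32
3:Del:R:3	del_ge2bp		3			3		33
3:Del:R:4	del_ge2bp		4			3		34
3:Del:R:5	del_ge2bp		5			3		35
4:Del:R:0	del_ge2bp		0			4		36
4:Del:R:1	del_ge2bp		1			4		37
4:Del:R:2	del_ge2bp		2			4		38
4:Del:R:3	del_ge2bp		3			4		39
4:Del:R:4	del_ge2bp		4			4		40
4:Del:R:5	del_ge2bp		5			4		41
5:Del:R:0	del_ge2bp		0			5		42
5:Del:R:1	del_ge2bp		1			5		43
5:Del:R:2	del_ge2bp		2			5		44
5:Del:R:3	del_ge2bp		3			5		45
5:Del:R:4	del_ge2bp		4			5		46
5:Del:R:5	del_ge2bp		5			5		47
2:Ins:R:0	ins_ge2bp		0			2		48
2:Ins:R:1	ins_ge2bp		1			2		49
2:Ins:R:2	ins_ge2bp		2			2		50
2:Ins:R:3	ins_ge2bp		3			2		51
2:Ins:R:4	ins_ge2bp		4			2		52
2:Ins:R:5	ins_ge2bp		5			2		53
3:Ins:R:0	ins_ge2bp		0			3		54
3:Ins:R:1	ins_ge2bp		1			3		55
3:Ins:R:2	ins_ge2bp		2			3		56
3:Ins:R:3	ins_ge2bp		3			3		57
3:Ins:R:4	ins_ge2bp		4			3		58
3:Ins:R:5	ins_ge2bp		5			3		59
4:Ins:R:0	ins_ge2bp		0			4		60
4:Ins:R:1	ins_ge2bp		1			4		61
4:Ins:R:2	ins_ge2bp		2			4		62
4:Ins:R:3	ins_ge2bp		3			4		63
4:Ins:R:4	ins_ge2bp		4			4		64
4:Ins:R:5	ins_ge2bp		5			4		65
5:Ins:R:0	ins_ge2bp		0			5		66
5:Ins:R:1	ins_ge2bp		1			5		67
5:Ins:R:2	ins_ge2bp		2			5		68
5:Ins:R:3	ins_ge2bp		3			5		69
5:Ins:R:4	ins_ge2bp		4			5		70
5:Ins:R:5	ins_ge2bp		5			5		71
2:Del:M:1	del_mh					2	1	72
3:Del:M:1	del_mh					3	1	73
3:Del:M:2	del_mh					3	2	74
4:Del:M:1	del_mh					4	1	75
4:Del:M:2	del_mh					4	2	76
4:Del:M:3	del_mh					4	3	77
5:Del:M:1	del_mh					5	1	78
5:Del:M:2	del_mh					5	2	79
5:Del:M:3	del_mh					5	3	80
5:Del:M:4	del_mh					5	4	81
5:Del:M:5	del_mh					5	5	82
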