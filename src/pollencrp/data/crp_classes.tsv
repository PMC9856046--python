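# Cysteine-spacing patterns of the five pollen-coat CRP families shared by
# Arabidopsis thaliana (At), Arabidopsis lyrata (Al) and Brassica oleracea (Bo).
# Notation: 'C' = conserved cysteine, 'X' = any non-cysteine residue,
# 'X(a-b)' = a..b arbitrary residues, 'X(a)' = exactly a residues.
# size_min/size_max: mature protein length range (residues) observed per row.
class_id	species	subgroups	size_min	size_max	pattern
PCP-A/DEFL/LCR	A.thaliana	CRP0000,CRP0260,CRP0520,CRP0560,CRP0570,CRP0580,CRP0650,CRP0700,CRP0710,CRP0960	76	90	CX(5-12)CX(4-8)CXXXCX(9-16)CX(3-14)CXCX(0-5)C
PCP-A/DEFL/LCR	A.lyrata	CRP0000,CRP0260,CRP0520,CRP0560,CRP0570,CRP0580,CRP0650,CRP0700,CRP0710,CRP0960	53	96	CX(7-16)CX(4-8)CXXXCX(9-16)CX(4-13)CXC(1-8)C
PCP-A/DEFL/LCR	B.oleracea	CRP0000,CRP0260,CRP0520,CRP0560,CRP0570,CRP0580,CRP0650,CRP0700,CRP0710,CRP0960	52	209	CX(3-21)CX(4-11)CXXXCX(9-15)CX(4-12)CXCX(1-6)C
PCP-B	A.thaliana	CRP5460,CRP5500,CRP5515	74	82	CXXXXCX(7-8)CXCCX(6-8)CX(6)CXXXC
PCP-B	A.lyrata	CRP5460,CRP5500,CRP5515	74	77	CXXXXCX(7-8)CXCCX(6-8)CX(6)CXXXC
PCP-B	B.oleracea	CRP5460,CRP5500,CRP5515	66	134	CX(4-10)CX(8)CXCCX(6-9)CX(6)CXXXC
SCRL	A.thaliana	CRP0830	87	98	CX(9)CX(7)CX(13-19)CXCX(11-15)CXCX(3-7)C
SCRL	A.lyrata	CRP0830	79	105	CX(9-10)CX(7-10)CX(13-19)CXCX(10-16)CXCX(3-7)C
SCRL	B.oleracea	CRP0830	73	108	CX(9-10)CX(7-8)CX(13-23)CXCX(11-27)CXCX(3-7)C
nsLTP	A.thaliana	CRP3860,CRP4000,CRP4380,CRP4670,CRP4820,CRP4900	91	180	CX(6-9)CX(13-16)CCX(8-19)CXCX(12-25)CX(6-15)C
nsLTP	A.lyrata	CRP3860,CRP4000,CRP4380,CRP4670,CRP4820,CRP4900	93	119	CX(6-9)CX(12-16)CCX(8-19)CXCX(17-24)CX(6-15)C
nsLTP	B.oleracea	CRP3860,CRP4000,CRP4380,CRP4670,CRP4820,CRP4900	90	265	CX(6-9)CX(13-16)CCX(8-19)CXCX(12-25)CX(6-13)C
GASA	A.thaliana	CRP2700	89	94	CXXXCXXXCX(8)CXXXCXXCCXXCX(1-2)CX(11)CXCX(12)C
GASA	A.lyrata	CRP2700	89	94	CXXXCXXXCX(8)CXXXCXXCCXXCX(1-2)CX(11)CXCX(12)C
GASA	B.oleracea	CRP2700	89	91	CXXXCXXXCX(8)CXXXCXXCCXXCXXCX(11)CXCX(12)C
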