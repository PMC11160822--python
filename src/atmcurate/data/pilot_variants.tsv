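variant_type	variant_id	clinvar_id	clinvar_classification	expected_classification	applied_codes
frameshift indel	NM_000051.4(ATM):c.1122_1123del (p.Glu376IlefsTer2)	818362	P/LP	Pathogenic	PM2_supporting;PVS1;PM3;PM5_supporting
frameshift indel	NM_000051.4(ATM):c.3245_3247delinsTGAT (p.His1082LeufsTer14)	3033	P/LP	Pathogenic	PVS1;PM2_supporting;PM3_very-strong;PM5_supporting
frameshift indel	NM_000051.4(ATM):c.6997dup	140818	P/LP	Pathogenic	PM2_supporting;PVS1;PM3_strong;PM5_supporting
gross del	NC_000011.10:g.(?_108287594)_(108287721_?)del	453341	P	Pathogenic	PVS1;PM2_supporting;PM5_supporting
gross dup	NC_000011.9:g.(?_108137888)_(108225611_?)dup	583716	P	Likely pathogenic	PVS1_strong;PM3;PM2_supporting
in frame indel	NM_000051.4(ATM):c.8578_8580delTCT (p.Ser2860del)	3018	VUS	Pathogenic	PM3_very-strong;PM2_supporting;PP3
in frame indel	NM_000051.4(ATM):c.1905_1910del (p.His635_His636del)	141289	VUS	Uncertain significance	PM2_supporting;PP3
missense	NM_000051.4(ATM):c.2614C>T (p.Pro872Ser)	133610	B/LB	Benign	BA1;BP2_strong;BP4
missense	NM_000051.4(ATM):c.3118A>G (p.Met1040Val)	3027	B/LB	Benign	BA1;BP2_strong;BP4
missense	NM_000051.4(ATM):c.6995T>C (p.Leu2332Pro)	133631	B/LB	Benign	BA1;BP4;BP2_strong
missense	NM_000051.4(ATM):c.146C>G (p.Ser49Cys)	3048	B/LB	Benign	BA1;BP2_strong
missense (indel)	NM_000051.4(ATM):c.5556_5557delinsGA (p.Asp1853Asn)	929198	B/LB	Uncertain significance	PM2_supporting;PP3
missense	NM_000051.4(ATM):c.1073A>G (p.Asn358Ser)	127329	Conflicting B/LB/VUS	Benign	BS1;BP2_strong;BP4
missense	NM_000051.4(ATM):c.3925G>A (p.Ala1309Thr)	127377	Conflicting B/LB/VUS	Benign	BS1;BP2_strong;BP4
missense	NM_000051.4(ATM):c.3284G>A (p.Arg1095Lys)	141522	Conflicting LP/VUS	Uncertain significance	PM2_supporting;PVS1_strong
missense	NM_000051.4(ATM):c.7919C>G (p.Thr2640Ser)	231842	LB	Uncertain significance	PM2_supporting
missense	NM_000051.3(ATM):c.8546G>C (p.Arg2849Pro)	490737	LP	Likely pathogenic	PS3_moderate;PM2_supporting;PP3;PM3
missense	NM_000051.4(ATM):c.7271T>G (p.Val2424Gly)	3023	P/LP	Pathogenic	PS3_moderate;PS4;PM3_very-strong;PP3;PP1
missense	NM_000051.4(ATM):c.3137T>C (p.Leu1046Pro)	186558	VUS	Likely pathogenic	PM2_supporting;PP3;PM3_strong;PP4
missense	NM_000051.3(ATM):c.8734A>G (p.Arg2912Gly)	133641	VUS	Uncertain significance	PP3;BP2_strong
nonsense (C-term)	NM_000051.4(ATM):c.9139C>T (p.Arg3047Ter)	3029	P	Pathogenic	PS3_supporting;PM3_very-strong;PVS1
nonsense (mid)	NM_000051.4(ATM):c.1442T>G (p.Leu481Ter)	453367	P/LP	Pathogenic	PM2_supporting;PM3_strong;PVS1;PM5_supporting
splice	NM_000051.4(ATM):c.2639-17G>T	140763	B	Benign	BA1;BP4;BP2_strong
splice	NM_000051.4(ATM):c.1066-6T>G	3038	Conflicting B/LB/VUS	Benign	BS1;BP2_strong
splice	NM_000051.4(ATM):c.8268+1G>A	420799	Conflicting LP/VUS	Likely pathogenic	PVS1;PM2_supporting
splice	NM_000051.4(ATM):c.332-1G>A	231535	LP	Pathogenic	PM3_strong;PM2_supporting;PVS1_strong
splice	NM_000051.4(ATM):c.1607+1G>T	220555	P/LP	Pathogenic	PM3_very-strong;PVS1_strong;PM2_supporting
splice	NM_000051.4(ATM):c.8585-2A>C	407718	P/LP	Pathogenic	PVS1;PM2_supporting;PM3_strong
splice	NM_000051.4(ATM):c.331+7G>A	453461	LB	Uncertain significance	BP4
start loss	NM_000051.4(ATM):c.2T>C (p.Met1?)	187275	P/LP	Pathogenic	PVS1;PM2_supporting;PM3_very-strong;PP4
synonymous	NM_000051.4(ATM):c.1176C>G (p.Gly392=)	142140	B	Benign	BP2_strong;BA1;BP4;BP7
synonymous	NM_000051.4(ATM):c.5544T>C (p.Asp1848=)	184944	LB	Likely benign	BP4;BP7
synonymous	NM_000051.4(ATM):c.8751C>T (p.Gly2917=)	453745	VUS	Likely benign	BP4;BP7;PM2_supporting
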