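name	class_label	blast_hit	blast_identity_pct	evalue_synthetic	precursor	signal_end	strategy	mature	amidated	n_disulfides	ptm	predicted_mh	tpm_male	tpm_female	tpm_control	orbitrap	arrow
U-Euscorpiustoxin-Ei1	neurotoxin	Putative potassium channel toxin (M. gertschi)	63	1e-20	MVKQLVAAFLVIMLISSLVDAKKTFMEKAKSVFSKAGNKIKEIAGKSEYMCPVVSSFCEQHCARQEKSGECDFNKCTCS	21	FULL_CHAIN	KKTFMEKAKSVFSKAGNKIKEIAGKSEYMCPVVSSFCEQHCARQEKSGECDFNKCTCS	False	3	C-C	6478.97	349.45	4136.68	-	D-m,D-f,ND-m,ND-f	↓
U-Euscorpiustoxin-Ei2a	neurotoxin	Putative sodium channel toxin (M. gertschi)	71	1e-20	MNAKLTVLLFLAMVAIASCGWINEKRVQSYIDEKIPNGVMKGAIKAVVHKIAKNEYGCVANIDTVSQCNKHCIAAGSEKGVCHGTKCKCDKELSYRRK	19	C_TERM_BASIC_CLEAVE	GWINEKRVQSYIDEKIPNGVMKGAIKAVVHKIAKNEYGCVANIDTVSQCNKHCIAAGSEKGVCHGTKCKCDKELSY	False	3	C-C	8301.05	2771.21	13995.7	-	D-m,D-f,ND-m,ND-f	↓
U-Euscorpiustoxin-Ei2b	neurotoxin	Antimicrobial peptide (Hadrurus spadix)	66	1e-20	MQIRCSILLLLMISSFCSCGILREKYFHQAVDKVAPMIPLPVVSQVVGNVAKQIVHKFAKNEALCMFNKDVAGMCDKSCKEAGKSNGICHGTKCKCDKPLSYKKK	19	C_TERM_BASIC_CLEAVE	GILREKYFHQAVDKVAPMIPLPVVSQVVGNVAKQIVHKFAKNEALCMFNKDVAGMCDKSCKEAGKSNGICHGTKCKCDKPLSY	False	3	C-C	9056.51	766.38	6848.29	-	D-m,D-f,ND-m,ND-f	↓
U-Euscorpiustoxin-Ei3a	neurotoxin	La1-like protein 15 (Urodacus yaschenkoi)	51	1e-20	MKRLQVAALVCLLLCALFSLSAGAGEICEANGLSIPVGQDKQDPKSCDLYKCIMQNNRLVLDKFSCATLKRKRGCKIVPGDSKAAFPKCCPTSNCRGAQWDQ	23	FULL_CHAIN	AGEICEANGLSIPVGQDKQDPKSCDLYKCIMQNNRLVLDKFSCATLKRKRGCKIVPGDSKAAFPKCCPTSNCRGAQWDQ	False	4	C-C	8637.12	8058.69	29307.7	2.73	D-m,D-f,ND-m,ND-f	↓
U-Euscorpiustoxin-Ei3b	neurotoxin	Putative La1-like peptide (M. gertschi)	68	1e-20	MENALGGVMLGSLLLLSLFSASLAIGEKCETGQHVID/EVGKQVQDSKSCTLYKCINYNRKYALETLTCASQKLKSGCRSIPGAANTPFPNCCPTVICQG	24	FULL_CHAIN_GLY_AMIDE	IGEKCETGQHVID/EVGKQVQDSKSCTLYKCINYNRKYALETLTCASQKLKSGCRSIPGAANTPFPNCCPTVICQ	True	4	A,C-C	7942.79/7956.88	2320.13	18041.9	3.49	D-m,D-f,ND-m,ND-f	↓
Antimicrobial Peptide Ei1	AMP	Putative non-disulfide bridge peptide (M. gertschi)	81	1e-20	MHFNKTLLVIFLSYLLVTDEAEAFWGFLAKLATKVVPSLFGSSSEKSKREIENFFEPYQKDLDLELDRFDRFLSKLDLN	23	N_TERM_REGION	FWGFLAKLATKVVPSLFGSSSEKS	False	0	-	2586.38	2015.04	9050.66	-	D-m,D-f,ND-m,ND-f	↓
Antimicrobial Peptide Ei2a	AMP	Antimicrobial peptide UyCT3 (Urodacus yaschenkoi)	59	1e-20	MKNQFVILIIAVVLLQLFSPSEAILSDIWNGIKGLFGKRGLFPQRPLINRDQFDDVFDDDLSAADLKFLQELLK	23	N_TERM_REGION	ILSDIWNGIKGLF	True	0	A	1474.82	1228.17	11051.7	-	D-m,D-f,ND-m,ND-f	↓
Antimicrobial Peptide Ei2b	AMP	Antimicrobial peptide UyCT3 (Urodacus yaschenkoi)	65	1e-20	MKNQFVILVIAVVLLQLFSPSEAILSDIWNGIKSIFGKRGLRNLDRFDDLFDDDVSDADLKVLQELFR	23	N_TERM_REGION	ILSDIWNGIKSIF	True	0	A	1504.83	637.46	2871.02	-	D-m,ND-m,ND-f	↓
Novel Venom Compound Ei1	novel				MKCYLAVLVLLLVCAVLPDQTCGIENGRKSPNFCRNKCLKEYIPNNCVGYCERVLKEKEK/EKEG	23	N_TERM_QUADRUPLET	KSPNFCRNKCLKEYIPNNCVGYCERVLKEKEK/EKE	True	2	A,C-C	4085.01/4086.00	5.1	3418.27	-	D-f,ND-m,ND-f	↓
U-Euscorpiustoxin-Ei4	neurotoxin	Putative Na+ channel toxin (Superstitionia donensis)	50	1e-20	MKWCTVFMFCLVILVHEFQDVYGEKEGYPLDATRNIYQCYDLGENDYCEKKCKEFGGHGYCYGFACYCKYIRDDVKIWKG	23	FULL_CHAIN_GLY_AMIDE	EKEGYPLDATRNIYQCYDLGENDYCEKKCKEFGGHGYCYGFACYCKYIRDDVKIWK	True	3	A,C-C	6683.95	8482.11	60.96	17.54	D-m,D-f,ND-m,ND-f	↑
Putative Protease Inhibitor Ei1a	protease inhibitor	Chymotrypsin-elastase inhibitor ixodidin-like (Ixodes scapularis)	37	1e-20	MTNLRETVANMKTLAVTLLTLAAFQLVLPYPQPEESSPPENCGENELFYGRRTCAPICNDEVCKKPSREPTACFAICYQGCYCKEGYGRNRRNETCVKCE	29	C_TERM_BASIC_CLEAVE	YPQPEESSPPENCGENELFYGRRTCAPICNDEVCKKPSREPTACFAICYQGCYCKEGY	True	4	A,C-C	6563.75	1712.29	218.501	88.11	D-m	↑
U-Euscorpiustoxin-Ei5	neurotoxin	AKTx (Hadrurus spadix)	35	1e-20	MNLIIIFTLLLSSPFIEVEGSQVNARASCTNSGVCRSSTCPSRGCRSGKCINRKCTCYYC	20	FULL_CHAIN	SQVNARASCTNSGVCRSSTCPSRGCRSGKCINRKCTCYYC	False	4	C-C	4301.78	1812.84	23.48	163.27	D-m,ND-m	↑
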