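# Significantly differentially enriched proteins: plasma-exposed HA-decorated
# (HAS3) vesicles versus plasma-exposed control (MCF7) vesicles, transcribed
# verbatim from the published table.
# adj_p_value is stored exactly as printed; the printed values exceed 1 and are
# consistent with -log10-transformed BH-adjusted p values (the published
# significance line is an adjusted (-log10) p of 1.30). That interpretation is
# documented here, not asserted.
# not_in_nascent marks rows printed in bold: protein not identified in nascent
# vesicles in this study or in the three prior proteome datasets.
label	gene	protein_name	accession	log2fc	adj_p_value	ev_previous	ev_this_study	not_in_nascent
1	TMEM209	Transmembrane protein 209	Q96SK2	-2.977	1.704			+
2	YBX1	Y-box-binding protein 1	P67809	-2.484	1.715	X
3	HNRNPCL4	Heterogeneous nuclear ribonucleoprotein C-like 4	P0DMR1	-1.858	2.09			+
4	NPM1	Nucleophosmin	P06748	-1.866	1.443	X	X
5	H4C1	Histone H4	P62805	-1.523	1.971	X	X
6	DPYSL5	Dihydropyrimidinase-related protein 5	Q9BPU6	-1.438	2.088		X
7	H1-5	Histone H1.5	P16401	-1.456	2.177		X
8	H3C15	Histone H3.2	Q71DI3	-1.455	2.083	X	X
9	H2AX	Histone H2AX	P16104	-1.357	2.166		X
10	GCC2	GRIP and coiled-coil domain-containing protein 2	Q8IWJ2	-1.319	1.564	X
11	RPS6	Small ribosomal subunit protein eS6	P62753	-1.233	1.371	X
12	NCL	Nucleolin	P19338	-0.942	1.719	X	X
13	H1-2	Histone H1.2	P16403	-0.443	1.668		X
14	AGRN	Agrin	O00468	-0.471	1.407	X	X
15	FABP5	Fatty acid-binding protein 5	Q01469	0.494	1.327	X	X
16	IGKC	Immunoglobulin kappa constant	P01834	0.723	1.323	X
17	PTGFRN	Prostaglandin F2 receptor negative regulator	Q9P2B2	0.995	1.435	X
18	FGA	Fibrinogen alpha chain	P02671	1.261	1.402			+
19	IGHG1	Immunoglobulin heavy constant gamma 1	P01857	0.972	1.359		X
20	A1BG	Alpha-1B-glycoprotein	P04217	1.14	1.356			+
21	ITGA2	Integrin alpha-2	P17301	1.205	1.363	X
22	CHMP4A	Charged multivesicular body protein 4a	Q9BY43	0.977	1.338	X
23	IGHA1	Immunoglobulin heavy constant alpha 1	P01876	0.87	1.33	X
24	IGHG4	Immunoglobulin heavy constant gamma 4	P01861	1.113	1.336		X
25	ITIH4	Inter-alpha-trypsin inhibitor heavy chain H4	Q14624	0.894	1.332	X
26	AHSG	Alpha-2-HS-glycoprotein	P02765	0.729	1.604			+
27	SERPINA3	Alpha-1-antichymotrypsin	P01011	1.457	1.342			+
28	C4A	Complement C4-A	P0C0L4	1.107	1.723			+
29	ATP1A1	Sodium/potassium-transporting ATPase subunit alpha-1	P05023	1.346	1.762	X	X
30	SLC3A2	Amino acid transporter heavy chain SLC3A2	P08195	1.725	1.554	X	X
31	A2M	Alpha-2-macroglobulin	P01023	1.761	1.615	X
32	C3	Complement C3	P01024	1.648	1.734	X
33	SLC1A5	Neutral amino acid transporter B(0)	Q15758	1.705	1.799	X
34	SERPINA1	Alpha-1-antitrypsin	P01009	1.854	1.689			+
35	TF	Serotransferrin	P02787	2.147	1.718			+
36	F5	Coagulation factor V	P12259	1.298	1.939			+
37	RAB10	Ras-related protein Rab-10	P61026	1.548	2.064	X
38	RAP1A	Ras-related protein Rap-1A	P62834	1.99	1.967	X
39	GC	Vitamin D-binding protein	P02774	2.102	1.328			+
40	S100A9	Protein S100-A9	P06702	2.709	1.329	X	X
41	IGHG2	Immunoglobulin heavy constant gamma 2	P01859	0.946	2.28			+
42	S100A16	Protein S100-A16	Q96FQ6	2.861	2.5	X	X
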