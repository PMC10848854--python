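Gene	Strand	Location	Size (bp)	Start Codon	Stop codon	Intergenic nucleotides
Cox1	H	1-1986	1986	ATG	TAA	1936
tRNA-Met1	H	3923-3989	67			842
tRNA-Lys	H	4832-4898	67			45
tRNA-Gln	H	4944-5006	63			0
rrnL	H	5007-6335	1329			212
rrnS	H	6548-7491	944			74
tRNA-Ile	H	7566-7632	67			97
tRNA-Ser1	H	7730-7799	70			105
Nad1	H	7905-8978	1074	ATG	TAG	185
tRNA-Ala	H	9164-9230	67			220
tRNA-Met2	H	9451-9539	89			54
tRNA-Met3	H	9594-9682	89			203
tRNA-Tyr	H	9886-9948	63			37
tRNA-Glu	H	9986-10051	66			9
tRNA-Phe	H	10061-10125	65			16
rrnL	H	10142-11507	1366			192
rrnS	H	11700-12643	944			164
tRNA-Thr	H	12808-12870	63			179
tRNA-Pro	H	13050-13115	66			91
tRNA-Leu1	H	13207-13269	63			537
tRNA-Asp	H	13807-13874	68			1112
tRNA-Leu2	H	14987-15049	63			3901
Nad3	H	18951-19290	340	ATT	T	444
tRNA-Asn	H	19735-19801	67			2
tRNA-Gly	H	19804-19869	66			7
tRNA-Ser2	H	19877-19946	70			25
tRNA-Trp1	H	19972-20039	68			13
tRNA-Leu3	H	20053-20115	63			29
tRNA-Val	H	20145-20211	67			30
tRNA-His	H	20242-20305	64			27
Cox2	H	20333-21028	696	ATG	TAG	125
Cytb	H	21154-22785	1632	ATA	TAG	78
Nad2	H	22864-23883	1020	ATT	TAA	14
tRNA-Trp2	H	23898-23965	68			6
Nad5	H	23972-25828	1857	TTG	TAG	96
Nad6	H	25925-26527	603	ATG	TAG	30
tRNA-Cys	H	26558-26620	63			1
Nad4	H	26622-27965	1344	ATG	TAG	74
Atp6	H	28040-28786	747	ATG	TAG
Nad4L	H	28855-29145	291	TTG	TAG	35
tRNA-Arg	H	29181-29243	63			209
Cox3	H	29453-30331	879	TTT	TAA	54
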