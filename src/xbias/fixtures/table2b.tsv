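probe_id	chrom	start	stop	Ki	Li	Lu	St	Ey	Hi	gene_symbol	entry	cluster
1422827_x_at	X	7461369	7471588	1.08*	ns	ns	1.11*	ns	ns	Slc35a2	1
1432533_a_at	X	7462961	7471586	1.10**	1.10*	ns	ns	ns	ns	Slc35a2	1
1436664_a_at	X	7470132	7471590	1.10**	1.10**	ns	ns	ns	ns	Slc35a2	1
1425490_a_at	X	7700426	7709678	1.04*	1.11**	ns	ns	ns	ns	Wdr13	2
1422660_at	X	7719484	7722860	ns	ns	ns	ns	1.08*	1.18**	Rbm3	3
1457519_at	X	7729990	7730655	1.08**	1.09**	ns	ns	ns	ns	Tbc1d25	4
1438753_at	X	7779325	7780137	1.07**	1.10*	ns	ns	ns	ns	--- (Porcn intron)	i
1451939_a_at	X	9616032	9694713	ns	ns	1.11*	ns	1.15*	ns	Srpx	5
1450039_at	X	12648662	12749154	1.22**	1.18**	ns	ns	ns	ns	Usp9x	6
1431955_at	X	20783706	20798793	1.05**	ns	ns	1.07*	ns	ns	4930453H23Rik	7
1422241_a_at	X	34727595	34731158	1.08**	1.11*	ns	ns	ns	ns	Ndufa1	8
1416344_at	X	35758238	35809556	1.24**	ns	1.03*	1.14*	ns	ns	Lamp2	9
1439298_at	X	39437302	39438087	1.09**	1.14*	ns	ns	ns	ns	--- (Xiap intron)	i
1449825_at	X	43682183	43683528	1.05*	1.08**	ns	ns	ns	ns	Actrt1	10
1433652_at	X	47135712	47137009	ns	1.09**	ns	1.55**	ns	ns	Igsf1	11
1442549_at	X	48470442	48471160	ns	1.10*	1.19*	ns	ns	ns	Mbnl3	12
1453453_at	X	49321871	49325949	1.03*	1.08**	ns	ns	ns	ns	1700080O16Rik	13
1443620_at	X	49403554	49404019	1.21*	ns	1.14*	ns	ns	ns	Gpc4	14
1448736_a_at	X	50341268	50374837	1.17**	1.32**	ns	ns	ns	ns	Hprt	15
1435815_at	X	58963393	58964128	ns	1.16**	ns	ns	ns	1.10**	Ldoc1	16
1434739_at	X	66015028	66057768	1.07**	1.21**	ns	ns	ns	ns	Fmr1nb	17
1458014_at	X	67115572	67116574	ns	1.06*	ns	1.05*	ns	ns	Aff2	18
1421536_at	X	70070608	70083883	1.03*	1.05*	ns	ns	ns	ns	Gabrq	19
1417412_at	X	70473356	70475147	1.06**	ns	ns	1.10*	ns	ns	F8a	20
1422711_a_at	X	70901332	70905177	ns	1.14**	ns	1.19*	ns	ns	Pnck	21
1451049_at	X	70931516	70961761	1.13**	ns	ns	1.13*	ns	ns	Bcap31	22
1438120_x_at	X	71260144	71260313	1.19**	1.11**	ns	ns	ns	ns	Irak1	23
1450161_at	X	71669950	71694950	1.07**	1.11*	ns	ns	ns	ns	Ikbkg	24
1437553_at	X	72698339	72699357	1.06**	1.07*	ns	ns	ns	ns	Brcc3	25
1429793_at	X	82514833	82515627	1.06*	1.09*	ns	ns	ns	ns	1600014K23Rik	26
1458481_at	X	98456711	98459331	1.04*	1.10*	ns	ns	ns	ns	Il2rg	27
1447725_at	X	100211276	100211547	1.06*	1.11**	ns	ns	ns	ns	C030034E14Rik	28
1437355_at	X	104032421	104033595	1.04*	1.08**	ns	ns	ns	ns	Zcchc5	29
1422164_at	X	108009755	108012520	1.06*	1.17**	ns	ns	ns	ns	Pou3f4	30
1444668_at	X	120324027	120326909	1.13**	1.25**	1.15**	ns	ns	ns	Astx	31
1417979_at	X	130385542	130400116	1.03*	ns	ns	ns	1.17**	ns	Tnmd	32
1425954_a_at	X	147018680	147022624	1.05*	1.14**	ns	ns	ns	ns	Apex2	33
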