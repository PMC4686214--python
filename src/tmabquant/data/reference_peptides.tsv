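gene	sequence	n_term_acetylated	q7q111_mean	q7q111_sd	q111q111_mean	q111q111_sd	epoxomicin_mean	epoxomicin_sd	bortezomib_mean	bortezomib_sd	capped_low
Cox5a	GISTPEELGLDKV	False	0.43	0.18	0.47	0.10	0.20	0.01	0.28	0.01	epoxomicin
Eif5a	SAMTEEAAVAIKAMAK	False	0.37	0.14	0.44	0.22	0.36	0.06	0.35	0.03
Erh	SHTILLVQPTKRPEGRTY	True	0.40	0.07	0.44	0.14	0.68	0.03	0.78	0.06
Hspe1	AAETVTKGGIMLPEKSQGKVLQA	False	0.34	0.13	0.31	0.10	0.20	0.01	0.31	0.05	epoxomicin
Hspe1	TVVAVGSGGKGKSGEIEPVSV	False	0.42	0.18	0.41	0.28	0.35	0.06	1.59	0.49
Lgals1	DLTIKLPDGHEF	False	0.28	0.10	0.37	0.19	0.20	0.01	0.22	0.02	epoxomicin
Lgals1	DLTIKLPDGHEFKF	False	0.24	0.03	0.34	0.21	0.28	0.10	0.20	0.01	bortezomib
Lgals1	NTKEDGTWGTEHREPAFPFQPGSITEV	False	0.33	0.19	0.42	0.19	0.34	0.17	0.56	0.11
Lgals1	PDGHEFKFPNRL	False	0.24	0.06	0.28	0.10	0.27	0.05	0.79	0.08
Lgals1	RGEVASDAKSFVLNL	False	0.28	0.08	0.35	0.17	0.26	0.04	0.23	0.01
Lgals1	RGEVASDAKSFVLNLGKDSNNL	False	0.26	0.01	0.26	0.07	0.42	0.19	0.34	0.06
Lgals1	SDAKSFVLNL	False	0.28	0.07	0.26	0.07	0.20	0.01	0.20	0.01	epoxomicin;bortezomib
Lgals1	SDAKSFVLNLGKDSNNL	False	0.26	0.04	0.29	0.11	0.27	0.05	0.25	0.04
Lgals1	TKEDGTWGTEHREPAFPFQPGSITEV	False	0.35	0.19	0.47	0.25	0.38	0.15	0.50	0.02
Lgals1	VASDAKSFVLNL	False	0.25	0.10	0.25	0.10	0.55	0.22	0.27	0.02
Lgals1	VASDAKSFVLNLGKDSNNL	False	0.24	0.04	0.27	0.09	0.95	0.43	0.42	0.14
Mif	AQATGKPAQYIAVHVVPDQL	False	0.26	0.06	0.38	0.18	0.26	0.08	0.29	0.05
Mif	AQATGKPAQYIAVHVVPDQLMTF	False	0.41	0.16	0.47	0.21	0.35	0.07	0.33	0.04
Ppia	ADKVPKTAENFRAL	False	0.34	0.05	0.53	0.16	0.23	0.04	0.63	0.11
Ppia	EDENFILKHTGPGILSM	False	0.42	0.09	0.60	0.21	0.28	0.10	0.23	0.01
Ppia	ELFADKVPKTAENFRAL	False	0.37	0.05	0.48	0.14	0.38	0.10	0.70	0.01
Ppia	KTEWLDGKHVVF	False	0.34	0.09	0.60	0.23	0.22	0.03	0.37	0.04
Rps21	AKADGIVSKNF	False	0.41	0.04	0.40	0.11	0.24	0.04	0.31	0.04
Rps28	MDTSRVQPIKL	True	0.44	0.08	0.44	0.10	0.21	0.02	0.35	0.03
Rps28	VKGPVREGDVLTLLESEREARRLR	False	0.50	0.09	0.52	0.19	0.34	0.17	0.25	0.06
Tmsb10	ADKPDMGEIASFDKAKLKKTETQEKNTLPTKETIEQEKRSEIS	True	0.51	0.07	0.87	0.12	1.20	0.42	1.68	0.52
Vim	LIKTVETRDGQVINETSQ	False	0.51	0.08	0.26	0.07	0.70	0.48	1.07	0.05
Vim	LLIKTVETRDGQVINETSQHHDDLE	False	0.40	0.10	0.35	0.14	1.39	0.14	0.42	0.08
Vim	NDRFANYIDKV	False	0.33	0.08	0.27	0.08	0.26	0.07	0.42	0.01
Vim	RKLLEGEESRISLPLPTFSSL	False	0.49	0.12	0.34	0.09	0.38	0.22	0.25	0.01
Vim	RTLLIKTVETRDGQVINETSQ	False	0.46	0.17	0.33	0.18	0.68	0.51	0.91	0.11
Vim	TLLIKTVETRDGQVINETSQHHDDLE	False	0.52	0.16	0.43	0.20	0.69	0.39	0.35	0.04
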