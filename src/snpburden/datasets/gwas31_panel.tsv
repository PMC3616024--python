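snp_id	chrom	major	minor	control_maf	published_or	published_p
rs721048	2p15	G	A	0.134	1.03	0.72
rs1465618	2p21	G	A	0.172	1.14	0.13
rs12621278	2q31	A	G	0.047	0.91	0.52
rs2660753	3p12	C	T	0.219	1.15	0.055
rs10934853	3q21	C	A	0.294	0.98	0.80
rs12500426	4q22	A	C	0.465	0.91	0.15
rs17021918	4q22	C	T	0.339	0.91	0.15
rs7679673	4q24	C	A	0.492	0.89	0.057
rs9364554	6q25	C	T	0.172	1.29	0.001
rs10486567	7p15	C	T	0.297	0.93	0.29
rs6465657	7q21	T	C	0.422	1.09	0.17
rs1512268	8p21	G	A	0.437	1.08	0.24
rs10086908	8q24	A	G	0.239	0.95	0.50
rs1447295	8q24	C	A	0.067	1.01	0.92
rs16901979	8q24	G	T	0.031	1.30	0.12
rs620861	8q24	G	A	0.402	0.83	0.005
rs6983267	8q24	T	G	0.477	1.34	5.7e-7
rs10993994	10q11	C	T	0.489	1.22	0.002
rs10896438	11q13	T	G	0.248	1.26	0.001
rs10896449	11q13	G	A	0.346	0.80	0.002
rs12793759	11q13	G	A	0.213	1.17	0.03
rs7127900	11p15	C	T	0.248	1.21	0.008
rs4054823	17p12	A	G	0.465	1.03	0.59
rs4430796	17q12	C	T	0.432	1.25	0.0001
rs11649743	17q21	C	T	0.142	0.87	0.16
rs1859962	17q24	G	T	0.468	0.89	0.05
rs17632542	19q13	T	C	0.079	0.66	0.001
rs2735839	19q13	G	A	0.183	0.85	0.05
rs8102476	19q13	C	T	0.389	0.87	0.03
rs5759167	22q13	A	C	0.498	1.19	0.006
rs5945619	Xp11	A	G	0.240	1.42	0.001
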