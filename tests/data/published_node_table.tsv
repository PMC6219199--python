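node	age	age_ci_lower	age_ci_upper	support	I	II	III	IV	lineage_diversity
1	2.73	1.73	3.92	1.00	0.259	0.0229	0	0.718	5.84
2	1.47	0.889	2.15	0.98	0.00110	0.00110	0	0.998	13.2
3	1.32	0.692	2.06	1.00	0.970	0	0	0.0302	19.8
4	2.01	1.13	2.95	1.00	0.931	0.000100	0	0.0680	16.5
5	1.25	0.623	2.00	0.99	0.869	0.000300	0.000200	0.130	20.4
6	0.639	0.200	1.13	1.00	0.891	0	0	0.109	32.3
7	1.21	0.398	2.23	0.99	0.0448	0.00680	0	0.949	17.5
8	0.500	0.195	0.857	0.99	0.0186	0.000100	0	0.981	58.0
9	1.06	0.435	1.81	1.00	0.687	0.00100	0	0.312	22.6
10	1.13	0.561	1.79	1.00	0.0160	0.0447	0	0.939	18.6
11	0.431	0.0971	0.829	1.00	0.0471	0.00140	0	0.952	65.9
12	0.647	0.264	1.12	1.00	0.000300	0.931	0	0.0691	9.63
13	0.786	0.293	1.37	1.00	0.0192	0.00130	0	0.980	34.3
14	2.82	1.60	4.38	1.00	0.622	0.00560	0.000100	0.372	9.12
15	1.68	0.825	2.76	0.99	0.0389	0.131	0.000100	0.830	8.50
16	2.52	1.28	4.10	1.00	0.0777	0.167	0.000300	0.755	4.44
17	0.590	0.0970	1.28	1.00	0.00480	0.316	0	0.680	36.3
18	0.319	0.0443	0.711	1.00	0.0113	0.000400	0	0.988	89.7
19	1.53	0.690	2.60	1.00	0.526	0.00570	0	0.468	15.7
20	0.0977	0.00180	0.272	1.00	0.000800	0.000100	0	0.999	121
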