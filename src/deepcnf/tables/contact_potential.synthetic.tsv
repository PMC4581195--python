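# SYNTHETIC stand-in table: 40 correlated contact-potential values per amino
# acid. The published table of this kind is not redistributed here; these are
# deterministic standard-normal placeholders (seed 20150729) with the correct
# shape and lookup semantics. Supply your own table via
# AminoAcidTables.from_files to use literature values.
aa	cp1	cp2	cp3	cp4	cp5	cp6	cp7	cp8	cp9	cp10	cp11	cp12	cp13	cp14	cp15	cp16	cp17	cp18	cp19	cp20	cp21	cp22	cp23	cp24	cp25	cp26	cp27	cp28	cp29	cp30	cp31	cp32	cp33	cp34	cp35	cp36	cp37	cp38	cp39	cp40
A	0.3559	0.6560	-2.1295	1.3512	-1.2430	-2.2160	-0.1193	1.7664	-1.0671	1.4300	0.0039	1.4344	-0.6346	-0.6902	-0.8114	-1.5893	0.9845	-1.5132	0.7257	-0.2499	-0.2602	-2.1224	0.6900	1.1689	0.7295	0.0881	0.8138	-0.6567	-0.7999	-1.2084	0.2427	0.3438	0.2219	0.0964	0.6089	1.7545	0.2861	0.1752	-0.3442	0.0112
R	-0.5489	-0.7943	-1.0077	-1.4180	0.3006	-0.4060	2.7386	0.8324	0.7888	1.2030	-1.1034	-0.6043	-0.9730	-0.5575	0.2411	0.2767	1.3172	-0.4567	-0.3020	-0.7275	1.0099	0.8016	-1.8539	-1.7854	-0.6698	-0.0082	-0.8760	-2.0855	-2.9629	-0.2622	-2.1907	-1.0074	-0.0124	-0.7018	0.6314	-0.5929	-0.5191	2.0784	0.1021	-0.5592
N	0.8352	-1.5368	1.5976	-1.1946	2.0272	0.2642	-0.2589	-0.5255	-0.2065	0.8900	0.0620	-0.4483	0.2021	-0.8878	-0.7130	-0.8747	0.3705	0.2719	0.7222	0.4051	0.6665	1.4342	-0.8422	-0.5451	-1.5517	0.5182	-0.0193	-0.3173	0.3455	-0.2725	2.0830	-0.7089	-1.6016	1.0562	-3.7139	0.7052	-1.5403	-0.4013	-0.2611	-0.1990
D	0.8937	-0.3405	-0.9374	0.7922	0.0300	1.2714	0.2729	0.0232	-0.6604	1.2066	-2.0305	-0.2191	-0.6579	0.9750	-0.2818	0.8114	1.0059	0.2241	-0.0818	0.8256	0.8564	0.7659	0.3581	1.1014	0.0659	0.4588	2.4801	0.6205	1.0471	0.5475	-0.4335	-2.6730	0.2235	0.3741	1.0173	0.1806	0.0444	0.8977	1.6507	0.6154
C	0.3439	0.2708	1.4455	0.6920	-1.7887	-0.8028	1.1523	-0.3607	1.4552	-0.2244	0.6583	-1.1428	-0.7214	1.1887	0.9512	-1.2601	0.5116	-0.2494	-0.5050	-0.5975	0.1506	-1.6158	0.1234	2.0840	0.2286	1.1382	0.7042	0.7795	-1.4144	0.4104	-0.6200	-0.9078	0.3704	0.1035	0.8928	0.3187	0.8864	-0.1167	0.5176	-0.4703
Q	-0.3669	-0.0680	-0.1967	1.2069	-1.5487	-0.7075	1.5108	0.9523	0.2415	-1.0221	0.8410	-1.6369	-0.5754	1.3206	-0.5999	1.5154	0.3022	0.9944	-0.1561	-0.5260	1.0195	-0.8793	0.9133	-0.2901	1.4617	0.6156	-0.7141	0.6691	-0.0421	-1.8055	0.7396	2.5470	-0.0785	-1.3757	-0.0418	-0.6802	0.6988	0.9938	0.4054	-1.2867
E	-0.0028	-0.0094	0.0905	0.8337	-0.6348	0.8197	-0.7334	-1.4040	1.2739	-0.4716	-0.4290	-0.7782	-0.6731	-1.3275	-0.6090	-0.8672	-0.8448	0.9057	0.2210	-1.3757	-0.0478	-0.6372	1.1223	-0.6818	0.4897	-0.3365	1.2911	0.2340	0.1928	1.9148	1.3987	-0.2937	0.8022	0.7611	-0.0855	-0.3926	0.1991	-0.7754	0.4404	-0.2835
G	0.2525	-0.7665	-0.7944	0.5183	0.5280	-1.6784	0.0523	0.3221	1.4196	1.2389	1.1051	-0.0649	1.2842	0.9337	0.2793	2.5672	0.3005	-0.7056	-1.3149	-1.8494	0.1807	-0.0243	-0.0554	-0.3339	-0.6161	-0.0798	1.3622	-1.5537	-1.1526	0.2761	-1.9164	-1.0523	1.0768	-1.0368	0.3841	0.1497	0.4997	0.4580	0.1733	1.5732
H	1.7056	0.0434	0.2458	0.1899	-0.9574	-0.7334	-0.5688	-0.5435	0.9307	-0.9612	0.5626	1.1266	0.1142	-0.9891	-0.2359	0.1026	0.7581	-2.3408	0.7934	-0.2869	-1.3720	-0.3740	0.0940	0.6311	0.9171	1.8243	0.2448	-0.6279	-1.2255	1.2804	0.5089	-0.3084	-2.0394	-0.4832	0.0407	1.5005	-0.5494	-1.0150	0.7058	-0.1268
I	0.0613	2.3061	0.3149	-0.9460	0.9969	-2.0239	0.0891	3.5369	-0.4466	-0.5351	0.4551	-0.9691	-0.0540	-0.6117	-0.8177	-1.2762	0.0237	0.4531	-0.9609	-0.6404	-0.2308	-0.3176	-1.5038	-0.0867	0.9396	-0.3706	-1.6255	-0.8672	1.1224	0.2429	-0.9037	-0.0036	-0.4482	-0.8991	-0.9403	1.5107	-0.3360	-0.4797	-1.2815	-0.4268
L	-1.0957	0.9461	-1.2087	-0.5356	-0.5351	-0.1858	1.8809	0.5959	0.4392	1.0730	0.6360	0.7394	0.9537	-0.0917	1.3735	0.3593	-0.7702	-0.2879	-0.2004	1.4948	-0.1593	2.3389	-1.2971	-0.9681	-0.4928	-1.1709	-0.1686	-1.8153	-1.0803	1.1833	1.3015	-0.0832	0.0023	0.5621	0.9112	-1.8816	-1.0713	1.0687	-0.8871	-0.3651
K	-0.3969	-0.5457	1.2444	-1.4196	-0.0916	-1.4016	0.0687	-0.7554	0.3975	0.9044	0.1526	-0.5036	-1.1186	0.0974	0.8760	-0.1524	0.7377	0.3646	-0.9147	-0.2353	0.2202	-2.5815	0.0528	-0.9102	-1.1919	1.2693	-0.1296	0.1715	0.1284	-1.8623	-0.1970	-0.8229	0.4301	-1.1589	1.3008	-0.0702	1.5692	-1.3489	-2.2775	-2.2309
M	-2.0287	-0.3904	-1.7748	0.0961	0.6684	-0.5056	1.0410	0.3924	1.5445	-0.0579	-0.0907	-0.2221	0.5852	1.3951	0.5106	-0.2347	1.2803	0.0263	-0.3808	1.1096	-1.7255	-0.7445	0.2042	-1.0392	-0.4175	3.5842	-0.4839	-0.3149	0.7286	1.9593	0.2190	0.8503	0.4673	0.2515	0.2021	0.2261	1.1003	-1.4375	1.1855	0.6116
F	-1.1199	-0.2582	0.0720	0.5475	0.2118	0.9918	-0.5374	1.1070	-0.0865	1.1892	2.3419	-0.0483	0.0740	0.8195	0.4544	-0.5469	0.3425	1.6320	-2.2893	0.5244	1.0793	0.3276	-3.0571	1.0817	-0.1674	0.8287	1.8586	1.5152	-1.0928	-0.5722	0.3538	-0.2167	-0.7223	-1.8504	0.2589	0.2418	0.1780	0.9071	1.1258	-0.3592
P	0.4624	0.5979	-0.1763	-0.7373	1.4238	0.0747	1.9435	-0.6685	2.1472	-0.0681	2.8744	-1.1032	2.2513	-1.0891	-0.6064	-1.9513	-0.4454	0.1476	-0.2743	-0.6918	0.4684	-2.1479	-0.0566	-0.7990	-0.9714	-0.0054	-1.3696	-0.5307	0.5241	1.8355	-1.1759	-2.2057	-0.0383	0.4220	-0.6239	0.2753	1.0620	1.4557	0.1296	-2.6061
S	-1.4267	-0.7723	0.5880	0.3836	-1.1523	-1.7109	0.5127	0.0096	-1.8998	0.4860	1.7894	-1.2408	-0.0261	-0.7619	0.1418	-0.0872	3.0951	0.3139	-0.4595	0.8769	-0.3929	-0.2652	-1.2624	-0.4556	-1.5331	1.1075	0.4939	1.6310	-0.4809	1.9446	1.5315	-0.6081	-0.1424	0.4440	-0.1761	-1.5610	0.3062	-0.9974	1.3668	-1.0380
T	-0.4033	0.7866	0.1462	0.4110	1.4321	-1.5846	-0.6842	-1.9725	-2.4115	-0.3904	0.9422	0.5638	0.5282	-0.9046	0.2496	0.4905	0.5179	-1.7414	0.7264	-1.0923	-1.0136	-2.0762	0.1530	0.8695	0.9949	1.3121	0.1631	0.5763	-1.3417	-0.1823	0.6340	-0.8760	-0.6525	-0.3741	2.4609	0.0963	0.2812	-1.3683	1.0223	-0.4162
W	1.0811	-0.1982	0.8714	-0.1669	0.5673	2.4775	1.5338	-0.0845	1.3178	-0.2390	0.0655	1.7086	-0.0213	-0.8153	-0.6805	0.8327	-1.2359	-0.5054	0.3520	-1.3205	0.0723	-0.9792	1.0257	-0.3057	-0.4093	1.0852	0.8590	2.0023	0.8238	-0.8146	-1.7806	-0.5646	-0.1650	-0.4342	0.0898	-0.8407	1.3748	0.4417	0.6674	-0.3861
Y	1.0798	-0.3178	0.9888	-0.9783	-0.1645	0.3097	1.6083	0.1340	-0.4640	-1.3538	-0.1193	1.1277	-0.2500	0.3567	-1.0647	0.0013	-0.9587	1.8638	0.0761	1.6446	2.1058	0.4629	-0.2855	-2.5157	-0.6448	0.8589	-2.5550	-0.0946	0.7436	0.9676	0.7284	-1.0927	-0.3404	0.8121	-1.1928	-0.4222	0.0089	-1.1085	-1.8043	-1.9972
V	1.0572	0.1658	-0.5326	0.1690	0.9590	0.1517	-0.6775	-1.2669	0.9112	-0.0348	1.7274	0.3358	-0.6407	-1.7685	1.0763	-0.2422	-1.9539	1.1665	-0.7301	-0.1135	-0.9032	-0.6522	0.2938	0.6970	-0.4292	-0.5319	-1.9814	0.0146	-1.3624	0.7918	0.4305	-0.8669	1.2178	0.5718	-0.7670	0.2713	0.3758	0.3061	1.1736	0.8113
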