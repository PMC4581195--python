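# SYNTHETIC stand-in table: 11 per-residue propensities of being an endpoint
# of a secondary-structure segment. The published table of this kind is not
# redistributed here; these are deterministic standard-normal placeholders
# (seed 20150729) with the correct shape and lookup semantics. Supply your
# own table via AminoAcidTables.from_files to use literature values.
aa	ep1	ep2	ep3	ep4	ep5	ep6	ep7	ep8	ep9	ep10	ep11
A	1.2073	1.5191	-0.5854	-0.6835	-0.3317	-0.4966	-1.2947	-0.0088	-0.3631	1.0059	-0.7505
R	1.3634	-1.1392	-0.2804	-0.1054	1.7645	-1.0005	-1.3500	-0.1620	-0.4145	1.1593	-1.2424
N	1.7439	0.2151	1.2788	-0.6536	1.5258	-1.2472	0.2935	-0.6169	-0.4399	-0.0513	0.9891
D	0.6582	-0.0091	0.7601	-1.1504	0.0857	-1.7792	-1.1000	0.6307	-1.5570	1.2338	0.0343
C	1.3368	-1.2744	-0.5173	0.2277	2.4587	1.0972	-0.6397	-0.0389	0.8466	0.2439	1.3186
Q	1.2218	-0.1651	-1.4338	0.4847	-1.5943	1.0144	-0.1098	0.5144	-0.4667	-0.1930	-0.5572
E	0.8610	0.2607	1.0928	0.7226	-2.0846	-1.6376	-0.8142	1.3596	1.2001	-0.4639	-1.3166
G	-0.6404	1.6882	-0.8161	0.6437	0.8363	0.1965	-1.2237	-1.0158	0.8555	0.7152	-0.4857
H	0.0517	-0.4602	-0.1277	-1.0569	-0.7051	0.0025	0.0542	-0.0797	0.6264	-1.8603	-0.1835
I	1.2119	-0.8247	-0.1991	0.3195	-0.4455	-2.6322	-1.5291	-1.5428	0.4980	0.2683	0.9564
L	-0.0817	0.4124	1.4312	-0.0913	-1.6239	-1.3640	-0.2463	-1.0486	1.3575	0.2797	-0.9815
K	-0.0234	1.0692	0.3331	-2.2290	1.0341	-1.0229	0.3359	-0.6797	0.6449	2.7213	2.0442
M	-0.8741	-0.2159	1.1974	-0.1987	1.3702	0.5262	1.7119	2.1004	-1.1207	0.4036	-0.0301
F	-0.8986	1.1210	-0.6629	0.9661	0.0598	-0.2654	1.0773	0.2111	-0.3379	-1.5514	-2.1993
P	0.6882	0.2662	-0.7021	0.7941	-0.7496	0.7773	-0.9915	0.0557	-0.9882	0.6149	-0.0724
S	0.7826	-2.0008	-0.5645	1.0643	-1.8173	-0.5356	1.5766	-1.4246	0.2926	1.0081	-0.0461
T	1.1619	0.5341	1.4532	1.1543	-1.1476	0.6563	-1.5806	-1.5325	-1.0526	-1.5825	-1.9329
W	1.0142	1.3047	0.2363	-0.0337	-0.1572	1.4921	-0.1759	-1.4270	1.5722	0.4922	1.7073
Y	0.2443	-0.1270	1.1038	0.5424	-0.2593	-1.8552	-0.1933	-1.1082	-0.0676	0.0870	-0.2538
V	1.8653	-1.2382	0.6910	0.2143	0.2399	-0.2206	-0.2466	1.1174	-0.0116	0.0917	0.4226
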