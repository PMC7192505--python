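	t0	t1	t2	t3	t4	t5	t6	t7	p0	p1	p2	p3	p4	p5	p6
g0	5.3047	3.96	5.7505	5.9406	3.049	3.6978	5.1278	4.6838	4.7805	5.2036	7.0197	5.3229	6.0084	8.189	6.0369
g1	4.9832	4.147	5.8794	5.7778	5.066	6.1272	5.4675	4.1407	7.4588	5.2863	6.2329	5.265	6.0593	7.5924	4.2545
g2	5.3688	4.0411	5.8785	4.9501	4.8151	4.3191	6.2225	4.8455	7.0648	6.8091	5.7276	4.6201	6.5938	5.8117	6.8025
g3	4.5717	4.6479	5.5323	5.3654	5.4127	5.4308	7.1416	4.5936	6.5284	8.5823	6.1888	5.1695	6.7331	6.786	8.2669
g4	4.4878	4.1862	5.616	6.129	4.8861	4.1598	4.1755	5.6506	7.5856	6.9639	8.4023	4.9546	5.6683	5.2955	5.9932
g5	5.7433	5.5432	4.3345	5.2322	5.1167	5.2187	5.8714	5.2236	4.7103	7.3257	6.2111	4.588	5.1797	6.9076	7.5896
g6	5.6789	5.0676	5.2891	5.6313	3.5428	4.6803	4.5296	4.3611	9.0958	10.288	7.0387	5.2136	3.7283	6.848	5.4432
g7	4.7249	6.4949	4.1342	5.9683	3.3171	4.6651	5.1628	5.5862	5.96	5.7043	6.317	7.8858	6.7042	6.2938	5.1537
g8	5.7112	5.7933	4.6513	4.5376	5.858	4.8087	3.7243	3.8667	4.3229	5.8678	6.4301	8.7983	6.6694	7.7776	5.8509
g9	4.0805	5.4972	5.1424	5.6905	4.5727	5.1585	5.6256	4.6907	4.9596	5.2453	5.5572	9.267	5.4322	7.59	5.3262
g10	5.4568	4.3381	4.6369	4.6183	3.8042	5.487	4.5306	5.0125	7.711	7.0004	6.2964	6.447	5.6488	7.0799	5.9085
g11	5.4807	5.4465	5.6654	4.9015	4.5767	4.9203	3.3127	3.5529	4.9067	4.8387	6.7244	8.5528	6.708	6.3458	6.8716
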