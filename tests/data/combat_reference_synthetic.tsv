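	t0	t1	t2	t3	t4	t5	t6	t7	p0	p1	p2	p3	p4	p5	p6
g0	6.079333	4.560183	6.582967	6.797729	3.530998	4.263967	5.879483	5.377883	4.262843	4.598355	6.038496	4.692958	5.23655	6.965734	5.25915
g1	5.493572	4.471454	6.58903	6.464841	5.594782	6.891925	6.08555	4.463754	6.533663	4.841911	5.57904	4.825324	5.443855	6.637699	4.038436
g2	5.938312	4.428188	6.518044	5.462083	5.308534	4.744385	6.909309	5.343111	6.28265	6.080118	5.223499	4.346285	5.909586	5.290111	6.074891
g3	5.106828	5.197621	6.25139	6.052528	6.108886	6.130452	8.168884	5.132922	5.820175	7.432344	5.553613	4.753533	5.98085	6.022373	7.184777
g4	5.073032	4.700475	6.46666	7.100352	5.565039	4.667864	4.687258	6.5094	6.541829	6.056751	7.179054	4.489007	5.045867	4.754992	5.299368
g5	6.434158	6.160046	4.504277	5.734014	5.575794	5.715521	6.609639	5.722233	4.461895	6.465614	5.611693	4.368199	4.821514	6.145298	6.667794
g6	7.042988	6.1756	6.489892	6.975447	4.012027	5.626052	5.41222	5.173132	7.415621	8.327426	5.842334	4.446482	3.310512	5.696485	4.622082
g7	5.321709	7.187931	4.698897	6.632703	3.837378	5.258658	5.783414	6.229831	5.326307	5.120368	5.613833	6.877334	5.925681	5.595147	4.676918
g8	6.685703	6.788455	5.359187	5.216886	6.86943	5.556181	4.199002	4.377223	3.937891	5.140735	5.578536	7.422393	5.764853	6.627686	5.127577
g9	4.385111	6.353317	5.860397	6.621867	5.068919	5.882765	6.531702	5.232855	4.495484	4.714238	4.953053	7.793562	4.857343	6.509521	4.776181
g10	6.103659	4.870001	5.199506	5.178995	4.281238	6.136962	5.082283	5.613703	6.755352	6.204299	5.658364	5.775151	5.156166	6.265949	5.357557
g11	6.361747	6.32074	6.583208	5.667266	5.27782	5.689808	3.762241	4.050249	4.387502	4.334191	5.812538	7.245964	5.799681	5.515724	5.92794
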