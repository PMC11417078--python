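patient_id	timepoint	library_id	replicate	compartment	cfdna_ng
HROC520	t0	HROC520_t0_r1	1	plasma	46.8
HROC520	t0	HROC520_t0_r2	2	plasma	46.8
HROC520	t1	HROC520_t1_r1	1	plasma	41.4
HROC520	t1	HROC520_t1_r2	2	plasma	41.4
HROC520	t0	HROC520_bc	1	buffycoat	
HROC528	t0	HROC528_t0_r1	1	plasma	16.4
HROC528	t0	HROC528_t0_r2	2	plasma	16.4
HROC528	t1	HROC528_t1_r1	1	plasma	53.1
HROC528	t1	HROC528_t1_r2	2	plasma	53.1
HROC528	t0	HROC528_bc	1	buffycoat	
HROC534	t0	HROC534_t0_r1	1	plasma	21.9
HROC534	t0	HROC534_t0_r2	2	plasma	21.9
HROC534	t1	HROC534_t1_r1	1	plasma	35.3
HROC534	t1	HROC534_t1_r2	2	plasma	35.3
HROC534	t0	HROC534_bc	1	buffycoat	
HROC535	t0	HROC535_t0_r1	1	plasma	53.4
HROC535	t0	HROC535_t0_r2	2	plasma	53.4
HROC535	t1	HROC535_t1_r1	1	plasma	32.0
HROC535	t1	HROC535_t1_r2	2	plasma	32.0
HROC535	t0	HROC535_bc	1	buffycoat	
HROC536	t0	HROC536_t0_r1	1	plasma	19.6
HROC536	t0	HROC536_t0_r2	2	plasma	19.6
HROC536	t1	HROC536_t1_r1	1	plasma	53.2
HROC536	t1	HROC536_t1_r2	2	plasma	53.2
HROC536	t0	HROC536_bc	1	buffycoat	
HROC539	t0	HROC539_t0_r1	1	plasma	19.6
HROC539	t0	HROC539_t0_r2	2	plasma	19.6
HROC539	t1	HROC539_t1_r1	1	plasma	49.8
HROC539	t1	HROC539_t1_r2	2	plasma	49.8
HROC539	t0	HROC539_bc	1	buffycoat	
HROC540	t0	HROC540_t0_r1	1	plasma	44.7
HROC540	t0	HROC540_t0_r2	2	plasma	44.7
HROC540	t1	HROC540_t1_r1	1	plasma	69.3
HROC540	t1	HROC540_t1_r2	2	plasma	69.3
HROC540	t0	HROC540_bc	1	buffycoat	
HROC544	t0	HROC544_t0_r1	1	plasma	34.5
HROC544	t0	HROC544_t0_r2	2	plasma	34.5
HROC544	t1	HROC544_t1_r1	1	plasma	366.0
HROC544	t1	HROC544_t1_r2	2	plasma	366.0
HROC544	t0	HROC544_bc	1	buffycoat	
HROC547	t0	HROC547_t0_r1	1	plasma	10.2
HROC547	t0	HROC547_t0_r2	2	plasma	10.2
HROC547	t1	HROC547_t1_r1	1	plasma	43.9
HROC547	t1	HROC547_t1_r2	2	plasma	43.9
HROC547	t0	HROC547_bc	1	buffycoat	
HROC554	t0	HROC554_t0_r1	1	plasma	56.7
HROC554	t0	HROC554_t0_r2	2	plasma	56.7
HROC554	t1	HROC554_t1_r1	1	plasma	21.2
HROC554	t1	HROC554_t1_r2	2	plasma	21.2
HROC554	t0	HROC554_bc	1	buffycoat	
HROC556	t0	HROC556_t0_r1	1	plasma	39.2
HROC556	t0	HROC556_t0_r2	2	plasma	39.2
HROC556	t1	HROC556_t1_r1	1	plasma	58.3
HROC556	t1	HROC556_t1_r2	2	plasma	58.3
HROC556	t0	HROC556_bc	1	buffycoat	
HROC558	t0	HROC558_t0_r1	1	plasma	45.5
HROC558	t0	HROC558_t0_r2	2	plasma	45.5
HROC558	t1	HROC558_t1_r1	1	plasma	48.2
HROC558	t1	HROC558_t1_r2	2	plasma	48.2
HROC558	t0	HROC558_bc	1	buffycoat	
HROC562	t0	HROC562_t0_r1	1	plasma	176.0
HROC562	t0	HROC562_t0_r2	2	plasma	176.0
HROC562	t1	HROC562_t1_r1	1	plasma	137.9
HROC562	t1	HROC562_t1_r2	2	plasma	137.9
HROC562	t0	HROC562_bc	1	buffycoat	
HROC566	t0	HROC566_t0_r1	1	plasma	18.6
HROC566	t0	HROC566_t0_r2	2	plasma	18.6
HROC566	t1	HROC566_t1_r1	1	plasma	5.25
HROC566	t1	HROC566_t1_r2	2	plasma	5.25
HROC566	t0	HROC566_bc	1	buffycoat	
HROC574	t0	HROC574_t0_r1	1	plasma	18.1
HROC574	t0	HROC574_t0_r2	2	plasma	18.1
HROC574	t1	HROC574_t1_r1	1	plasma	21.2
HROC574	t1	HROC574_t1_r2	2	plasma	21.2
HROC574	t0	HROC574_bc	1	buffycoat	
HROC586	t0	HROC586_t0_r1	1	plasma	6.4
HROC586	t0	HROC586_t0_r2	2	plasma	6.4
HROC586	t1	HROC586_t1_r1	1	plasma	19.9
HROC586	t1	HROC586_t1_r2	2	plasma	19.9
HROC586	t0	HROC586_bc	1	buffycoat	
HROC601	t0	HROC601_t0_r1	1	plasma	29.2
HROC601	t0	HROC601_t0_r2	2	plasma	29.2
HROC601	t1	HROC601_t1_r1	1	plasma	39.2
HROC601	t1	HROC601_t1_r2	2	plasma	39.2
HROC601	t0	HROC601_bc	1	buffycoat	
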