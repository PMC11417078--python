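patient_id	protocol	dworak_trg	downstaging
HROC520	fRCT	4	yes
HROC528	RAPIDO	3	yes
HROC535	RAPIDO	3	yes
HROC539	fRCT	4	yes
HROC540	SCRT	3	yes
HROC547	RAPIDO	4	yes
HROC554	fRCT	4	yes
HROC556	fRCT	3	yes
HROC566	RAPIDO	3	yes
HROC534	fRCT	1	no
HROC536	SCRT	1	yes
HROC544	RAPIDO	1	no
HROC558	SCRT	1	no
HROC562	RAPIDO	1	yes
HROC574	SCRT	1	no
HROC586	SCRT	1	yes
HROC561	SCRT	1	yes
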