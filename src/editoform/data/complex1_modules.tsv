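module	accession	expected_mass_kda
N	AT5G37510
N	AT5G08530
N	AT4G02580
N	AT2G20360
Q	AT5G11770
Q	AT1G79010
Q	AT5G67590
Q	ATMG00510
Q	ATMG00070
85kDa	AT1G19580	85
85kDa	AT1G47260	85
85kDa	AT5G66510	85
85kDa	AT5G63510	85
85kDa	AT3G48680	85
200kDa	AT1G19580	200
200kDa	AT1G47260	200
200kDa	AT5G66510	200
200kDa	AT5G63510	200
200kDa	AT3G48680	200
200kDa	ATMG00285	200
200kDa	AT4G16450	200
400kDa	AT1G19580	400
400kDa	AT1G47260	400
400kDa	AT5G66510	400
400kDa	ATMG00285	400
400kDa	AT4G16450	400
400kDa	ATMG00990	400
400kDa	ATMG00650	400
400kDa	ATMG00270	400
400kDa	AT3G47930	400
P_P	AT1G19580	450
P_P	AT1G47260	450
P_P	AT5G66510	450
P_P	ATMG00285	450
P_P	AT4G16450	450
P_P	ATMG00990	450
P_P	ATMG00650	450
P_P	ATMG00270	450
P_P	ATMG00516	450
P_D	ATMG00580
P_D	ATMG00513
P_D	AT2G42210
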