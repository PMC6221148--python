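species	site86	site90	site93	type
Trogon_melanurus	F	S	T	UVS
Momotus_momota	F	S	T	UVS
Malacoptila_panamensis	S	S	T	VS
Galbula_ruficauda	C	S	T	VS
Thamnophilus_atrinucha	C	C	T	UVS
Pitangus_sulphuratus	C	S	T	VS
Mionectes_oleagineus	C	S	T	VS
Myiarchus_panamensis	C	S	T	VS
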