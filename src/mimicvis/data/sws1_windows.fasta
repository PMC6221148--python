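>Trogon_melanurus Black-tailed Trogon
FIFCVFSVFTV
>Momotus_momota Blue-crowned Motmot
FIFCSFSVFTV
>Malacoptila_panamensis White-whiskered Puffbird
FISCIFSVFTV
>Galbula_ruficauda Rufous-tailed Jacamar
LMCCIFSVFTV
>Thamnophilus_atrinucha Slaty Antshrike
FMCCIFCIFTV
>Pitangus_sulphuratus Great Kiskadee
FMCCIFSVFTV
>Mionectes_oleagineus Ochre-bellied Flycatcher
FMCCIFSVFTV
>Myiarchus_panamensis Panama Flycatcher
FMCCIFSVFTV
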