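strain_id,isolation_source,fgi_type,genome_gc_pct,island_gc_pct,gc_deviation_pct,size_kb,n_cds
G. thermodenitrificans DSM465^T,Sugar beet juice,-,49.05,45.08,-3.97,0.9,0
G. thermodenitrificans G11MC16,Grass compost,-,48.80,45.77,-3.03,1.0,0
G. thermodenitrificans NG80-2,Formation water of oil well,-,49.01,46.30,-2.71,1.3,0
Geobacillus sp. C56-T3,Hot Spring,-,52.49,43.24,-9.25,1.6,1
G. caldoxylosilyticus CIC9,Hot Spring,-,44.17,39.14,-5.03,2.0,2
Geobacillus sp. NUB3621,Soil,-,44.38,42.37,-2.01,2.0,1
Geobacillus sp. JF8,Bark compost,-,52.87,46.52,-6.35,2.1,1
Geobacillus sp. FW23,Formation water of oil well,-,52.24,49.36,-2.88,3.1,2
G. thermoleovorans B23,Production water subterranean oil reservoir,-,52.29,49.36,-2.93,3.1,2
G. kaustophilus Blys,Hot Spring,-,52.05,49.35,-2.70,3.1,2
G. thermoleovorans CCB_US3_UF5,Hot Spring,-,52.28,49.36,-2.92,3.1,2
Geobacillus sp. CAMR5420,CAMR thermophile culture collection,-,51.89,39.70,-12.19,4.5,5
Geobacillus sp. A8,Deep mine water,-,52.41,46.24,-6.17,5.1,3
G. stearothermophilus ATCC7953,Underprocessed canned food,-,52.39,41.28,-11.11,5.3,4
G. toebii WCH70,Compost,-,42.84,40.76,-2.08,5.6,6
G. caldoxylosilyticus DSM 12041^T,Soil,-,43.92,40.33,-3.59,5.9,5
G. stearothermophilus 22,Hot Spring,-,52.62,45.46,-7.16,6.9,6
G. stearothermophilus 53,Hot Spring,-,52.56,45.46,-7.10,6.9,6
G. kaustophilus DSM 7263^T,Pasteurized milk,I,51.99,36.60,-15.39,14.5,13
G. thermoglucosidans C56-YS93,Hot Spring,I,43.95,34.60,-9.35,15.7,15
G. kaustophilus HTA426,Deep sea sediment,I,52.09,38.35,-13.74,16.5,14
G. thermoglucosidans TNO09.20,Dairy factory biofilm,II,43.82,35.00,-8.82,20.6,18
G. thermoglucosidans Y4.1MC1,Hot Spring,II,44.02,34.83,-9.19,20.3,17
G. thermoglucosidans DSM 2542^T,Soil,II,43.69,36.16,-7.53,19.2,17
Geobacillus sp. PSS2,Dead steaming tree,III,51.58,36.93,-14.65,27.0,21
Geobacillus sp. C56-T2,Hot Spring,III,52.39,38.95,-13.44,30.4,23
Geobacillus sp. Y412MC52,Hot Spring,IV,52.43,44.58,-7.85,20.1,20
Geobacillus sp. Y412MC61,Hot Spring,IV,52.42,44.58,-7.84,20.1,20
G. thermocatenulatus GS-1,Oil well,IV,52.11,45.20,-6.91,20.5,19
Geobacillus sp. CAMR12739,CAMR thermophile culture collection,IV,52.21,44.67,-7.54,21.2,22
Geobacillus sp. MAS1,Hot Spring,IV,52.21,43.73,-8.48,21.5,20
Geobacillus sp. 10,Hot Spring,IV,52.71,43.29,-9.42,22.0,20
Geobacillus sp. Et7-4,Geyser,IV,51.69,41.96,-9.73,18.8,16
Geobacillus sp. GHH01,Botanical garden soil,IV,52.28,43.46,-8.82,18.9,18
Geobacillus sp. WSUCF1,Compost,V,52.21,39.44,-12.77,15.8,13
Geobacillus sp. PSS1,Dead steaming tree,V,52.40,38.13,-14.27,13.4,11
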