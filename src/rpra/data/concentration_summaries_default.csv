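# Heavy-metal concentration summaries for the Shunde Waterway survey area:
# arithmetic mean, sd and observed range per stratum x metal.
# Soils and sediment in mg/kg; surface water in ug/L.
stratum,metal,mean,sd,minimum,maximum,units,n_sites
RVS,As,72.3,26.8,34.7,106.3,mg/kg,7
RVS,Hg,0.39,0.12,0.25,0.59,mg/kg,7
RVS,Cd,2.25,1.13,1.02,4.01,mg/kg,7
RVS,Zn,358.6,249.6,170.2,907.7,mg/kg,7
RVS,Pb,100.3,26.1,59.0,125.5,mg/kg,7
RVS,Cu,61.7,20.4,39.1,99.6,mg/kg,7
RVS,Cr,71.5,4.3,66.7,77.4,mg/kg,7
RVS,Ni,27.5,5.2,21.4,36.2,mg/kg,7
RGS,As,42.5,34.2,14.9,133.4,mg/kg,13
RGS,Hg,0.29,0.10,0.12,0.45,mg/kg,13
RGS,Cd,1.02,0.77,0.28,2.44,mg/kg,13
RGS,Zn,262.6,354.9,85.1,1408.3,mg/kg,13
RGS,Pb,80.6,84.3,28.1,324.7,mg/kg,13
RGS,Cu,37.8,21.6,10.4,91.7,mg/kg,13
RGS,Cr,66.8,9.8,51.6,87.4,mg/kg,13
RGS,Ni,22.1,5.0,14.6,32.6,mg/kg,13
PVS,As,17.5,3.6,12.6,25.5,mg/kg,11
PVS,Hg,0.40,0.41,0.12,1.43,mg/kg,11
PVS,Cd,0.55,0.41,0.12,1.68,mg/kg,11
PVS,Zn,124.5,59.3,64.3,289.1,mg/kg,11
PVS,Pb,36.8,16.7,21.1,76.2,mg/kg,11
PVS,Cu,32.5,17.8,8.4,66.3,mg/kg,11
PVS,Cr,68.6,16.1,42.1,100.9,mg/kg,11
PVS,Ni,26.5,10.8,7.4,42.8,mg/kg,11
PGS,As,18.5,7.6,11.5,47.0,mg/kg,20
PGS,Hg,0.24,0.16,0.03,0.66,mg/kg,20
PGS,Cd,0.44,0.22,0.21,1.16,mg/kg,20
PGS,Zn,111.6,36.1,59.1,212.7,mg/kg,20
PGS,Pb,31.4,12.0,11.9,56.0,mg/kg,20
PGS,Cu,18.8,9.6,5.1,40.6,mg/kg,20
PGS,Cr,61.8,10.8,46.1,78.7,mg/kg,20
PGS,Ni,19.2,7.9,3.0,29.9,mg/kg,20
profile_0_100,As,27.8,20.5,11.6,62.7,mg/kg,6
profile_0_100,Hg,0.41,0.24,0.17,0.74,mg/kg,6
profile_0_100,Cd,1.29,1.02,0.43,2.97,mg/kg,6
profile_0_100,Zn,181.8,158.0,85.9,501.5,mg/kg,6
profile_0_100,Pb,52.5,35.8,26.9,123.7,mg/kg,6
profile_0_100,Cu,49.2,28.1,26.5,103.9,mg/kg,6
profile_0_100,Cr,73.3,14.6,52.0,96.5,mg/kg,6
profile_0_100,Ni,31.8,7.3,21.2,41.0,mg/kg,6
sediment,As,47.8,13.3,22.7,66.6,mg/kg,10
sediment,Hg,0.20,0.12,0.06,0.51,mg/kg,10
sediment,Cd,1.76,0.45,0.65,2.19,mg/kg,10
sediment,Zn,311.0,118.1,136.8,481.8,mg/kg,10
sediment,Pb,93.3,44.7,29.8,163.7,mg/kg,10
sediment,Cu,93.5,58.4,40.2,236.0,mg/kg,10
sediment,Cr,106.0,78.5,54.2,321.6,mg/kg,10
sediment,Ni,29.8,8.0,17.6,39.8,mg/kg,10
surface_water,As,3.2,1.1,2.2,5.4,ug/L,10
surface_water,Hg,0.02,0.01,0.01,0.03,ug/L,10
surface_water,Cd,0.10,0.07,0.03,0.25,ug/L,10
surface_water,Zn,12.6,4.0,5.9,19.4,ug/L,10
surface_water,Pb,2.3,2.5,0.7,9.0,ug/L,10
surface_water,Cu,3.8,2.2,2.0,8.0,ug/L,10
surface_water,Cr,2.4,4.3,0.5,14.6,ug/L,10
surface_water,Ni,2.3,2.0,1.2,7.6,ug/L,10
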