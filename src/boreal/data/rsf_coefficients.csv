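range,season,predictor,coefficient,transform
Missisa,spring,prop_conifer,1.20,exponential
Missisa,spring,prop_peatland,0.80,exponential
Missisa,spring,prop_water,-1.50,exponential
Missisa,spring,road_density,-9.00,exponential
Missisa,summer,prop_conifer,0.90,exponential
Missisa,summer,prop_peatland,1.10,exponential
Missisa,summer,prop_water,-1.00,exponential
Missisa,summer,road_density,-8.00,exponential
Missisa,fall,prop_conifer,1.00,exponential
Missisa,fall,prop_peatland,0.60,exponential
Missisa,fall,prop_water,-1.20,exponential
Missisa,fall,road_density,-4.00,exponential
Missisa,winter,prop_conifer,1.60,exponential
Missisa,winter,prop_peatland,0.40,exponential
Missisa,winter,prop_water,-2.00,exponential
Missisa,winter,road_density,-3.00,exponential
JamesBay,spring,prop_conifer,1.00,exponential
JamesBay,spring,prop_peatland,0.90,exponential
JamesBay,spring,prop_water,-1.20,exponential
JamesBay,spring,road_density,-1.00,exponential
JamesBay,summer,prop_conifer,0.80,exponential
JamesBay,summer,prop_peatland,1.00,exponential
JamesBay,summer,prop_water,-0.80,exponential
JamesBay,summer,road_density,-0.90,exponential
JamesBay,fall,prop_conifer,0.90,exponential
JamesBay,fall,prop_peatland,0.70,exponential
JamesBay,fall,prop_water,-1.00,exponential
JamesBay,fall,road_density,-0.70,exponential
JamesBay,winter,prop_conifer,1.40,exponential
JamesBay,winter,prop_peatland,0.50,exponential
JamesBay,winter,prop_water,-1.60,exponential
JamesBay,winter,road_density,-0.50,exponential
Nipigon,spring,prop_conifer,1.50,exponential
Nipigon,spring,prop_peatland,0.20,exponential
Nipigon,spring,prop_water,-0.60,exponential
Nipigon,spring,road_density,-0.20,exponential
Nipigon,summer,prop_conifer,1.30,exponential
Nipigon,summer,prop_peatland,0.30,exponential
Nipigon,summer,prop_water,-0.50,exponential
Nipigon,summer,road_density,-0.15,exponential
Nipigon,fall,prop_conifer,1.40,exponential
Nipigon,fall,prop_peatland,0.25,exponential
Nipigon,fall,prop_water,-0.55,exponential
Nipigon,fall,road_density,-0.10,exponential
Nipigon,winter,prop_conifer,1.80,exponential
Nipigon,winter,prop_peatland,0.10,exponential
Nipigon,winter,prop_water,-0.90,exponential
Nipigon,winter,road_density,-0.10,exponential
Pagwachuan,spring,prop_conifer,1.10,exponential
Pagwachuan,spring,prop_peatland,0.40,exponential
Pagwachuan,spring,prop_water,-0.70,exponential
Pagwachuan,spring,road_density,-0.30,exponential
Pagwachuan,summer,prop_conifer,1.00,exponential
Pagwachuan,summer,prop_peatland,0.50,exponential
Pagwachuan,summer,prop_water,-0.60,exponential
Pagwachuan,summer,road_density,-0.25,exponential
Pagwachuan,fall,prop_conifer,1.05,exponential
Pagwachuan,fall,prop_peatland,0.45,exponential
Pagwachuan,fall,prop_water,-0.65,exponential
Pagwachuan,fall,road_density,-0.20,exponential
Pagwachuan,winter,prop_conifer,1.50,exponential
Pagwachuan,winter,prop_peatland,0.20,exponential
Pagwachuan,winter,prop_water,-1.10,exponential
Pagwachuan,winter,road_density,-0.15,exponential
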