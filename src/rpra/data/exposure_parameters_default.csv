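# Exposure-parameter distributions — a literature-assembled stand-in table
# (synthetic defaults) in the style of the Chinese Exposure Factors Handbook
# and USEPA exposure factor compilations, for an adult receptor.
# family: point | lognormal (arithmetic mean/sd, truncated to [min,max]) |
# triangular (min, mode, max).  Exposure frequencies: 350 d/yr indoor,
# 225 d/yr outdoor.  Override per run with a table of the same schema.
name,family,mean,sd,min,max,mode,units,description
IR_s,lognormal,70,35,10,200,,mg/d,incidental soil ingestion rate
IR_sd,lognormal,50,25,10,150,,mg/d,incidental sediment ingestion rate while swimming
IR_w,lognormal,2.0,0.6,0.5,4.0,,L/d,drinking water ingestion rate
IR_v,lognormal,0.30,0.10,0.05,0.75,,kg/d,vegetable ingestion rate (fresh weight)
IR_a,lognormal,15,3,5,25,,m3/d,air inhalation rate
EF_ia,point,350,,,,,d/yr,exposure frequency for indoor activities
EF_oa,point,225,,,,,d/yr,exposure frequency for outdoor activities
EF_sw,lognormal,30,24,1,120,,events/yr,swimming frequency
ET_sw,triangular,1.42,,0.25,3.0,1.0,h/event,duration of a swimming event
ED,point,24,,,,,yr,exposure duration
BW,lognormal,60,10,40,100,,kg,adult body weight
SA_o,lognormal,0.50,0.15,0.20,1.00,,m2,exposed skin area during outdoor activity
SA_sw,lognormal,1.80,0.25,1.20,2.60,,m2,whole-body skin area while swimming
AF_sa,lognormal,0.20,0.12,0.02,0.80,,mg/cm2,soil-to-skin adherence (farming/outdoor)
AF_sd,lognormal,0.50,0.30,0.05,2.00,,mg/cm2,wet sediment-to-skin adherence
theta_v,triangular,0.90,,0.85,0.95,0.90,unitless,vegetable water content
theta_w,triangular,0.30,,0.15,0.45,0.30,L/L,water-filled soil porosity
rho_b,triangular,1.50,,1.20,1.80,1.50,g/cm3,dry soil bulk density
DF,lognormal,20,15,2,100,,unitless,leachate dilution factor to the aquifer
PEF,point,1.36e9,,,,,m3/kg,particulate emission factor
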