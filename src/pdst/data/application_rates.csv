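name,product_name,rate_units,product_rate_min,product_rate_max,ai_fraction,product_density_kg_L,slow_release_interval_years
"2,4-D","2,4-D",L_per_ha,1.55991085714,3.11982171429,0.625,1.12,
ametryn,ametryn,kg_per_ha,0.6251575,2.50063,0.8,,
amicarbazone,amicarbazone,kg_per_ha,0.56075796,1.4018949,0.5,,
asulam,asulam,kg_per_ha,5.1942144,6.9256192,0.5,,
atrazine,atrazine,kg_per_ha,1.113167616,3.3732352,0.9,,
bifenthrin,bifenthrin,kg_per_ha,0.0454584522664,0.0757640871106,0.5,,
cadusafos,cadusafos,kg_per_ha,6.3705066794,7.96313334925,0.5,,
carbofuran,carbofuran,kg_per_ha,5.97375,5.97375,0.5,,
chlorothalonil,chlorothalonil,kg_per_ha,1.146736875,2.29347375,0.72,,
chlorpyrifos,chlorpyrifos,kg_per_ha,0.484858516457,1.93943406583,0.5,,
clothianidin,clothianidin,kg_per_ha,0.4132303872,1.033075968,0.5,,
dicamba,dicamba,kg_per_ha,0.464184,0.618912,0.5,,
diquat dibromide,diquat dibromide,L_per_ha,0.553232399999,1.67646181818,0.2,1.1,
diuron,diuron,kg_per_ha,1.15519404,1.9253234,0.9,,
fipronil,fipronil,kg_per_ha,0.0785890784,0.098236348,0.5,,
fluazifop-P-butyl,fluazifop-P-butyl,kg_per_ha,0.44163072,0.44163072,0.5,,
fluensulfone,fluensulfone,kg_per_ha,1.9136176,3.8272352,0.5,,
flumioxazin,flumioxazin,kg_per_ha,0.18149153064,0.72596612256,0.5,,
fluroxypyr,fluroxypyr,L_per_ha,0.700211068212,1.75052767053,0.333,1.05,
flutriafol,flutriafol,kg_per_ha,3.92731515,5.2364202,0.5,,
glufosinate ammonium,glufosinate ammonium,kg_per_ha,0.62777088,1.902336,0.5,,
glyphosate,glyphosate,L_per_ha,3.82245217391,6.37075362319,0.45,1.15,
halosulfuron-methyl,halosulfuron-methyl,kg_per_ha,0.15871608544,0.1983951068,0.5,,
haloxyfop,haloxyfop,kg_per_ha,0.159148,0.159148,0.5,,
hexazinone,hexazinone,kg_per_ha,0.35525248,0.71050496,0.75,,
imazapic,imazapic,kg_per_ha,0.04831515,0.1932606,0.5,,
imidacloprid,imidacloprid (L),kg_per_ha,0.572237203884,1.43059300971,0.35,,
imidacloprid,imidacloprid (SR),kg_per_ha,1.14419975588,2.86049938971,0.35,,4
isoxaflutole,isoxaflutole,kg_per_ha,0.228419724,0.304559632,0.5,,
MCPA,MCPA,kg_per_ha,0.7195115928,2.18033816,0.5,,
metolachlor,metolachlor,kg_per_ha,2.0471021376,3.411836896,0.5,,
metribuzin,metribuzin,kg_per_ha,1.6457472,2.057184,0.75,,
metsulfuron-methyl,metsulfuron-methyl,kg_per_ha,0.01403099712,0.01403099712,0.5,,
MSMA,MSMA,L_per_ha,2.98084106692,5.96168213384,0.72,1.1,
paraquat dichloride,paraquat dichloride,L_per_ha,0.38764488889,1.55057955556,0.25,1.08,
pendimethalin,pendimethalin,kg_per_ha,1.32734077609,3.31835194023,0.44,,
permethrin,permethrin,kg_per_ha,0.1525992,0.2034656,0.5,,
picloram,picloram,kg_per_ha,0.1172916096,0.35542912,0.5,,
propiconazole,propiconazole,kg_per_ha,0.035727768,0.05954628,0.5,,
S-metolachlor,S-metolachlor,kg_per_ha,2.76322009392,3.4540251174,0.5,,
tebuconazole,tebuconazole,kg_per_ha,0.25118112,0.25118112,0.5,,
terbuthylazine,terbuthylazine,kg_per_ha,0.696787,1.393574,0.75,,
terbutryn,terbutryn,kg_per_ha,0.55319712,2.21278848,0.5,,
triadimenol,triadimenol,kg_per_ha,0.02425232,0.0606308,0.5,,
trichlorfon,trichlorfon,kg_per_ha,0.8858935176,1.1811913568,0.5,,
trifloxysulfuron sodium,trifloxysulfuron sodium,kg_per_ha,0.0245819772,0.07449084,0.5,,
trifluralin,trifluralin,kg_per_ha,0.02571505398,0.0428584233,0.48,,
trinexapac-ethyl,trinexapac-ethyl,kg_per_ha,0.29867584,0.3733448,0.5,,
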