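formulation,name,mobility,effect,risk_reported,risk_lt_one
"2,4-D","2,4-D",18,52,9,0
ametryn,ametryn,155,20000,31000,0
amicarbazone,amicarbazone,305,350,1100,0
asulam,asulam,48,16,8,0
atrazine,atrazine,1138,782,8900,0
bifenthrin,bifenthrin,0.01,208333,21,0
cadusafos,cadusafos,182,2197802,4000000,0
carbofuran,carbofuran,35,1500,520,0
chlorothalonil,chlorothalonil,0.133,3450,5,0
chlorpyrifos,chlorpyrifos,4,21276596,850000,0
clothianidin,clothianidin,3938,1724,68000,0
dicamba,dicamba,87,5,4,0
diquat dibromide,diquat dibromide,0.01,335,,1
diuron,diuron,136,2478,3400,0
fipronil,fipronil,777,5618,43600,0
fluazifop-P-butyl,fluazifop-P-butyl,40,48,20,0
fluensulfone,fluensulfone,26,160,40,0
flumioxazin,flumioxazin,4,85366,3500,0
fluroxypyr,fluroxypyr,27,2,1,0
flutriafol,flutriafol,9977,11,1100,0
glufosinate ammonium,glufosinate ammonium,6,10,1,0
glyphosate,glyphosate,12,13,2,0
halosulfuron-methyl,halosulfuron-methyl,40,2074,830,0
haloxyfop,haloxyfop,22,0.04,,1
hexazinone,hexazinone,1274,480,6100,0
imazapic,imazapic,6,234,15,0
imidacloprid (L),imidacloprid,1046,4167,43600,0
imidacloprid (SR),imidacloprid,1046,2083,21800,0
isoxaflutole,isoxaflutole,0.06,326,,1
MCPA,MCPA,71,494,350,0
metolachlor,metolachlor,1170,3757,44000,0
metribuzin,metribuzin,168,600,1000,0
metsulfuron-methyl,metsulfuron-methyl,268,292,780,0
MSMA,MSMA,1354,5831,79000,0
paraquat dichloride,paraquat dichloride,0.01,148,,1
pendimethalin,pendimethalin,0.01,30531,3,0
permethrin,permethrin,0.01,10000,1,0
picloram,picloram,1871,0.32,6,0
propiconazole,propiconazole,37,3,1,0
S-metolachlor,S-metolachlor,69,7513,5200,0
tebuconazole,tebuconazole,242,24,58,0
terbuthylazine,terbuthylazine,67,875,590,0
terbutryn,terbutryn,100,3056,3100,0
triadimenol,triadimenol,1345,0.25,3,0
trichlorfon,trichlorfon,6,17647,1100,0
trifloxysulfuron sodium,trifloxysulfuron sodium,177,100,180,0
trifluralin,trifluralin,0.01,6261,1,0
trinexapac-ethyl,trinexapac-ethyl,0.14,2,,1
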