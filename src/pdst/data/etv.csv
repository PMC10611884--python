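name,limit_umol_L,limit_type,method,percentile,reliability
"2,4-D",0.19,ETV,SSD,95,high
ametryn,0.00044,DGV,SSD,95,high
amicarbazone,0.0083,ETV,SSD,95,low
asulam,0.94,ETV,SSD,95,moderate
atrazine,0.018,DGV,SSD,95,very_high
bifenthrin,4.3e-07,ETV,SSD,99,low
cadusafos,6.7e-06,ETV,AF,NA,unknown
carbofuran,0.009,ETV,SSD,95,very_high
chlorothalonil,0.0018,DGV,SSD,95,high
chlorpyrifos,1.3e-07,ETV,SSD,99,very_high
clothianidin,0.0012,ETV,SSD,95,low
dicamba,0.28,ETV,SSD,95,high
diquat dibromide,0.0032,ETV,SSD,95,low
diuron,0.003,DGV,SSD,95,high
fipronil,2e-05,ETV,SSD,99,moderate
fluazifop-P-butyl,0.012,ETV,AF,NA,unknown
fluensulfone,0.041,ETV,SSD,95,moderate
flumioxazin,1.2e-05,ETV,SSD,95,moderate
fluroxypyr,1.2,DGV,SSD,95,moderate
flutriafol,0.79,ETV,SSD,95,low
glufosinate ammonium,0.48,ETV,SSD,95,low
glyphosate,1.5,DGV,SSD,95,moderate
halosulfuron-methyl,0.00011,ETV,SSD,95,low
haloxyfop,5.5,DGV,SSD,95,low
hexazinone,0.0044,DGV,SSD,95,low
imazapic,0.0015,DGV,SSD,95,very_low
imidacloprid,0.00047,DGV,SSD,95,moderate
isoxaflutole,0.0013,DGV,SSD,95,low
MCPA,0.011,ETV,SSD,95,very_high
metolachlor,0.0016,DGV,SSD,95,very_high
metribuzin,0.012,DGV,SSD,95,high
metsulfuron-methyl,6.3e-05,DGV,SSD,95,moderate
MSMA,0.005,ETV,AF,NA,unknown
paraquat dichloride,0.011,DGV,SSD,95,moderate
pendimethalin,0.00017,DGV,SSD,99,moderate
permethrin,2.6e-05,DGV,SSD,99,moderate
picloram,2.3,DGV,SSD,95,low
propiconazole,0.029,DGV,SSD,95,moderate
S-metolachlor,0.00081,ETV,SSD,95,low
tebuconazole,0.017,ETV,SSD,95,moderate
terbuthylazine,0.0052,DGV,SSD,95,very_high
terbutryn,0.0015,DGV,SSD,95,moderate
triadimenol,0.41,ETV,SSD,95,moderate
trichlorfon,0.00013,ETV,SSD,95,very_high
trifloxysulfuron sodium,0.00081,ETV,SSD,95,low
trifluralin,9.8e-06,ETV,SSD,99,moderate
trinexapac-ethyl,0.37,ETV,SSD,95,low
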