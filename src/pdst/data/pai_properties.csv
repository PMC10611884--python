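name,pesticide_class,chemical_class,molar_mass_g_mol,koc_exp_L_kg,koc_model_L_kg,log_kow,pka,dt50_soil_days,dt50_water_days,mobility_given
"2,4-D",herbicide,phenoxy acid,221.04,39.3,56.0,-0.82,2.87,4.4,17.7418974555,
ametryn,herbicide,triazine,227.33,316.0,360.0,2.63,4.1,37.0,30.0598680465,
amicarbazone,herbicide,triazolinone,241.29,30.0,41.0,1.18,,54.0,23.3013966231,
asulam,herbicide,carbamate,230.24,,40.0,-0.29,4.82,7.0,29.8387764858,
atrazine,herbicide,triazine,215.68,100.0,169.0,2.7,1.7,75.0,79.9817264948,
bifenthrin,insecticide,pyrethroid,422.87,236610.0,302000.0,6.6,,26.0,10.0,0.01
cadusafos,insecticide,organophosphate,270.39,227.0,310.0,3.85,,39.0,30.3351708836,
carbofuran,insecticide,carbamate,221.25,22.0,29.0,1.8,,14.0,9.76686528963,
chlorothalonil,fungicide,chloronitrile,265.91,850.0,2630.0,2.94,,22.0,0.0629330051301,
chlorpyrifos,insecticide,organophosphate,350.59,5509.0,7430.0,4.7,,27.6,10.149337201,
clothianidin,insecticide,neonicotinoid,249.68,123.0,160.0,0.91,,545.0,39.9980162571,
dicamba,herbicide,benzoic acid,221.04,13.0,12.0,-1.88,1.87,6.4,48.7250274935,
diquat dibromide,herbicide,bipyridylium,344.05,2184580.0,1139.6,-4.6,,1000.0,3.0,0.01
diuron,herbicide,phenylurea,233.09,813.0,680.0,2.87,,146.0,9.50427226262,
fipronil,insecticide,phenylpyrazole,437.15,727.0,803.0,4.01,,142.0,53.1752736182,
fluazifop-P-butyl,herbicide,aryloxyphenoxypropionate,383.36,,3394.0,4.5,,78.0,14.455634769,
fluensulfone,nematicide,fluoroalkenyl sulfone,291.71,,130.0,1.96,,13.0,11.2215141135,
flumioxazin,herbicide,N-phenylphthalimide,354.34,889.0,620.0,2.55,,17.5,2.42906149841,
fluroxypyr,herbicide,pyridine carboxylic acid,255.03,68.0,52.0,-1.07,2.94,11.3,11.5660106781,
flutriafol,fungicide,triazole,301.29,205.0,250.0,2.3,,1358.0,46.4115047942,
glufosinate ammonium,herbicide,phosphinic acid,198.16,,600.0,-3.96,2.0,7.4,7.28468517542,
glyphosate,herbicide,glycine derivative,169.07,1424.0,2100.0,-3.2,2.34,15.0,10.8869705429,
halosulfuron-methyl,herbicide,sulfonylurea,434.81,,93.5,-0.02,3.44,14.0,14.8306654497,
haloxyfop,herbicide,aryloxyphenoxypropionate,361.7,75.0,110.0,1.59,4.27,9.0,12.0833347354,
hexazinone,herbicide,triazinone,252.31,54.0,73.0,1.17,2.2,105.0,55.9981034493,
imazapic,herbicide,imidazolinone,275.3,137.0,110.0,0.39,3.9,120.0,0.284197425554,
imidacloprid,insecticide,neonicotinoid,255.66,225.0,260.0,0.57,,191.0,35.5096263445,
isoxaflutole,herbicide,isoxazole,359.32,145.0,120.0,2.32,,0.9,0.384355441863,
MCPA,herbicide,phenoxy acid,200.62,74.0,93.0,-0.81,3.73,24.0,14.5812438674,
metolachlor,herbicide,chloroacetamide,283.79,120.0,180.0,3.4,,90.0,71.5340260848,
metribuzin,herbicide,triazinone,214.29,38.0,60.0,1.65,0.99,19.0,38.1041455545,
metsulfuron-methyl,herbicide,sulfonylurea,381.36,39.5,35.0,-1.87,3.75,30.0,38.7804065737,
MSMA,herbicide,organoarsenic,161.95,,1000.0,-3.1,4.1,1000.0,15.222034851,
paraquat dichloride,herbicide,bipyridylium,257.16,1000000.0,1067.2,-4.5,,3000.0,7.0,0.01
pendimethalin,herbicide,dinitroaniline,281.31,17491.0,15000.0,5.2,,100.0,4.0,0.01
permethrin,insecticide,pyrethroid,391.28,100000.0,62000.0,6.1,,13.0,1.0,0.01
picloram,herbicide,pyridine carboxylic acid,241.46,13.0,16.0,-1.92,2.3,82.0,81.7848288784,
propiconazole,fungicide,triazole,342.22,1086.0,720.0,3.72,1.09,71.8,6.03845349912,
S-metolachlor,herbicide,chloroacetamide,283.79,226.0,180.0,3.05,,15.0,29.8643056185,
tebuconazole,fungicide,triazole,307.82,769.0,500.0,3.7,,63.0,38.2428763306,
terbuthylazine,herbicide,triazine,229.71,231.0,280.0,3.4,1.9,22.0,19.8955096626,
terbutryn,herbicide,triazine,241.36,2432.0,800.0,3.66,4.3,74.0,26.9944659641,
triadimenol,fungicide,triazole,295.76,750.0,520.0,3.18,,250.0,52.9846577277,
trichlorfon,insecticide,organophosphate,257.44,10.0,16.0,0.43,,2.7,7.65043626613,
trifloxysulfuron sodium,herbicide,sulfonylurea,459.82,,59.0,-0.43,4.76,38.0,21.8887109557,
trifluralin,herbicide,dinitroaniline,335.28,15800.0,8765.0,5.27,,181.0,1.0,0.01
trinexapac-ethyl,herbicide,cyclohexanedione,252.26,,498.0,-0.29,4.57,0.73,1.60543581965,
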