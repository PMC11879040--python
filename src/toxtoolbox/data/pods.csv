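chem_id,name,smiles,mol_weight,use_category,ipp_min_uM,csp_global_uM,httr_global_hepg2_uM,httr_global_heparg_uM,httr_global_mcf7_uM,httr_pathway_hepg2_uM,httr_pathway_heparg_uM,httr_pathway_mcf7_uM
bha,butylated hydroxyanisole,,209.67,Food,25.0,2.5,2.0,3.0,4.0,2.5,3.75,5.0
cetirizine,cetirizine dihydrochloride,,154.89,Drug,0.025,6.25,6.25,9.375,12.5,12.5,18.75,25.0
chem05,benchmark chemical 05,,113.01,Drug,,5.0,4.0,6.0,8.0,5.0,7.5,10.0
chem06,benchmark chemical 06,,116.23,Drug,,12.5,1.0,1.5,2.0,12.5,18.75,25.0
chem07,benchmark chemical 07,,119.45,Drug,,6.25,0.5,0.75,1.0,62.5,93.75,125.0
chem08,benchmark chemical 08,,122.67,Drug,,2.5,2.0,3.0,4.0,25.0,37.5,50.0
chem09,benchmark chemical 09,,125.9,Drug,,1.25,1.0,1.5,2.0,1.25,1.875,2.5
chem10,benchmark chemical 10,,129.12,Agricultural,,1.0,0.8,1.2000000000000002,1.6,1.0,1.5000000000000002,2.0
chem11,benchmark chemical 11,,132.34,Drug,,1.25,1.0,1.5,2.0,1.25,1.875,2.5
chem12,benchmark chemical 12,,135.56,Drug,,2.5,2.0,3.0,4.0,2.5,3.75,5.0
chem13,benchmark chemical 13,,138.78,Cosmetic,,55.0,55.0,82.5,110.0,110.0,165.0,220.0
chem14,benchmark chemical 14,,142.01,Cosmetic,,55.0,4.4,6.6000000000000005,8.8,55.0,82.5,110.0
chem15,benchmark chemical 15,,145.23,Food,,5.5,4.4,6.6000000000000005,8.8,5.5,8.25,11.0
chem20,benchmark chemical 20,,161.34,Drug,12.5,12.5,1.0,1.5,2.0,12.5,18.75,25.0
chem21,benchmark chemical 21,,164.56,Drug,12.5,1.25,1.0,1.5,2.0,12.5,18.75,25.0
chem22,benchmark chemical 22,,167.78,Drug,1.25,12.5,1.0,1.5,2.0,12.5,18.75,25.0
chem23,benchmark chemical 23,,171.0,Agricultural,0.75,7.5,0.6000000000000001,0.9000000000000001,1.2000000000000002,7.5,11.25,15.0
chem24,benchmark chemical 24,,174.23,Drug,1.875,18.75,1.5,2.25,3.0,1.875,2.8125,3.75
chem25,benchmark chemical 25,,177.45,Agricultural,1.25,1.25,1.0,1.5,2.0,12.5,18.75,25.0
chem26,benchmark chemical 26,,180.67,Drug,0.875,0.875,0.7000000000000001,1.05,1.4000000000000001,8.75,13.125,17.5
chem27,benchmark chemical 27,,183.89,Agricultural,1.25,1.25,1.0,1.5,2.0,1.25,1.875,2.5
chem28,benchmark chemical 28,,187.11,Drug,2.5,2.5,2.0,3.0,4.0,2.5,3.75,5.0
chem29,benchmark chemical 29,,190.34,Drug,1.25,1.25,1.0,1.5,2.0,1.25,1.875,2.5
chem30,benchmark chemical 30,,193.56,Agricultural,0.625,0.625,0.5,0.75,1.0,0.625,0.9375,1.25
chem31,benchmark chemical 31,,196.78,Drug,3.75,3.75,3.0,4.5,6.0,3.75,5.625,7.5
chem32,benchmark chemical 32,,200.0,Cosmetic,55.0,55.0,55.0,82.5,110.0,110.0,165.0,220.0
chem33,benchmark chemical 33,,203.22,Food,27.5,27.5,27.5,41.25,55.0,55.0,82.5,110.0
chem34,benchmark chemical 34,,206.45,Cosmetic,2.2,220.0,22.0,33.0,44.0,220.0,330.0,440.0
chem36,benchmark chemical 36,,212.89,Cosmetic,55.0,5.5,4.4,6.0,7.0,5.5,7.5,8.75
chem37,benchmark chemical 37,,216.11,Cosmetic,55.0,5.5,4.4,6.6000000000000005,8.8,5.5,8.25,11.0
chem38,benchmark chemical 38,,219.33,Cosmetic,55.0,55.0,4.4,6.6000000000000005,8.8,55.0,82.5,110.0
ketoconazole,ketoconazole,,148.45,Drug,5.0,50.0,0.5,0.75,1.0,50.0,75.0,100.0
metoclopramide,metoclopramide,,151.67,Drug,0.046,50.0,16.0,30.0,40.0,60.0,80.0,90.0
octanediol,"1,2-octanediol",,106.56,Cosmetic,,5.5,5.5,6.0,7.0,6.0,7.0,8.0
panthenol,panthenol,,109.79,Cosmetic,,55.0,60.0,0.05,0.08,70.0,50.0,60.0
trimellitic_anhydride,trimellitic anhydride,,103.34,Occupational,,150.0,120.0,150.0,200.0,400.0,500.0,600.0
verapamil,verapamil hydrochloride,,158.12,Drug,0.1,25.0,25.0,37.5,50.0,50.0,75.0,100.0
warfarin,warfarin,,100.12,Drug,,80.0,20.0,13.6,30.0,300.0,259.0,350.0
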