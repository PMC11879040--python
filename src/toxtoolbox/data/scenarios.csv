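scenario_id,chem_id,route,applied_dose_mgkgd,cmax_l1_uM,cmax_l2_uM,cmax_l3_uM,risk_label
bha_diet,bha,oral,1.0,2.0,2.0,2.0,low
cetirizine_oral,cetirizine,oral,1.0,0.5,0.5,0.5,high
chem05_s1,chem05,oral,2.0,0.03,4.0,4.0,high
chem06_s1,chem06,iv,1.0,1.0,1.0,1.0,high
chem06_s2,chem06,iv,1.0,1.0,1.0,1.0,high
chem07_s1,chem07,oral,1.0,0.5,0.5,0.5,high
chem07_s2,chem07,oral,10.0,5.0,5.0,5.0,high
chem08_s1,chem08,oral,1.0,2.0,2.0,2.0,high
chem09_s1,chem09,oral,1.0,1.0,1.0,1.0,high
chem09_s2,chem09,oral,1.0,1.0,1.0,1.0,high
chem10_s1,chem10,oral,1.0,0.8,0.8,0.8,high
chem10_s2,chem10,oral,1.0,0.8,0.8,0.8,high
chem11_s1,chem11,oral,1.0,1.0,1.0,1.0,high
chem11_s2,chem11,oral,1.0,1.0,1.0,,high
chem12_s1,chem12,oral,1.0,2.0,2.0,2.0,high
chem12_s2,chem12,oral,1.0,2.0,2.0,,high
chem13_s1,chem13,dermal,1.0,1.0,1.0,,low
chem14_s1,chem14,dermal,1.0,1.0,1.0,,low
chem14_s2,chem14,dermal,1.0,1.0,1.0,,low
chem15_s1,chem15,oral,1.0,1.0,1.0,,low
chem20_s1,chem20,oral,1.0,1.0,1.0,1.0,high
chem20_s2,chem20,oral,1.0,1.0,1.0,1.0,high
chem21_s1,chem21,oral,1.0,1.0,1.0,1.0,high
chem21_s2,chem21,iv,1.0,1.0,1.0,1.0,high
chem22_s1,chem22,oral,1.0,1.0,1.0,1.0,high
chem22_s2,chem22,oral,1.0,1.0,1.0,1.0,high
chem23_s1,chem23,oral,1.0,0.6,0.6,0.6,high
chem23_s2,chem23,oral,1.0,0.6,0.6,0.6,high
chem24_s1,chem24,oral,1.0,1.5,1.5,1.5,high
chem24_s2,chem24,oral,1.0,1.5,1.5,1.5,high
chem25_s1,chem25,oral,1.0,1.0,1.0,1.0,high
chem25_s2,chem25,oral,1.0,1.0,1.0,1.0,high
chem26_s1,chem26,iv,1.0,0.7,0.7,0.7,high
chem26_s2,chem26,iv,1.0,0.7,0.7,0.7,high
chem27_s1,chem27,oral,1.0,1.0,1.0,1.0,high
chem27_s2,chem27,oral,1.0,1.0,1.0,,high
chem27_s3,chem27,oral,1.0,1.0,1.0,,low
chem28_s1,chem28,oral,1.0,2.0,2.0,2.0,high
chem28_s2,chem28,oral,1.0,2.0,2.0,,high
chem28_s3,chem28,oral,1.0,2.0,2.0,,low
chem29_s1,chem29,oral,1.0,1.0,1.0,1.0,high
chem29_s2,chem29,oral,1.0,1.0,1.0,1.0,high
chem29_s3,chem29,oral,1.0,1.0,1.0,1.0,high
chem30_s1,chem30,oral,1.0,0.5,0.5,0.5,high
chem30_s2,chem30,oral,1.0,0.5,0.5,0.5,high
chem31_s1,chem31,oral,1.0,3.0,3.0,3.0,high
chem31_s2,chem31,oral,1.0,3.0,3.0,3.0,high
chem32_s1,chem32,dermal,1.0,1.0,1.0,,low
chem32_s2,chem32,dermal,1.0,1.0,1.0,,low
chem33_s1,chem33,oral,1.0,0.5,0.5,,low
chem33_s2,chem33,oral,1.0,0.5,0.5,,low
chem34_s1,chem34,dermal,0.1,0.4,0.4,,low
chem34_s2,chem34,dermal,1.0,4.0,4.0,,low
chem36_s1,chem36,dermal,0.4,0.03,1.0,,low
chem36_s2,chem36,dermal,0.4,1.0,1.0,,low
chem37_s1,chem37,oral,1.0,1.0,1.0,,low
chem37_s2,chem37,oral,1.0,1.0,1.0,,low
chem38_s1,chem38,oral,1.0,1.0,1.0,,low
chem38_s2,chem38,oral,1.0,1.0,1.0,,low
ketoconazole_oral,ketoconazole,oral,3.0,4.0,4.0,4.0,high
ketoconazole_shampoo_long,ketoconazole,dermal,0.02,0.4,0.4,0.4,low
ketoconazole_shampoo_short,ketoconazole,dermal,0.02,0.4,0.4,0.4,low
metoclopramide_oral,metoclopramide,oral,0.5,1.0,1.0,1.0,high
octanediol_body_lotion,octanediol,dermal,0.2,0.01,,,low
panthenol_body_lotion,panthenol,dermal,0.3,1.0,,,low
trimellitic_case_report,trimellitic_anhydride,inhalation,0.5,2.0,2.0,,high
trimellitic_occupational,trimellitic_anhydride,inhalation,0.1,1.2,1.0,,low
verapamil_iv,verapamil,iv,1.0,2.0,2.0,2.0,high
warfarin_high_dose,warfarin,oral,0.15,0.1,1.0,6.0,high
warfarin_low_dose,warfarin,oral,0.05,0.1,0.12,0.6,high
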