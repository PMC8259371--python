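accession,taxon,x,2n,thcl,m_ca,cv_cl,cv_ci,kf,clr_min,clr_max,stebbins
aur,Daucus aureus [PI 319403],11,22,23.50,36.89,17.85,10.23,1m + 10sm,1.54,2.89,3A
cap1,Daucus carota subsp. capillifolius [PI 279764],9,18,28.67,34.63,17.68,22.12,8sm + 1st,2.32,4.08,3A
cap2,Daucus carota subsp. capillifolius [Ames 30198],9,18,22.19,34.79,18.33,16.94,8sm + 1st,1.89,3.36,3A
car1,Daucus carota subsp. carota [PI 274297],9,18,28.95,34.01,17.26,20.19,7sm + 2st,2.38,4.03,3A
car2,Daucus carota subsp. carota [PI 478369],9,18,24.56,33.36,16.21,18.24,1m + 6sm + 2st,2.07,3.61,2A
car3,Daucus carota subsp. carota [PI 478861],9,18,31.15,35.89,15.13,26.50,1m + 4sm + 4st,2.62,4.33,3A
car4,Daucus carota subsp. carota [PI 652393],9,18,25.23,35.79,15.52,19.38,6sm + 3st,2.04,3.45,3A
gum1,Daucus carota subsp. gummifer [PI 478883],9,18,33.47,35.94,17.42,24.31,5sm + 4st,2.72,4.77,3A
gum2,Daucus carota subsp. gummifer [Ames 26383],9,18,28.32,34.06,17.41,18.45,1m + 5sm + 3st,2.39,4.20,2A
sat1,Daucus carota subsp. sativus ['Amsterdam'],9,18,29.86,35.73,16.04,24.37,7sm + 2st,2.55,4.16,3A
sat2,Daucus carota subsp. sativus ['Dolanka'],9,18,29.90,31.04,14.70,18.93,1m + 8sm,2.65,4.26,3A
sat3,Daucus carota subsp. sativus [DH1],9,18,28.08,34.45,14.38,19.65,8sm + 1st,2.42,3.91,3A
rou,Daucus rouyi [PI 674284],10,20,35.50,38.74,20.41,14.47,2m + 8sm,2.45,5.12,3A
sah,Daucus sahariensis [Ames 29097],9,18,27.97,32.28,20.46,13.68,2m + 7sm,2.24,4.20,3A
syr,Daucus syrticus [Ames 29108],9,18,26.86,26.08,17.66,9.39,6m + 3sm,2.25,4.07,2A
orl,Orlaya daucoides [PI 649477],8,16,35.61,20.55,30.47,12.16,2m + 6sm,3.27,7.73,2A
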