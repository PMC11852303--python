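species,years,area_km2,llt_c
Chitala ornata,30,605,12
Misgurnus anguillicaudatus,36,7703,0
Hoplosternum littorale,29,80312,10
Hypostomus sp.,66,350,11.2
Pterygoplichthys sp.,33,78025,10
Clarias batrachus,57,79130,9.8
Belonesox belizanus,67,12221,9.7
Xiphophorus hellerii,54,2439,7.5
Xiphophorus maculatus,54,89,7.3
Xiphophorus variatus,54,210,7.3
Monopterus albus/javanensis,27,9580,8
Macrognathus siamensis,22,2970,9
Amphilophus citrinellus,43,847,12
Astronotus ocellatus,64,21774,12.9
Cichla ocellaris,40,12820,15
Cichlasoma bimaculatum,64,30166,8.9
Trichromis salvini,44,1115,9.5
Mayaheros urophthalmus,40,51768,10
Astatotilapia calliptera,26,43,10.5
Rubricatochromis letourneuxi,65,41136,9.5
Herichthys cyanoguttatus,84,1253,5
Heros severus,31,1420,12.8
Oreochromis aureus,63,83005,6.2
Oreochromis mossambicus,54,3845,9.5
Oreochromis niloticus,18,22761,8.2
Parachromis managuensis,32,7927,12
Rocio octofasciata,64,871,8
Sarotherodon melanotheron,64,3811,10.3
Pelmatolapia mariae,50,36390,11.2
Channa aurolineata,24,2129,10
Trichopsis vittata,46,3,7.2
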