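species,spread_rate,potential_range_km2,pct_range_per_yr,category
Chitala ornata,20,111523,0.018,slow
Misgurnus anguillicaudatus,214,141300,0.151,slow
Hoplosternum littorale,2769,128371,2.157,fast
Hypostomus sp.,5,111523,0.005,slow
Pterygoplichthys sp.,2364,128371,1.842,fast
Clarias batrachus,1388,128371,1.081,fast
Belonesox belizanus,182,128371,0.142,slow
Xiphophorus hellerii,45,141300,0.032,slow
Xiphophorus maculatus,2,141300,0.001,slow
Xiphophorus variatus,4,141300,0.003,slow
Monopterus albus/javanensis,355,141300,0.251,fast
Macrognathus siamensis,135,128371,0.105,slow
Amphilophus citrinellus,20,111523,0.018,slow
Astronotus ocellatus,340,75038,0.453,fast
Cichla ocellaris,321,32026,1.001,fast
Cichlasoma bimaculatum,471,128371,0.367,fast
Trichromis salvini,25,128371,0.020,slow
Mayaheros urophthalmus,1294,128371,1.008,fast
Astatotilapia calliptera,2,128371,0.001,slow
Rubricatochromis letourneuxi,633,128371,0.493,fast
Herichthys cyanoguttatus,15,141300,0.011,slow
Heros severus,46,75038,0.061,slow
Oreochromis aureus,1318,141300,0.932,fast
Oreochromis mossambicus,71,128371,0.055,slow
Oreochromis niloticus,1265,141300,0.895,fast
Parachromis managuensis,248,111523,0.222,fast
Rocio octofasciata,14,141300,0.010,slow
Sarotherodon melanotheron,60,128371,0.046,slow
Pelmatolapia mariae,728,111523,0.653,fast
Channa aurolineata,89,128371,0.069,slow
Trichopsis vittata,0,141300,0.000,slow
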