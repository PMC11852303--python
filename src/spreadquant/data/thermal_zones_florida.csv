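llt_upper_bound_c,potential_area_km2
8.6,141300
11.0,128371
12.5,111523
13.5,75038
15.0,32026
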