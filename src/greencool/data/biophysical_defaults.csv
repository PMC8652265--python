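base_class,base_code,albedo,kc,green_area
building,1,0.20,0.10,0
"road, path",2,0.10,0.05,0
sidewalk,3,0.25,0.05,0
traffic island,4,0.20,0.30,0
other impervious,5,0.18,0.05,0
garden,6,0.22,0.85,1
forest,7,0.15,1.00,1
water,8,0.07,1.00,0
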