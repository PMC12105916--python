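veg_class,reserve_area_km2,buffer_area_km2,low,medium,high,extreme
Rainforests (Pyrophyte 0-<1%),4.75,2.04,0.16,0.23,0.01,0.001
Rainforests (Pyrophyte 1-10%),22.39,9.59,1.96,1.17,0.03,0.01
Rainforests (Pyrophyte 11-30%),5.3,3.22,0.79,0.65,0.02,0.01
Wet Sclerophyll Forests (Shrubby subformation),50.37,31.58,12.5,7.81,2.13,0.22
Wet Sclerophyll Forests (Grassy subformation),15.05,9.28,4.26,2.31,0.61,0.03
Dry Sclerophyll Forests (Shrubby subformation),3.13,1.58,0.46,0.75,0.31,0.01
Heathlands,2.42,1.29,0.1,0.4,0.61,0.1
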