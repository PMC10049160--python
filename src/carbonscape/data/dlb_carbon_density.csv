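class_code,class_name,year,above,below,soil,dead
1,farmland,2020,1.80,0.35,61.41,0.00
2,forests,2020,27.12,7.32,111.12,1.16
3,grassland,2020,1.19,2.37,63.42,0.06
4,wetland,2020,8.50,1.95,131.61,0.95
5,waters,2020,0.00,0.00,0.00,0.00
6,construction,2020,0.00,0.00,44.15,0.00
7,unused,2020,0.00,0.00,30.47,0.00
1,farmland,2030,1.93,0.38,66.06,0.00
2,forests,2030,28.05,7.57,114.96,1.20
3,grassland,2030,1.26,2.49,66.90,0.07
4,wetland,2030,8.24,1.89,127.62,0.92
5,waters,2030,0.00,0.00,0.00,0.00
6,construction,2030,0.00,0.00,49.14,0.00
7,unused,2030,0.00,0.00,29.94,0.00
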