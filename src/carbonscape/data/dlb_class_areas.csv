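class_code,class_name,2020,2030_nes,2030_eps,2030_eds,2030_pds
1,farmland,73615.78,72698.53,72643.50,72861.43,72707.71
2,forests,160449.22,160364.60,160570.26,160279.99,160496.34
3,grassland,13568.41,13199.58,13785.44,13015.16,13207.69
4,wetland,4416.96,4567.22,4682.18,4448.08,4468.54
5,waters,4561.83,4655.35,4737.22,4561.83,4570.83
6,construction,6580.18,7707.39,6775.37,8031.38,7743.02
7,unused,30.46,30.17,28.87,24.97,28.71
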