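group,layer,eccentricity_um,retardation_um,thickness_ratio,area_ratio,volume_ratio
PG1,GCL_IPL,300,31,1.19,0.80,0.96
PG1,GCL_IPL,500,48,0.83,0.82,0.68
PG1,GCL_IPL,700,54,0.83,0.85,0.70
PG1,GCL_IPL,900,61,0.80,0.87,0.70
PG2,GCL_IPL,300,113,0.84,0.39,0.33
PG2,GCL_IPL,500,120,0.90,0.58,0.52
PG2,GCL_IPL,700,78,0.93,0.79,0.74
PG2,GCL_IPL,900,50,0.86,0.89,0.77
PG3,GCL_IPL,300,252,2.19,0.03,0.06
PG3,GCL_IPL,500,313,0.94,0.14,0.13
PG3,GCL_IPL,700,288,1.04,0.35,0.36
PG3,GCL_IPL,900,264,1.11,0.50,0.55
PG1,INL,300,13,1.01,0.91,0.92
PG1,INL,500,10,1.20,0.96,1.15
PG1,INL,700,40,1.05,0.89,0.93
PG1,INL,900,70,0.96,0.85,0.81
PG2,INL,300,185,1.04,0.15,0.15
PG2,INL,500,171,1.13,0.43,0.49
PG2,INL,700,189,1.08,0.53,0.58
PG2,INL,900,222,0.98,0.57,0.56
PG3,INL,300,250,2.03,0.03,0.06
PG3,INL,500,315,1.44,0.14,0.20
PG3,INL,700,363,1.20,0.23,0.28
PG3,INL,900,412,1.05,0.29,0.31
PG1,OPL,300,27,1.20,0.83,1.00
PG1,OPL,500,58,1.25,0.78,0.98
PG1,OPL,700,65,1.03,0.82,0.85
PG1,OPL,900,72,0.88,0.85,0.74
PG2,OPL,300,156,0.77,0.23,0.18
PG2,OPL,500,146,1.12,0.50,0.56
PG2,OPL,700,151,1.01,0.62,0.62
PG2,OPL,900,155,0.91,0.68,0.63
PG3,OPL,300,199,1.14,0.11,0.13
PG3,OPL,500,262,1.26,0.23,0.28
PG3,OPL,700,279,1.05,0.36,0.38
PG3,OPL,900,295,0.91,0.45,0.41
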