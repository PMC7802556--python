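system,compound,temperature_C,form,c0,k,window_start_h,window_end_h
glucose_only,glucose,90,zero_order,54103,-352.65,0,6
glucose_only,glucose,95,zero_order,53874,-368.05,0,6
glucose_only,glucose,100,first_order_exp,53693,-0.01,0,6
glucose_only,glucose,105,first_order_exp,54122,-0.016,0,6
glucose_only,glucose,110,first_order_exp,53920,-0.016,0,6
glucose_only,fructose,90,zero_order,291.39,23.284,1,6
glucose_only,fructose,95,zero_order,926.16,32.75,1,6
glucose_only,fructose,100,zero_order,445.57,-18.261,1,6
glucose_only,fructose,105,zero_order,359.44,-7.3494,1,6
glucose_only,fructose,110,zero_order,335.43,3.9297,1,6
glucose_only,1-deoxyglucosone,95,logarithmic,-3e-05,3e-05,3,6
glucose_only,1-deoxyglucosone,100,logarithmic,3e-05,7e-05,1,6
glucose_only,1-deoxyglucosone,105,logarithmic,0.0001,0.0002,1,6
glucose_only,1-deoxyglucosone,110,logarithmic,4e-05,0.0001,1,6
glucose_only,3-deoxyglucosone,90,zero_order,0.0049,0.0028,1,6
glucose_only,3-deoxyglucosone,95,zero_order,0.0063,0.0027,1,6
glucose_only,3-deoxyglucosone,100,zero_order,0.0119,0.0041,1,6
glucose_only,3-deoxyglucosone,105,zero_order,0.0173,0.0056,1,6
glucose_only,3-deoxyglucosone,110,zero_order,0.017,0.0054,1,6
glucose_only,"3,4-dideoxyglucosone",90,zero_order,0.0016,0.0005,1,6
glucose_only,"3,4-dideoxyglucosone",95,zero_order,0.0016,0.0006,1,6
glucose_only,"3,4-dideoxyglucosone",100,zero_order,0.0028,0.0010,1,6
glucose_only,"3,4-dideoxyglucosone",105,zero_order,0.0024,0.0018,1,6
glucose_only,"3,4-dideoxyglucosone",110,zero_order,0.0047,0.0015,1,6
glucose_only,glucosone,90,zero_order,0.0005,0.0003,1,6
glucose_only,glucosone,95,zero_order,0.0015,0.0004,1,6
glucose_only,glucosone,100,zero_order,0.0015,0.0002,1,6
glucose_only,glucosone,105,zero_order,0.0017,0.0005,3,6
glucose_only,glucosone,110,zero_order,0.0014,0.0001,3,6
glucose_only,glyoxal,90,zero_order,0.0003,5e-05,1,6
glucose_only,glyoxal,95,zero_order,0.0002,6e-05,1,6
glucose_only,glyoxal,100,zero_order,0.0002,4e-05,1,6
glucose_only,glyoxal,105,zero_order,0.0001,4e-05,1,6
glucose_only,glyoxal,110,zero_order,0.0002,1e-05,1,6
glucose_only,methylglyoxal,90,zero_order,1e-05,2e-05,1,6
glucose_only,methylglyoxal,95,zero_order,2e-05,2e-05,1,6
glucose_only,methylglyoxal,100,zero_order,2e-05,5e-05,1,6
glucose_only,methylglyoxal,105,zero_order,4e-05,0.0001,1,6
glucose_only,methylglyoxal,110,zero_order,4e-05,5e-05,1,6
glucose_only,diacetyl,90,zero_order,1e-06,1e-06,1,6
glucose_only,diacetyl,95,zero_order,4e-06,1e-06,1,6
glucose_only,diacetyl,100,zero_order,4e-06,2e-06,1,6
glucose_only,diacetyl,105,zero_order,8e-06,3e-06,1,6
glucose_only,diacetyl,110,zero_order,9e-06,6e-06,1,6
glucose_only,5-hydroxymethylfurfural,95,zero_order,-0.2876,0.1183,2,6
glucose_only,5-hydroxymethylfurfural,100,first_order_exp,0.0182,0.8451,2,6
glucose_only,5-hydroxymethylfurfural,105,first_order_exp,0.0334,0.8523,2,6
glucose_only,5-hydroxymethylfurfural,110,first_order_exp,0.0019,1.501,1,6
glucose_glu,glucose,90,zero_order,53960,-364.74,0,6
glucose_glu,glucose,95,zero_order,53366,-792.89,0,6
glucose_glu,glucose,100,first_order_exp,53139,-0.023,0,6
glucose_glu,glucose,105,first_order_exp,53617,-0.034,0,6
glucose_glu,glucose,110,first_order_exp,53195,-0.036,0,6
glucose_glu,fructose,90,zero_order,641.37,57.971,1,6
glucose_glu,fructose,95,zero_order,383.74,59.177,1,6
glucose_glu,fructose,100,zero_order,576.35,110.91,1,6
glucose_glu,fructose,105,zero_order,1318.8,-115.71,1,6
glucose_glu,fructose,110,zero_order,-4.1767,133.13,1,6
glucose_glu,1-deoxyglucosone,90,zero_order,2e-05,3e-06,2,6
glucose_glu,1-deoxyglucosone,95,zero_order,4e-05,9e-06,1,6
glucose_glu,1-deoxyglucosone,100,zero_order,0.0002,-5e-06,1,6
glucose_glu,1-deoxyglucosone,105,first_order_exp,0.0002,0.1323,1,6
glucose_glu,1-deoxyglucosone,110,first_order_exp,0.0002,0.2910,1,6
glucose_glu,3-deoxyglucosone,90,zero_order,0.0037,0.0013,1,6
glucose_glu,3-deoxyglucosone,95,zero_order,0.0061,0.0011,1,6
glucose_glu,3-deoxyglucosone,100,zero_order,0.0094,0.0018,1,6
glucose_glu,3-deoxyglucosone,105,zero_order,0.011,0.0029,1,6
glucose_glu,3-deoxyglucosone,110,zero_order,0.008,0.006,1,6
glucose_glu,"3,4-dideoxyglucosone",90,zero_order,0.0007,0.0002,1,6
glucose_glu,"3,4-dideoxyglucosone",95,zero_order,0.001,0.0002,1,6
glucose_glu,"3,4-dideoxyglucosone",100,zero_order,0.0014,0.0003,1,6
glucose_glu,"3,4-dideoxyglucosone",105,zero_order,0.0014,0.0006,1,6
glucose_glu,"3,4-dideoxyglucosone",110,first_order_exp,0.0017,0.2785,1,6
glucose_glu,glucosone,90,zero_order,0.0009,0.0004,1,6
glucose_glu,glucosone,95,zero_order,0.0016,0.0004,1,6
glucose_glu,glucosone,100,zero_order,0.001,0.0003,1,6
glucose_glu,glucosone,105,zero_order,0.0007,0.0003,1,6
glucose_glu,glucosone,110,zero_order,0.0008,0.0004,1,6
glucose_glu,glyoxal,90,zero_order,6e-05,0.0001,1,6
glucose_glu,glyoxal,95,first_order_exp,0.0002,0.569,1,4
glucose_glu,glyoxal,100,first_order_exp,0.0004,0.2617,1,4
glucose_glu,glyoxal,105,first_order_exp,0.0003,0.1225,1,4
glucose_glu,glyoxal,110,first_order_exp,0.0004,0.1671,1,6
glucose_glu,methylglyoxal,90,zero_order,-0.0001,0.0002,1,6
glucose_glu,methylglyoxal,95,zero_order,0.0001,0.0002,1,6
glucose_glu,methylglyoxal,100,zero_order,0.0001,0.0001,1,4
glucose_glu,methylglyoxal,105,zero_order,-0.0001,0.0001,1,6
glucose_glu,methylglyoxal,110,zero_order,-0.0002,0.0002,1,6
glucose_glu,diacetyl,90,first_order_exp,8e-06,0.3968,1,6
glucose_glu,diacetyl,95,first_order_exp,6e-06,0.8168,1,5
glucose_glu,diacetyl,100,zero_order,2e-05,3e-05,1,6
glucose_glu,diacetyl,105,zero_order,-4e-05,5e-05,1,6
glucose_glu,diacetyl,110,zero_order,-0.0001,0.0001,1,6
glucose_glu,5-hydroxymethylfurfural,90,first_order_exp,0.0030,0.5722,1,6
glucose_glu,5-hydroxymethylfurfural,95,first_order_exp,0.0055,0.5468,1,6
glucose_glu,5-hydroxymethylfurfural,100,first_order_exp,0.0113,0.5304,1,6
glucose_glu,5-hydroxymethylfurfural,105,first_order_exp,0.0144,0.5478,1,6
glucose_glu,5-hydroxymethylfurfural,110,zero_order,-0.0309,0.0637,1,6
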