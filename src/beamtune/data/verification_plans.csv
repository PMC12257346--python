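plan_id,target_volume_cm3,technique,n_arcs,mu,clin_aaa,opt_aaa,opt_acuros
1,14.1,DCAT,1,3267,89.67,93.99,95.58
2,21.0,DCAT,1,3074,90.89,91.07,95.93
3,8.2,DCAT,1,3061,95.65,95.71,95.27
4,12.8,DCAT,1,3085,93.70,95.71,96.35
5,13.8,DCAT,1,3012,95.70,97.36,95.36
6,18.6,DCAT,1,3356,82.90,85.33,88.88
7,5.0,DCAT,1,3954,85.55,89.15,94.12
8,23.8,DCAT,1,2813,94.57,93.96,94.63
9,38.0,DCAT,1,3025,94.55,97.37,97.28
10,30.9,DCAT,1,3586,92.30,92.30,94.82
11,22.2,DCAT,1,2939,91.80,95.05,97.38
12,15.8,VMAT,2,4632,97.93,97.45,98.82
13,65.3,VMAT,2,3149,95.80,96.89,98.42
14,33.4,VMAT,2,2123,91.81,93.86,94.82
15,31.1,VMAT,2,4993,98.14,96.92,95.38
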