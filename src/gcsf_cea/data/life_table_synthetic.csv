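age,qx
56,0.004035045564628365
57,0.004437173585980887
58,0.004879377225555527
59,0.005365650373582772
60,0.005900384946820977
61,0.006488410555424448
62,0.007135038122966171
63,0.007846107853582078
64,0.00862804197946599
65,0.009487902765119528
66,0.010433456292239124
67,0.011473242601331911
68,0.012616652823564684
69,0.013874013999484654
70,0.015256682350676818
71,0.01677714584676789
72,0.018449136994140428
73,0.0202877568650411
74,0.022309611487287828
75,0.02453296182641909
76,0.026977888714892397
77,0.029666474217937996
78,0.03262300107412574
79,0.03587417201195074
80,0.039449350923258644
81,0.043380828071738466
82,0.04770411173179024
83,0.052458248891788135
84,0.05768617791826391
85,0.06343511636619875
86,0.06975698743804525
87,0.07670888894316677
88,0.08435360899323817
89,0.09276019309125924
90,0.10200456773601035
91,0.11217022617421417
92,0.12334898249397236
93,0.1356418008702914
94,0.14915970745226742
95,0.16402479312790488
96,0.1803713162233277
97,0.19834691509573288
98,0.21811394157196798
99,0.23985092727607193
100,0.2637541960893394
101,0.29003963730630883
102,0.3189446555014456
103,0.35073031471730887
104,0.3856836963400539
105,0.42412049195810714
106,0.4663878546221715
107,0.5128675342585364
108,0.5639793255540898
109,0.6201848594536019
110,1.0
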