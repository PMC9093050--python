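label,x,y,z
Fp1,-0.26911357,0.90010273,-0.34262655
Fp2,0.25720870,0.90396656,-0.34159646
AF7,-0.50310576,0.77586173,-0.38068776
AF8,0.49417963,0.78177335,-0.38028531
AF3,-0.34256440,0.93392383,-0.10215630
AF4,0.34341876,0.93445787,-0.09408534
F7,-0.69486750,0.58388687,-0.41980386
F8,0.69141300,0.59028203,-0.41655154
F5,-0.69839324,0.69846612,-0.15617929
F6,0.69840836,0.69811149,-0.15768994
F3,-0.58291921,0.80333834,0.12187169
F4,0.57740432,0.80965411,0.10518780
F1,-0.33511101,0.87820748,0.34125100
F2,0.33802045,0.88139542,0.32997620
FT7,-0.83884133,0.32251155,-0.43855618
FT8,0.83264560,0.33574140,-0.44043049
FC5,-0.90544309,0.41648986,-0.08190850
FC6,0.90124346,0.42566457,-0.08105496
FC3,-0.79442907,0.52052802,0.31294254
FC4,0.79111114,0.52715350,0.31024564
FC1,-0.47294366,0.58668635,0.65736095
FC2,0.46672581,0.60011313,0.64963932
T7,-0.90112181,0.01302250,-0.43337040
T8,0.89893210,0.02374889,-0.43744379
C5,-0.99865528,0.04294339,-0.02904303
C6,0.99815158,0.05398991,-0.02790175
C3,-0.89316779,0.07579389,0.44329064
C4,0.89695833,0.08584722,0.43370036
C1,-0.53299482,0.10471421,0.83961387
C2,0.54035629,0.11173607,0.83398449
TP9,-0.72299821,-0.24483526,-0.64601028
TP10,0.71724269,-0.25032312,-0.65030859
TP7,-0.87178268,-0.29292074,-0.39267340
TP8,0.87054201,-0.29071658,-0.39703965
CP5,-0.93952042,-0.34242829,-0.00665194
CP6,0.94394043,-0.33009650,-0.00357218
CP3,-0.81797694,-0.37822661,0.43342629
CP4,0.82550466,-0.36871020,0.42731118
CP1,-0.47703202,-0.39459222,0.78532633
CP2,0.49323471,-0.39152766,0.77680475
P7,-0.74444013,-0.57127210,-0.34562562
P8,0.74140538,-0.57285200,-0.34951201
P5,-0.75501243,-0.65478741,-0.03478047
P6,0.75222023,-0.65778994,-0.03843340
P3,-0.63074216,-0.72127518,0.28622795
P4,0.63788404,-0.71295690,0.29119822
P1,-0.35691271,-0.76741747,0.53261970
P2,0.37157347,-0.75532619,0.53982914
PO7,-0.54655385,-0.78846794,-0.28212975
PO8,0.54055675,-0.79203938,-0.28367590
PO3,-0.40684549,-0.91141911,0.06157882
PO4,0.39467634,-0.91725969,0.05352805
O1,-0.29506663,-0.92946719,-0.22141913
O2,0.28514963,-0.93215025,-0.22312686
Fz,-0.00595862,0.90804258,0.41883549
Cz,-0.00590218,0.11675743,0.99314292
Pz,-0.00592502,-0.78084281,0.62469945
POz,-0.00682041,-0.97563577,0.21929049
Oz,-0.00708156,-0.98539170,-0.17015597
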