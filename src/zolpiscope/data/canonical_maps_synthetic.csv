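label,A,B,C,D
Fp1,0.16856319,0.09117639,-0.20979306,-0.05797902
Fp2,0.09346548,0.16712204,-0.21045248,-0.05781605
AF7,0.18433873,0.03986185,-0.18902052,-0.06279663
AF8,0.04183955,0.18356319,-0.19013184,-0.06266766
AF3,0.18398236,0.08549969,-0.19536649,-0.03157503
AF4,0.08545652,0.18383874,-0.19476571,-0.03026898
F7,0.18430809,-0.01510588,-0.15520439,-0.06734098
F8,-0.01403538,0.18438570,-0.15616078,-0.06714855
F5,0.20128440,0.00080180,-0.15441862,-0.04907506
F6,0.00045842,0.20083360,-0.15448168,-0.04923244
F3,0.19976050,0.03236494,-0.15049140,0.00580332
F4,0.03388447,0.19947831,-0.15317220,0.00184345
F1,0.17490240,0.07858634,-0.14586586,0.11565760
F2,0.07860532,0.17546462,-0.14746803,0.10913804
FT7,0.16743291,-0.07316947,-0.10615230,-0.07058429
FT8,-0.07092347,0.16815507,-0.10888154,-0.07051442
FC5,0.19051454,-0.06924796,-0.09325339,-0.05187738
FC6,-0.06785819,0.19086216,-0.09495815,-0.05150523
FC3,0.18951184,-0.03844315,-0.07897143,0.03400494
FC4,-0.03743994,0.18962406,-0.08049167,0.03391777
FC1,0.15281135,0.01708425,-0.06174462,0.31409940
FC2,0.01967406,0.15360899,-0.06502233,0.31048545
T7,0.13189937,-0.12642299,-0.04568045,-0.07267470
T8,-0.12529696,0.13295931,-0.04811611,-0.07267595
C5,0.15021955,-0.13610805,-0.01619793,-0.05834181
C6,-0.13521186,0.15150367,-0.01824059,-0.05799986
C3,0.13977877,-0.11629205,0.01865127,0.02141170
C4,-0.11608729,0.14157176,0.01586469,0.01946491
C1,0.09216481,-0.06055700,0.04762932,0.31784520
C2,-0.06110839,0.09419928,0.04577630,0.31380656
TP9,0.06923180,-0.13784438,-0.01423082,-0.07566401
TP10,-0.13857595,0.06767450,-0.01354167,-0.07569831
TP7,0.08370618,-0.16604470,0.01720277,-0.07368914
TP8,-0.16641717,0.08384752,0.01639428,-0.07373213
CP5,0.08632658,-0.18283932,0.06049133,-0.06474148
CP6,-0.18262783,0.08872045,0.05836859,-0.06440966
CP3,0.06371041,-0.17055689,0.10583873,-0.02363483
CP4,-0.17115428,0.06622415,0.10345955,-0.02410283
CP1,0.01235091,-0.12406305,0.13972234,0.09700399
CP2,-0.12667386,0.01536022,0.13838437,0.09267546
P7,0.02539211,-0.18767572,0.07528931,-0.07431701
P8,-0.18840908,0.02493552,0.07525654,-0.07436168
P5,0.01490734,-0.20115315,0.11861248,-0.06961104
P6,-0.20217250,0.01431788,0.11887597,-0.06973453
P3,-0.01251204,-0.19287618,0.15952043,-0.05625286
P4,-0.19366757,-0.00996233,0.15834101,-0.05566707
P1,-0.05850449,-0.16026150,0.18997108,-0.03137249
P2,-0.16147845,-0.05417868,0.18825537,-0.02950370
PO7,-0.03427142,-0.19044168,0.12295135,-0.07448670
PO8,-0.19104508,-0.03523186,0.12350903,-0.07451384
PO3,-0.07202587,-0.18804133,0.17679027,-0.06959000
PO4,-0.18807541,-0.07406525,0.17722036,-0.06985297
O1,-0.09068707,-0.17461501,0.15559350,-0.07440776
O2,-0.17447250,-0.09188720,0.15596480,-0.07443403
Fz,0.13187880,0.13000892,-0.14488110,0.18374102
Cz,0.01813207,0.01667064,0.05869204,0.59971836
Pz,-0.11088489,-0.11190793,0.20061033,-0.01551602
POz,-0.13875556,-0.13993899,0.20300710,-0.06515402
Oz,-0.14012033,-0.14137387,0.17091262,-0.07409505
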