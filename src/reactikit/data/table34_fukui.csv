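molecule,medium,atom,index,value
Neu5Gc,Gas,O2,f-,0.1237
Neu5Gc,Gas,O3,f-,0.02612
Neu5Gc,Gas,O4,f-,0.01854
Neu5Gc,Gas,O5,f-,-0.003166
Neu5Gc,Gas,O6,f-,0.01067
Neu5Gc,Gas,O7,f-,0.009959
Neu5Gc,Gas,O10,f-,0.05184
Neu5Gc,Benzene,O2,f-,0.08462
Neu5Gc,Benzene,O3,f-,0.01581
Neu5Gc,Benzene,O4,f-,0.01468
Neu5Gc,Benzene,O5,f-,0.001390
Neu5Gc,Benzene,O6,f-,0.008207
Neu5Gc,Benzene,O7,f-,0.007863
Neu5Gc,Benzene,O10,f-,0.04109
Neu5Gc,Acetic acid,O2,f-,0.06119
Neu5Gc,Acetic acid,O3,f-,0.01006
Neu5Gc,Acetic acid,O4,f-,0.008661
Neu5Gc,Acetic acid,O5,f-,0.002425
Neu5Gc,Acetic acid,O6,f-,0.005481
Neu5Gc,Acetic acid,O7,f-,0.004638
Neu5Gc,Acetic acid,O10,f-,0.03003
Neu5Gc,Ethanol,O2,f-,0.03166
Neu5Gc,Ethanol,O3,f-,0.01348
Neu5Gc,Ethanol,O4,f-,0.008483
Neu5Gc,Ethanol,O5,f-,0.004389
Neu5Gc,Ethanol,O6,f-,0.004433
Neu5Gc,Ethanol,O7,f-,0.003873
Neu5Gc,Ethanol,O10,f-,0.02739
Neu5Gc,Formic acid,O2,f-,0.02883
Neu5Gc,Formic acid,O3,f-,0.01327
Neu5Gc,Formic acid,O4,f-,0.008223
Neu5Gc,Formic acid,O5,f-,0.004598
Neu5Gc,Formic acid,O6,f-,0.003941
Neu5Gc,Formic acid,O7,f-,0.003317
Neu5Gc,Formic acid,O10,f-,0.02415
Neu5Gc,Lactic acid,O2,f-,0.05031
Neu5Gc,Lactic acid,O3,f-,0.009583
Neu5Gc,Lactic acid,O4,f-,0.007909
Neu5Gc,Lactic acid,O5,f-,0.002491
Neu5Gc,Lactic acid,O6,f-,0.004599
Neu5Gc,Lactic acid,O7,f-,0.003322
Neu5Gc,Lactic acid,O10,f-,0.03325
Neu5Gc,Water,O2,f-,0.03077
Neu5Gc,Water,O3,f-,0.01305
Neu5Gc,Water,O4,f-,0.008335
Neu5Gc,Water,O5,f-,0.004534
Neu5Gc,Water,O6,f-,0.003866
Neu5Gc,Water,O7,f-,0.003205
Neu5Gc,Water,O10,f-,0.02450
Neu5Gc,Gas,O2,f+,0.02046
Neu5Gc,Gas,O3,f+,0.01737
Neu5Gc,Gas,O4,f+,0.04551
Neu5Gc,Gas,O5,f+,0.001062
Neu5Gc,Gas,O6,f+,0.0694
Neu5Gc,Gas,O7,f+,0.01091
Neu5Gc,Gas,O10,f+,0.01983
Neu5Gc,Benzene,O2,f+,0.01696
Neu5Gc,Benzene,O3,f+,0.01141
Neu5Gc,Benzene,O4,f+,0.05685
Neu5Gc,Benzene,O5,f+,0.002364
Neu5Gc,Benzene,O6,f+,0.09615
Neu5Gc,Benzene,O7,f+,0.003067
Neu5Gc,Benzene,O10,f+,0.007161
Neu5Gc,Acetic acid,O2,f+,0.01556
Neu5Gc,Acetic acid,O3,f+,0.006019
Neu5Gc,Acetic acid,O4,f+,0.04722
Neu5Gc,Acetic acid,O5,f+,0.001904
Neu5Gc,Acetic acid,O6,f+,0.1224
Neu5Gc,Acetic acid,O7,f+,0.001077
Neu5Gc,Acetic acid,O10,f+,0.002703
Neu5Gc,Ethanol,O2,f+,0.01396
Neu5Gc,Ethanol,O3,f+,0.004336
Neu5Gc,Ethanol,O4,f+,0.04283
Neu5Gc,Ethanol,O5,f+,0.001304
Neu5Gc,Ethanol,O6,f+,0.1240
Neu5Gc,Ethanol,O7,f+,0.0006920
Neu5Gc,Ethanol,O10,f+,0.001186
Neu5Gc,Formic acid,O2,f+,0.01279
Neu5Gc,Formic acid,O3,f+,0.003578
Neu5Gc,Formic acid,O4,f+,0.04548
Neu5Gc,Formic acid,O5,f+,0.001167
Neu5Gc,Formic acid,O6,f+,0.1269
Neu5Gc,Formic acid,O7,f+,0.0005470
Neu5Gc,Formic acid,O10,f+,0.0008410
Neu5Gc,Lactic acid,O2,f+,0.01419
Neu5Gc,Lactic acid,O3,f+,0.007517
Neu5Gc,Lactic acid,O4,f+,0.04970
Neu5Gc,Lactic acid,O5,f+,0.001725
Neu5Gc,Lactic acid,O6,f+,0.1086
Neu5Gc,Lactic acid,O7,f+,0.001256
Neu5Gc,Lactic acid,O10,f+,0.001962
Neu5Gc,Water,O2,f+,0.01274
Neu5Gc,Water,O3,f+,0.003522
Neu5Gc,Water,O4,f+,0.04491
Neu5Gc,Water,O5,f+,0.001134
Neu5Gc,Water,O6,f+,0.1270
Neu5Gc,Water,O7,f+,0.0005410
Neu5Gc,Water,O10,f+,0.0007780
Neu5Ac,Gas,O2,f-,0.1140
Neu5Ac,Gas,O3,f-,0.02236
Neu5Ac,Gas,O4,f-,0.01776
Neu5Ac,Gas,O5,f-,0.0001650
Neu5Ac,Gas,O6,f-,0.01092
Neu5Ac,Gas,O7,f-,0.01185
Neu5Ac,Benzene,O2,f-,0.06632
Neu5Ac,Benzene,O3,f-,0.01300
Neu5Ac,Benzene,O4,f-,0.009534
Neu5Ac,Benzene,O5,f-,0.0005200
Neu5Ac,Benzene,O6,f-,0.007312
Neu5Ac,Benzene,O7,f-,0.007243
Neu5Ac,Acetic acid,O2,f-,0.05073
Neu5Ac,Acetic acid,O3,f-,0.009047
Neu5Ac,Acetic acid,O4,f-,0.008116
Neu5Ac,Acetic acid,O5,f-,0.001855
Neu5Ac,Acetic acid,O6,f-,0.005053
Neu5Ac,Acetic acid,O7,f-,0.004259
Neu5Ac,Ethanol,O2,f-,0.02826
Neu5Ac,Ethanol,O3,f-,0.01184
Neu5Ac,Ethanol,O4,f-,0.007726
Neu5Ac,Ethanol,O5,f-,0.003867
Neu5Ac,Ethanol,O6,f-,0.004107
Neu5Ac,Ethanol,O7,f-,0.003490
Neu5Ac,Formic acid,O2,f-,0.05069
Neu5Ac,Formic acid,O3,f-,0.008504
Neu5Ac,Formic acid,O4,f-,0.007130
Neu5Ac,Formic acid,O5,f-,0.003015
Neu5Ac,Formic acid,O6,f-,0.003647
Neu5Ac,Formic acid,O7,f-,0.002429
Neu5Ac,Lactic acid,O2,f-,0.05070
Neu5Ac,Lactic acid,O3,f-,0.009064
Neu5Ac,Lactic acid,O4,f-,0.007035
Neu5Ac,Lactic acid,O5,f-,0.002215
Neu5Ac,Lactic acid,O6,f-,0.004367
Neu5Ac,Lactic acid,O7,f-,0.003040
Neu5Ac,Water,O2,f-,0.04718
Neu5Ac,Water,O3,f-,0.008686
Neu5Ac,Water,O4,f-,0.007317
Neu5Ac,Water,O5,f-,0.003156
Neu5Ac,Water,O6,f-,0.003574
Neu5Ac,Water,O7,f-,0.002371
Neu5Ac,Gas,O2,f+,0.02053
Neu5Ac,Gas,O3,f+,0.01515
Neu5Ac,Gas,O4,f+,0.05226
Neu5Ac,Gas,O5,f+,0.001968
Neu5Ac,Gas,O6,f+,0.08011
Neu5Ac,Gas,O7,f+,0.006588
Neu5Ac,Benzene,O2,f+,0.01705
Neu5Ac,Benzene,O3,f+,0.01137
Neu5Ac,Benzene,O4,f+,0.05745
Neu5Ac,Benzene,O5,f+,0.002491
Neu5Ac,Benzene,O6,f+,0.09739
Neu5Ac,Benzene,O7,f+,0.003006
Neu5Ac,Acetic acid,O2,f+,0.01432
Neu5Ac,Acetic acid,O3,f+,0.006090
Neu5Ac,Acetic acid,O4,f+,0.04783
Neu5Ac,Acetic acid,O5,f+,0.002124
Neu5Ac,Acetic acid,O6,f+,0.1225
Neu5Ac,Acetic acid,O7,f+,0.001194
Neu5Ac,Ethanol,O2,f+,0.01363
Neu5Ac,Ethanol,O3,f+,0.004200
Neu5Ac,Ethanol,O4,f+,0.04485
Neu5Ac,Ethanol,O5,f+,0.001290
Neu5Ac,Ethanol,O6,f+,0.1236
Neu5Ac,Ethanol,O7,f+,0.0006360
Neu5Ac,Formic acid,O2,f+,0.01236
Neu5Ac,Formic acid,O3,f+,0.003406
Neu5Ac,Formic acid,O4,f+,0.04676
Neu5Ac,Formic acid,O5,f+,0.001115
Neu5Ac,Formic acid,O6,f+,0.1266
Neu5Ac,Formic acid,O7,f+,0.0005200
Neu5Ac,Lactic acid,O2,f+,0.01399
Neu5Ac,Lactic acid,O3,f+,0.007559
Neu5Ac,Lactic acid,O4,f+,0.05077
Neu5Ac,Lactic acid,O5,f+,0.001706
Neu5Ac,Lactic acid,O6,f+,0.1076
Neu5Ac,Lactic acid,O7,f+,0.001251
Neu5Ac,Water,O2,f+,0.01237
Neu5Ac,Water,O3,f+,0.003225
Neu5Ac,Water,O4,f+,0.04587
Neu5Ac,Water,O5,f+,0.001147
Neu5Ac,Water,O6,f+,0.1267
Neu5Ac,Water,O7,f+,0.0005170
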