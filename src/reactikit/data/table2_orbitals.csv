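molecule,medium,HOMO,LUMO,Egap,eta,s,chi,mu,omega
Neu5Gc,Gas,-8.900,0.753,9.653,4.826,0.1036,4.074,-4.074,1.719
Neu5Gc,Benzene,-8.867,0.955,9.822,4.911,0.1018,3.955,-3.955,1.593
Neu5Gc,Ethanol,-8.660,1.039,9.699,4.849,0.1030,3.810,-3.810,1.496
Neu5Gc,Acetic acid,-8.728,0.995,9.723,4.861,0.1028,3.866,-3.866,1.537
Neu5Gc,Lactic acid,-8.715,1.125,9.840,4.920,0.1016,3.795,-3.795,1.463
Neu5Gc,Formic acid,-8.720,1.013,9.733,4.866,0.1027,3.853,-3.853,1.525
Neu5Gc,Water,-8.731,0.988,9.720,4.860,0.1028,3.871,-3.871,1.542
Neu5Ac,Gas,-8.766,0.878,9.644,4.822,0.1036,3.944,-3.944,1.613
Neu5Ac,Benzene,-8.674,1.027,9.702,4.851,0.1030,3.823,-3.823,1.506
Neu5Ac,Ethanol,-8.594,1.068,9.662,4.831,0.1034,3.762,-3.762,1.465
Neu5Ac,Acetic acid,-8.701,1.021,9.722,4.860,0.1028,3.840,-3.840,1.516
Neu5Ac,Lactic acid,-8.578,1.141,9.719,4.859,0.1029,3.719,-3.718,1.423
Neu5Ac,Formic acid,-8.548,1.030,9.578,4.789,0.1043,3.759,-3.759,1.475
Neu5Ac,Water,-8.718,1.007,9.726,4.863,0.1028,3.855,-3.855,1.528
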