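molecule,medium,IP
Neu5Ac,Gas,198.37
Neu5Ac,Benzene,168.58
Neu5Ac,Acetic acid,135.72
Neu5Ac,Ethanol,138.41
Neu5Ac,Formic acid,132.06
Neu5Ac,Lactic acid,136.56
Neu5Ac,Water,131.63
Neu5Gc,Gas,200.81
Neu5Gc,Benzene,172.75
Neu5Gc,Acetic acid,137.51
Neu5Gc,Ethanol,139.97
Neu5Gc,Formic acid,134.57
Neu5Gc,Lactic acid,139.84
Neu5Gc,Water,133.99
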