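molecule,medium,bond,rho_printed,lap_printed,V_printed,G_printed,H_printed,EHB_printed,length_printed,angle_printed,rho,lap,V,G,flag
Neu5Gc,Gas,O2-H31...O9,0.02953,0.1126,-0.02557,0.02687,0.001301,-33.56,2.794,4.804,0.02953,0.1126,-0.02557,0.02687,
Neu5Gc,Gas,O3-H34...O1,0.02885,0.1327,-0.02784,0.03050,0.002673,-36.55,2.524,6.080,0.02885,0.1327,-0.02784,0.03050,h_print_anomaly
Neu5Gc,Gas,O10-H41...O9,0.02385,0.1051,-0.02086,0.02357,0.002710,-27.39,2.646,13.65,0.02385,0.1051,-0.02086,0.02357,
Neu5Gc,Gas,N11-H30...O5,0.02255,0.09263,-0.01774,0.02045,0.002705,-23.29,2.921,2.811,0.02255,0.09263,-0.01774,0.02045,
Neu5Gc,Acetic acid,O10-H41...O9,0.2266,0.1019,-0.01975,0.2262,0.002869,-25.94,2.653,4.951,0.02266,0.1019,-0.01975,0.02262,decimal_typo_rho_G
Neu5Gc,Benzene,O10-H41...O9,0.02319,0.1038,-0.02031,0.02313,0.002817,-26.67,2.652,5.516,0.02319,0.1038,-0.02031,0.02313,
Neu5Ac,Gas,O3-H33...O1,0.02262,0.1058,-0.02053,0.02349,0.002964,-26.95,2.586,8.897,0.02262,0.1058,-0.02053,0.02349,
Neu5Ac,Gas,O2-H30...O9,0.02907,0.1101,-0.02485,0.02619,0.001343,-32.62,2.800,4.906,0.02907,0.1101,-0.02485,0.02619,
Neu5Ac,Acetic acid,O2-H30...O9,0.02361,0.08990,-0.01891,0.02069,0.001782,-24.82,2.850,5.233,0.02361,0.08990,-0.01891,0.02069,
Neu5Ac,Benzene,O3-H33...O1,0.02027,0.09740,-0.01829,0.02132,0.003026,-24.02,2.625,11.40,0.02027,0.09740,-0.01829,0.02132,
Neu5Ac,Benzene,O2-H30...O9,0.02818,0.1064,-0.02373,0.02518,0.001443,-31.16,2.816,4.511,0.02818,0.1064,-0.02373,0.02518,
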