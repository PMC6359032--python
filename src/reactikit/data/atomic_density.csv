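# Spherical free-atom density shells: rho_el(r) = sum_k c_k exp(-alpha_k r).
# Exponents from Slater-rule screened charges (alpha = 2(Z-s)/n); each
# shell coefficient normalises the pure exponential to the shell's
# electron count: c = N_e alpha^3 / (8 pi). Edit freely; the loader
# accepts any positive (coefficient, exponent) list per element.
element,coefficient,exponent
H,0.31830989,2.00000000
He,3.12771294,3.40000000
Li,12.53058698,5.40000000
Li,0.08741585,1.30000000
Be,32.24670133,7.40000000
Be,0.59005700,1.95000000
B,66.09577463,9.40000000
B,2.09798046,2.60000000
C,117.89752550,11.40000000
C,5.46349078,3.25000000
N,191.47167260,13.40000000
N,11.80114009,3.90000000
O,290.63793454,15.40000000
O,22.48772805,4.55000000
F,419.21602996,17.40000000
F,39.16230192,5.20000000
Ne,581.02567751,19.40000000
Ne,63.72615647,5.85000000
Na,779.88659580,21.40000000
Na,102.31088510,6.85000000
Na,0.12553199,1.46666667
Mg,1019.61850348,23.40000000
Mg,153.97815005,7.85000000
Mg,0.54582188,1.90000000
Al,1304.04111918,25.40000000
Al,220.63781064,8.85000000
Al,1.51639293,2.33333333
Si,1636.97416154,27.40000000
Si,304.19972618,9.85000000
Si,3.37047139,2.76666667
P,2022.23734918,29.40000000
P,406.57375600,10.85000000
P,6.51898647,3.20000000
S,2463.65040075,31.40000000
S,529.66975941,11.85000000
S,11.45057038,3.63333333
Cl,2965.03303487,33.40000000
Cl,675.39759573,12.85000000
Cl,18.73155829,4.06666667
Ar,3530.20497019,35.40000000
Ar,845.66712427,13.85000000
Ar,29.00598838,4.50000000
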