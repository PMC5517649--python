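# Coarse residue-contact energy matrix (coarse energy units, lower = more favourable).
# Constructed from the Kyte-Doolittle hydropathy scale (J Mol Biol 157:105-132, 1982)
# via the one-body dominance approximation for knowledge-based contact potentials
# (contact energies are well approximated by additive per-residue terms):
#   e(a, b) = -0.1 * (KD(a) + KD(b))
# Hydrophobic-hydrophobic contacts are favourable (negative); charged/polar pairs
# are penalised. This is a documented stand-in for an all-atom design score and
# carries no claim of equivalence to any statistical potential fitted to structures.
aa	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	-0.360	0.270	0.170	0.170	-0.430	0.170	0.170	-0.140	0.140	-0.630	-0.560	0.210	-0.370	-0.460	-0.020	-0.100	-0.110	-0.090	-0.050	-0.600
R	0.270	0.900	0.800	0.800	0.200	0.800	0.800	0.490	0.770	-0.000	0.070	0.840	0.260	0.170	0.610	0.530	0.520	0.540	0.580	0.030
N	0.170	0.800	0.700	0.700	0.100	0.700	0.700	0.390	0.670	-0.100	-0.030	0.740	0.160	0.070	0.510	0.430	0.420	0.440	0.480	-0.070
D	0.170	0.800	0.700	0.700	0.100	0.700	0.700	0.390	0.670	-0.100	-0.030	0.740	0.160	0.070	0.510	0.430	0.420	0.440	0.480	-0.070
C	-0.430	0.200	0.100	0.100	-0.500	0.100	0.100	-0.210	0.070	-0.700	-0.630	0.140	-0.440	-0.530	-0.090	-0.170	-0.180	-0.160	-0.120	-0.670
Q	0.170	0.800	0.700	0.700	0.100	0.700	0.700	0.390	0.670	-0.100	-0.030	0.740	0.160	0.070	0.510	0.430	0.420	0.440	0.480	-0.070
E	0.170	0.800	0.700	0.700	0.100	0.700	0.700	0.390	0.670	-0.100	-0.030	0.740	0.160	0.070	0.510	0.430	0.420	0.440	0.480	-0.070
G	-0.140	0.490	0.390	0.390	-0.210	0.390	0.390	0.080	0.360	-0.410	-0.340	0.430	-0.150	-0.240	0.200	0.120	0.110	0.130	0.170	-0.380
H	0.140	0.770	0.670	0.670	0.070	0.670	0.670	0.360	0.640	-0.130	-0.060	0.710	0.130	0.040	0.480	0.400	0.390	0.410	0.450	-0.100
I	-0.630	-0.000	-0.100	-0.100	-0.700	-0.100	-0.100	-0.410	-0.130	-0.900	-0.830	-0.060	-0.640	-0.730	-0.290	-0.370	-0.380	-0.360	-0.320	-0.870
L	-0.560	0.070	-0.030	-0.030	-0.630	-0.030	-0.030	-0.340	-0.060	-0.830	-0.760	0.010	-0.570	-0.660	-0.220	-0.300	-0.310	-0.290	-0.250	-0.800
K	0.210	0.840	0.740	0.740	0.140	0.740	0.740	0.430	0.710	-0.060	0.010	0.780	0.200	0.110	0.550	0.470	0.460	0.480	0.520	-0.030
M	-0.370	0.260	0.160	0.160	-0.440	0.160	0.160	-0.150	0.130	-0.640	-0.570	0.200	-0.380	-0.470	-0.030	-0.110	-0.120	-0.100	-0.060	-0.610
F	-0.460	0.170	0.070	0.070	-0.530	0.070	0.070	-0.240	0.040	-0.730	-0.660	0.110	-0.470	-0.560	-0.120	-0.200	-0.210	-0.190	-0.150	-0.700
P	-0.020	0.610	0.510	0.510	-0.090	0.510	0.510	0.200	0.480	-0.290	-0.220	0.550	-0.030	-0.120	0.320	0.240	0.230	0.250	0.290	-0.260
S	-0.100	0.530	0.430	0.430	-0.170	0.430	0.430	0.120	0.400	-0.370	-0.300	0.470	-0.110	-0.200	0.240	0.160	0.150	0.170	0.210	-0.340
T	-0.110	0.520	0.420	0.420	-0.180	0.420	0.420	0.110	0.390	-0.380	-0.310	0.460	-0.120	-0.210	0.230	0.150	0.140	0.160	0.200	-0.350
W	-0.090	0.540	0.440	0.440	-0.160	0.440	0.440	0.130	0.410	-0.360	-0.290	0.480	-0.100	-0.190	0.250	0.170	0.160	0.180	0.220	-0.330
Y	-0.050	0.580	0.480	0.480	-0.120	0.480	0.480	0.170	0.450	-0.320	-0.250	0.520	-0.060	-0.150	0.290	0.210	0.200	0.220	0.260	-0.290
V	-0.600	0.030	-0.070	-0.070	-0.670	-0.070	-0.070	-0.380	-0.100	-0.870	-0.800	-0.030	-0.610	-0.700	-0.260	-0.340	-0.350	-0.330	-0.290	-0.840
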