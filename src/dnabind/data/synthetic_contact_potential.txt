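# Synthetic pairwise contact potential for protein folding (stand-in).
# M(a,b) = -0.05 * h(a) * h(b) with h = Kyte-Doolittle hydropathy:
# favourable (negative) contacts between hydrophobic pairs, unfavourable
# between hydrophobic/hydrophilic pairs. Symmetric 20x20, kcal/mol-like units.
        A       C       D       E       F       G       H       I       K       L       M       N       P       Q       R       S       T       V       W       Y
A  -0.162  -0.225   0.315   0.315  -0.252   0.036   0.288  -0.405   0.351  -0.342  -0.171   0.315   0.144   0.315   0.405   0.072   0.063  -0.378   0.081   0.117
C  -0.225  -0.312   0.438   0.438  -0.350   0.050   0.400  -0.562   0.487  -0.475  -0.237   0.438   0.200   0.438   0.562   0.100   0.087  -0.525   0.113   0.163
D   0.315   0.438  -0.613  -0.613   0.490  -0.070  -0.560   0.788  -0.682   0.665   0.333  -0.613  -0.280  -0.613  -0.788  -0.140  -0.122   0.735  -0.158  -0.228
E   0.315   0.438  -0.613  -0.613   0.490  -0.070  -0.560   0.788  -0.682   0.665   0.333  -0.613  -0.280  -0.613  -0.788  -0.140  -0.122   0.735  -0.158  -0.228
F  -0.252  -0.350   0.490   0.490  -0.392   0.056   0.448  -0.630   0.546  -0.532  -0.266   0.490   0.224   0.490   0.630   0.112   0.098  -0.588   0.126   0.182
G   0.036   0.050  -0.070  -0.070   0.056  -0.008  -0.064   0.090  -0.078   0.076   0.038  -0.070  -0.032  -0.070  -0.090  -0.016  -0.014   0.084  -0.018  -0.026
H   0.288   0.400  -0.560  -0.560   0.448  -0.064  -0.512   0.720  -0.624   0.608   0.304  -0.560  -0.256  -0.560  -0.720  -0.128  -0.112   0.672  -0.144  -0.208
I  -0.405  -0.562   0.788   0.788  -0.630   0.090   0.720  -1.012   0.877  -0.855  -0.427   0.787   0.360   0.787   1.012   0.180   0.158  -0.945   0.203   0.293
K   0.351   0.487  -0.682  -0.682   0.546  -0.078  -0.624   0.877  -0.760   0.741   0.370  -0.682  -0.312  -0.682  -0.878  -0.156  -0.136   0.819  -0.176  -0.254
L  -0.342  -0.475   0.665   0.665  -0.532   0.076   0.608  -0.855   0.741  -0.722  -0.361   0.665   0.304   0.665   0.855   0.152   0.133  -0.798   0.171   0.247
M  -0.171  -0.237   0.333   0.333  -0.266   0.038   0.304  -0.427   0.370  -0.361  -0.180   0.333   0.152   0.333   0.427   0.076   0.066  -0.399   0.086   0.124
N   0.315   0.438  -0.613  -0.613   0.490  -0.070  -0.560   0.787  -0.682   0.665   0.333  -0.613  -0.280  -0.613  -0.788  -0.140  -0.122   0.735  -0.158  -0.228
P   0.144   0.200  -0.280  -0.280   0.224  -0.032  -0.256   0.360  -0.312   0.304   0.152  -0.280  -0.128  -0.280  -0.360  -0.064  -0.056   0.336  -0.072  -0.104
Q   0.315   0.438  -0.613  -0.613   0.490  -0.070  -0.560   0.787  -0.682   0.665   0.333  -0.613  -0.280  -0.613  -0.788  -0.140  -0.122   0.735  -0.158  -0.228
R   0.405   0.562  -0.788  -0.788   0.630  -0.090  -0.720   1.012  -0.878   0.855   0.427  -0.788  -0.360  -0.788  -1.012  -0.180  -0.158   0.945  -0.203  -0.293
S   0.072   0.100  -0.140  -0.140   0.112  -0.016  -0.128   0.180  -0.156   0.152   0.076  -0.140  -0.064  -0.140  -0.180  -0.032  -0.028   0.168  -0.036  -0.052
T   0.063   0.087  -0.122  -0.122   0.098  -0.014  -0.112   0.158  -0.136   0.133   0.066  -0.122  -0.056  -0.122  -0.158  -0.028  -0.024   0.147  -0.032  -0.045
V  -0.378  -0.525   0.735   0.735  -0.588   0.084   0.672  -0.945   0.819  -0.798  -0.399   0.735   0.336   0.735   0.945   0.168   0.147  -0.882   0.189   0.273
W   0.081   0.113  -0.158  -0.158   0.126  -0.018  -0.144   0.203  -0.176   0.171   0.086  -0.158  -0.072  -0.158  -0.203  -0.036  -0.032   0.189  -0.041  -0.059
Y   0.117   0.163  -0.228  -0.228   0.182  -0.026  -0.208   0.293  -0.254   0.247   0.124  -0.228  -0.104  -0.228  -0.293  -0.052  -0.045   0.273  -0.059  -0.085
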