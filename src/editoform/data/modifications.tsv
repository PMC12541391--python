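name	delta_mass	specificity
Acetyl	42.010565	K,S,T,C,N-term
Amidated	-0.984016	C-term
Biotin	226.077598	K
Butyryl	70.041865	K
Carbamidomethyl	57.021464	C,K,H,D,E
Carbamyl	43.005814	K,R,C,N-term
Carboxy	43.989829	K,D,E,W
Carboxymethyl	58.005479	C,K,W
Crotonyl	68.026215	K
Cysteinyl	119.004099	C
Deamidated	0.984016	N,Q
Dehydrated	-18.010565	S,T,D,Y
Dethiomethyl	-48.003371	M
Dimethyl	28.031300	K,R,N-term
Dioxidation	31.989829	M,W,C,F,Y
Ethyl	28.031300	K,E,D,N-term
Farnesyl	204.187801	C
Formyl	27.994915	K,S,T,N-term
GeranylGeranyl	272.250401	C
GlyGly	114.042927	K
Glutaryl	114.031694	K
Glutathione	305.068156	C
Guanidinyl	42.021798	K
Hex	162.052824	S,T,K,N
HexNAc	203.079373	S,T,N
Lipoyl	188.032956	K
Malonyl	86.000394	K,C
Methyl	14.015650	*
Methylthio	45.987721	C,N,D
Myristoyl	210.198366	K,C,G,N-term
Nitro	44.985078	W,Y,F
Nitrosyl	28.990164	C
Oxidation	15.994915	*
Palmitoyl	238.229666	C,K,S,T
Phospho	79.966331	S,T,Y,H,D
Propionyl	56.026215	K,S,T,N-term
PyroGlu_from_E	-18.010565	E
PyroGlu_from_Q	-17.026549	Q
Succinyl	100.016044	K
Sulfo	79.956815	S,T,Y
Trimethyl	42.046950	K,R
Trioxidation	47.984744	C,W,Y,F
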