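position	substrate
A1	water
A2	beta-methyl-D-glucoside
A3	D-galactonic acid gamma-lactone
A4	L-arginine
B1	pyruvic acid methyl ester
B2	D-xylose
B3	D-galacturonic acid
B4	L-asparagine
C1	Tween 40
C2	i-erythritol
C3	2-hydroxy benzoic acid
C4	L-phenylalanine
D1	Tween 80
D2	D-mannitol
D3	4-hydroxy benzoic acid
D4	L-serine
E1	alpha-cyclodextrin
E2	N-acetyl-D-glucosamine
E3	gamma-hydroxybutyric acid
E4	L-threonine
F1	glycogen
F2	D-glucosaminic acid
F3	itaconic acid
F4	glycyl-L-glutamic acid
G1	D-cellobiose
G2	glucose-1-phosphate
G3	alpha-ketobutyric acid
G4	phenylethylamine
H1	alpha-D-lactose
H2	D,L-alpha-glycerol phosphate
H3	D-malic acid
H4	putrescine
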