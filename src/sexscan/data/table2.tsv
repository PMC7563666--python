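population	group	phenotype	n	known_genotype	amhX	amhdY	amhY	predicted
Manzala	domestic	female	1	XX	+	-	-	XX
Manzala	domestic	male	1	XY	+	+	+	XY
Manzala	domestic	male	1	YY	-	+	+	YY
Kpandu	wild	female	27		+	-	-	XX
Kpandu	wild	male	24		+	+	+	XY
Kpandu	wild	male	3		+	-	-	XX
Koka	wild	female	14		+	-	-	XX
Koka	wild	male	8		+	-	+	XY
Koka	wild	male	9		+	-	ND	ND
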