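population	start	end	ci	type	size	shared
Koka	34491225	34512737	50	duplication	21512	yes
Koka	34493315	34498588	390	deletion	5273	yes
Koka	34503117	34509103	852	deletion	5986	yes
Kpandu	34491225	34512741	50	duplication	21516	yes
Kpandu	34491681	34491957	2	deletion	276	no
Kpandu	34493315	34498548	150	deletion	5233	yes
Kpandu	34499596	34499830	3	deletion	234	no
Kpandu	34503494	34509103	2	deletion	5609	yes
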