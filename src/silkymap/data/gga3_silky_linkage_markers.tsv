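marker	chrom	position_bp	recombination_fraction	lod
ss317369158	3	70119483	0.01	23.2
rs16294399	3	70201106	0.01	22.9
rs16294517	3	70299532	0	11.1
ss317369395	3	70311973	0	17.8
rs15380516	3	70367159	0	15.1
rs16294597	3	70367382	0	23.2
rs16294606	3	70377047	0	20.2
rs16294615	3	70383717	0	19.6
rs14372495	3	70384172	0	20.2
rs14372520	3	70399176	0	20.5
ss666793689	3	70412158	0	8.4
rs14372560	3	70422653	0	18.4
rs16294682	3	70441580	0	5.7
rs16294701	3	70447648	0	19.6
rs16294719	3	70461007	0	29.2
rs13691298	3	70467968	0	34.0
rs16294744	3	70481788	0	14.8
rs14372652	3	70504365	0	21.7
rs14372671	3	70527941	0	28.0
ss317369621	3	70558349	0	29.5
ss317369629	3	70581126	0.01	31.2
rs10724747	3	70640111	0.01	18.8
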