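phylum	code	group	count
Acidobacteria	ad	1|-|+	3
Acidobacteria	ad	2|-|+	2
Acidobacteria	ad	1|+|+	1
Green non-sulfur	ns	1|-|+	6
Green non-sulfur	ns	1|+|+	1
Green sulfur	gs	1|-|+	5
Green sulfur	gs	1|+|+	1
Deinococcus-Thermus	dt	1|+|+	6
Hyperthermophilic	ht	1|-|+	12
Hyperthermophilic	ht	2|-|+	5
Hyperthermophilic	ht	1|+|+	1
Cyanobacteria	cy	1|-|+	7
Planctomycetes	pl	1|-|+	2
Planctomycetes	pl	1|+|+	3
Verrucomicrobia	ve	1|+|+	4
Fusobacteria	fu	1|-|+	5
Bacteroidetes	ba	1|-|+	1
Bacteroidetes	ba	1|+|+	1
Bacteroidetes	ba	1|+|-	12
Spirochaetes	sp	1|-|+	4
Spirochaetes	sp	1|+|+	1
Chlamydiae	ch	1|-|+	6
Actinobacteria	ac	1|-|+	16
Actinobacteria	ac	1|+|+	1
Tenericutes	te	1|-|+	3
Tenericutes	te	1|+|-	3
Firmicutes	fi	1|-|+	18
Firmicutes	fi	1|+|+	8
Firmicutes	fi	1|+|-	2
Alpha-proteobacteria	alpha	1|-|+	18
Alpha-proteobacteria	alpha	2|-|+	45
Alpha-proteobacteria	alpha	2|+|+	2
Alpha-proteobacteria	alpha	1|+|+	4
Epsilon-proteobacteria	epsilon	2|-|+	4
Epsilon-proteobacteria	epsilon	2|+|+	6
Delta-proteobacteria	delta	1|-|+	1
Delta-proteobacteria	delta	1|+|+	23
Gamma-proteobacteria	gamma	2|-|+	7
Gamma-proteobacteria	gamma	1|+|+	28
Gamma-proteobacteria	gamma	1|+|-	45
Beta-proteobacteria	beta	1|+|+	43
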