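category	pattern	priority
metal_resistance	copper	10
metal_resistance	CopA	10
metal_resistance	CusA	10
metal_resistance	CzcA	10
metal_resistance	cobalt-zinc-cadmium	10
metal_resistance	arsenate	10
metal_resistance	arsenical	10
metal_resistance	mercuric	10
metal_resistance	chromate	10
antibiotic_resistance	beta-lactamase	20
antibiotic_resistance	lactamase	20
antibiotic_resistance	AcrB/AcrD/AcrF	20
antibiotic_resistance	streptomycin adenylyltransferase	20
antibiotic_resistance	aminoglycoside	20
antibiotic_resistance	multidrug	20
antibiotic_resistance	tetracycline	20
antibiotic_resistance	chloramphenicol	20
toxin_antitoxin	antitoxin	30
toxin_antitoxin	toxin	30
toxin_antitoxin	RelE	30
toxin_antitoxin	HicB	30
toxin_antitoxin	PIN domain	30
phage_hallmark	capsid	40
phage_hallmark	terminase	40
phage_hallmark	portal	40
phage_hallmark	tail	40
phage_hallmark	baseplate	40
phage_hallmark	integrase	40
phage_hallmark	holin	40
phage_hallmark	tape measure	40
metabolism	dehydrogenase	50
metabolism	reductase	50
metabolism	kinase	50
metabolism	synthase	50
metabolism	synthetase	50
metabolism	transferase	50
metabolism	hydrolase	50
metabolism	phosphatase	50
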