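Feature	p	t	k	b	d	g	č	ǰ	f	θ	s	x	m	n	ɲ	l	r	ɾ
Sonorant													+	+	+	+	+	+
Consonantal
Continuant									+	+	+	+					+	+
Nasal													+	+	+
Lateral																+
Tense																		+
Laryngeal	√	√	√	√	√	√	√	√	√	√	√	√	√	√	√	√	√	√
Voiced				+	+	+		+
Spread-glottis
Place	√	√	√	√	√	√	√	√	√	√	√	√	√	√	√	√	√	√
Labial	√			√					√				√
Round
Labiodental
Coronal							√	√			√				√
Anterior							−	−							−
Grooved											+
Dorsal			√			√						√
Back
High
Low
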