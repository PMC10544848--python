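Feature	i	e	u	o	a
Sonorant
Consonantal	−	−	−	−	−
Continuant
Nasal
Lateral
Tense
Laryngeal	√	√	√	√	√
Voiced
Spread-glottis
Place	√	√	√	√	√
Labial
Round
Labiodental
Coronal
Anterior
Distributed
Grooved
Dorsal	√		√	√	√
Back			+	+	+
High	+		+
Low					+
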