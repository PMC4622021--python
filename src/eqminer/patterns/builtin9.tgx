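# Built-in phenotype extraction patterns.
# Each pattern requires a quality (PATO) adjective; the entity namespace
# group varies: anatomy/chemical (1-3), phenotype ontologies (4-6),
# disease vocabularies (7-9).  Syntactic shapes: plain JJ sister,
# ADJP-wrapped JJ, and NP-coordination.
NP < (JJ < (SEM < /PATO/) ++ (/NN.?/ < (SEM < /FMA|RXNORM|CHEBI|MA/)))
NP < ((ADJP < (JJ < (SEM < /PATO/))) ++ (/NN.?/ < (SEM < /FMA|RXNORM|CHEBI|MA/)))
NP < ((NP < (JJ < (SEM < /PATO/))) + CC (NP < (NN < (SEM < /FMA|RXNORM|CHEBI|MA/))))
NP < (JJ < (SEM < /PATO/) ++ (/NN.?/ < (SEM < /MP|HP/)))
NP < ((ADJP < (JJ < (SEM < /PATO/))) ++ (/NN.?/ < (SEM < /MP|HP/)))
NP < ((NP < (JJ < (SEM < /PATO/))) + CC (NP < (NN < (SEM < /MP|HP/))))
NP < (JJ < (SEM < /PATO/) ++ (/NN.?/ < (SEM < /DOID|ORDO|OMIM/)))
NP < ((ADJP < (JJ < (SEM < /PATO/))) ++ (/NN.?/ < (SEM < /DOID|ORDO|OMIM/)))
NP < ((NP < (JJ < (SEM < /PATO/))) + CC (NP < (NN < (SEM < /DOID|ORDO|OMIM/))))
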