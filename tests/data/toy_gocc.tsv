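protein_id	term
P01	extracellular space
P02	extracellular space
P03	extracellular space
P04	extracellular space
P06	extracellular space
P07	extracellular space
P05	Extracellular  Exosome
P08	nucleus
P09	nucleus
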