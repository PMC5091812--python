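# Genera repeatedly reported as reagent/kit contaminants in low-biomass
# sequencing studies. One genus per line; lines starting with '#' are
# comments. Edit freely — this catalog is configuration, not code.
Propionibacterium
Acidovorax
Cupriavidus
Alteromonas
Pandoraea
Rubrivivax
Ralstonia
Burkholderia
Bradyrhizobium
Sphingomonas
Methylobacterium
Pseudomonas
Acinetobacter
Stenotrophomonas
Comamonas
Delftia
Escherichia
Corynebacterium
Streptococcus
Staphylococcus
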