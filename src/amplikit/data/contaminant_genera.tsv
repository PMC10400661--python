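# Default contaminant genus signature list: genera widely reported as
# reagent / laboratory ("kitome") contaminants in low-biomass 16S studies.
# This packaged list is a generic placeholder — edit or replace it with a
# study-specific signature list for real analyses.
Ralstonia
Burkholderia
Bradyrhizobium
Sphingomonas
Methylobacterium
Herbaspirillum
Delftia
Cupriavidus
Pelomonas
Stenotrophomonas
Variovorax
Comamonas
Phyllobacterium
Mesorhizobium
Afipia
Acinetobacter
Brevundimonas
Caulobacter
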