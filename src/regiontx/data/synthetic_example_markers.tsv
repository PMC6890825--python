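# SYNTHETIC example marker file (editable fixture).
# These are placeholder gene names matching the synthetic proportion atlas,
# NOT curated cell-type markers; supply your own two-column TSV
# (cell_type<TAB>gene) for real-data runs.
cell_type	gene
neuron	NEURON_M00
neuron	NEURON_M01
neuron	NEURON_M02
neuron	NEURON_M03
neuron	NEURON_M04
neuron	NEURON_M05
astrocyte	ASTROCYTE_M00
astrocyte	ASTROCYTE_M01
astrocyte	ASTROCYTE_M02
astrocyte	ASTROCYTE_M03
astrocyte	ASTROCYTE_M04
astrocyte	ASTROCYTE_M05
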