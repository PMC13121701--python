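accession	category
GO:0000278	mitotic cell cycle
GO:0001525	angiogenesis
GO:0030155	regulation of cell adhesion
GO:0006954	inflammatory response
GO:0001837	epithelial-to-mesenchymal transition
GO:0012501	programmed cell death
GO:0007599	hemostasis
GO:0043114	regulation of vascular permeability
GO:0008217	regulation of blood pressure
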