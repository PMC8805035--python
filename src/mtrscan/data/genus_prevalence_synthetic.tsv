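genus	n_species_with_cluster	n_assemblies_assessed
Shewanella	40	45
Paraferrimonas	2	3
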