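# Stoichiometric compound-class boundaries in van Krevelen space.
#
# Transcribed from the MSCC (multidimensional stoichiometric compound
# classification) criteria of Rivas-Ubach et al. (2018, Anal. Chem. 90,
# 6152-6160): lipids, carbohydrates, peptides, amino sugars, oxy-aromatic
# phytochemicals and nucleotides. The nucleotide rule's phosphorus condition
# is dropped because phosphorus is outside the element model.
#
# Rules are applied IN ORDER; the first rule whose bounds all hold wins, and
# a formula matching no rule is labelled "unclassified". All bounds are
# inclusive; omit a ratio to leave it unconstrained; a two-element list is
# [low, high].
rules:
  - label: nucleotide
    o_c: [0.5, 1.7]
    h_c: [1.0, 1.8]
    n_c: [0.2, 0.5]
  - label: amino sugar
    o_c: [0.61, 0.8]
    h_c: [1.45, 2.15]
    n_c: [0.07, 0.2]
  - label: peptide
    o_c: [0.12, 0.6]
    h_c: [0.9, 2.5]
    n_c: [0.126, 0.7]
  - label: carbohydrate
    o_c: [0.8, 1.0]
    h_c: [1.65, 2.7]
    n_c: [0.0, 0.0]
  - label: lipid
    o_c: [0.0, 0.6]
    h_c: [1.32, 2.25]
    n_c: [0.0, 0.0]
  - label: oxy-aromatic
    o_c: [0.0, 1.15]
    h_c: [0.7, 1.32]
    n_c: [0.0, 0.126]
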