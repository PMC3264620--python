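# Dec-DETA: decanoyl-diethylenetriamine ligand targeting the A-beta
# central helix.  Hydrocarbon tail C1-C9 packs against the middle
# nonpolar part (L17-A21); the two protonated amine nitrogens N2 and N3
# form salt bridges / hydrogen bonds with E22 and D23.
name: dec_deta
heavy_atoms: [C1, C2, C3, C4, C5, C6, C7, C8, C9, C11, N2, N3, O1]
basic_groups: [[N2], [N3]]
acidic_groups: []
nonpolar_atoms: [C1, C2, C3, C4, C5, C6, C7, C8, C9]
donor_hydrogens:
  N2: [HN2]
  N3: [HN3]
extra_acceptors: [O1]
nonpolar_target_residue: 18
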