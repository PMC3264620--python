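# Pep1b: designed peptide-like ligand for the A-beta central helix.
# Two basic amine groups (N5/N6 and N7/N8) target the acidic residues
# E22/D23; two acidic carboxylate groups (O1/O2 and O4/O5) target the
# basic residues H13/K16; the central indole (C13-C20 plus N3) packs
# against F20.  O3 is a backbone-like carbonyl acceptor.
name: pep1b
heavy_atoms: [C13, C14, C15, C16, C17, C18, C19, C20, N3,
              N5, N6, N7, N8, O1, O2, O3, O4, O5]
basic_groups: [[N5, N6], [N7, N8]]
acidic_groups: [[O1, O2], [O4, O5]]
nonpolar_atoms: [C13, C14, C15, C16, C17, C18, C19, C20, N3]
donor_hydrogens:
  N5: [HN5]
  N6: [HN6]
  N7: [HN7]
  N8: [HN8]
extra_acceptors: [O3]
nonpolar_target_residue: 20
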