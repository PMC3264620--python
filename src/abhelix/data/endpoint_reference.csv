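# Published last-2-ns endpoint averages for ten independent 20 ns
# simulations per system: middle-region (15-24) backbone RMSD (A),
# middle-region alpha-helical hydrogen-bond count, and endpoint group
# label, for A-beta(13-26) alone and with Dec-DETA or Pep1b.
trajectory,system,avg_rmsd,avg_ahb,group
1,no_ligand,2.59,2.4,B
2,no_ligand,2.79,2.8,B
3,no_ligand,2.20,2.5,B
4,no_ligand,5.25,0.0,C
5,no_ligand,3.84,0.9,B
6,no_ligand,2.29,1.8,B
7,no_ligand,4.85,0.4,C
8,no_ligand,3.06,1.4,B
9,no_ligand,4.89,0.1,C
10,no_ligand,1.24,4.2,A
1,dec_deta,1.09,3.5,A
2,dec_deta,2.23,3.1,B
3,dec_deta,3.78,0.8,B
4,dec_deta,5.50,0.1,C
5,dec_deta,2.55,1.9,B
6,dec_deta,1.51,3.6,A
7,dec_deta,1.46,4.5,A
8,dec_deta,1.36,4.2,A
9,dec_deta,0.85,4.3,A
10,dec_deta,3.18,3.7,B
1,pep1b,0.91,3.6,A
2,pep1b,1.79,2.5,A
3,pep1b,3.73,0.8,B
4,pep1b,0.91,4.4,A
5,pep1b,3.65,1.6,B
6,pep1b,2.21,3.7,B
7,pep1b,1.38,2.3,A
8,pep1b,2.12,2.3,B
9,pep1b,3.07,2.3,B
10,pep1b,2.21,3.4,B
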