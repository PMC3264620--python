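# abhelix

Trajectory analysis of amyloid-β central-helix stabilization by designed
ligands.

## The problem

The middle region (residues 15–24) of the amyloid-β peptide is α-helical
at the membrane interface; its unfolding to extended, β-strand-like
conformations is an early step toward aggregation into the fibrils and
oligomers implicated in Alzheimer's disease. One proposed intervention
is to trap the peptide in its helical state with small designed ligands:
**Dec-DETA** (a decanoyl tail with two basic amine groups that target
E22/D23) and **Pep1b** (two basic groups for E22/D23, two acidic
carboxylate groups for H13/K16, and a central indole that packs against
F20).

`abhelix` implements the complete quantitative pipeline used to judge
whether such a ligand stabilizes the central helix in molecular-dynamics
trajectories of the capped fragment Aβ(13–26) (sequence `HHQKLVFFAEDVGS`):

- **model_io** — full-atom ideal α-helix construction by
  internal-coordinate chain extension, acetyl/amide capping, formal-charge
  bookkeeping, ligand specifications, multi-model-PDB and array I/O;
- **geometry** — Kabsch superposition, backbone RMSD of the middle
  region, radius of gyration, sidechain centers of geometry;
- **contacts** — hydrogen bonds at the acceptor–hydrogen ≤ 2.4 Å
  criterion, α-helical O(i)–HN(i+4) counts, residue–ligand contact maps
  (sidechain COG to ligand heavy atom ≤ 6.0 Å), nonpolar C–C/C–N contacts
  (≤ 5.0 Å, backbone carbonyl carbons excluded), dual-mode binding;
- **classify_stats** — per-frame conformation classes
  (1: RMSD < 2 Å, 2: 2 ≤ RMSD < 4 Å, 3: RMSD ≥ 4 Å), per-trajectory
  endpoint groups A/B/C from last-2-ns averages, histograms, per-class
  binding fractions and averages, binding timelines;
- **synthetic** — a trajectory generator with known ground truth:
  per-residue helix/coil two-state Markov chains, a bound/unbound ligand
  chain, and a protection factor ρ that divides the unfolding rate while
  the ligand is bound (stationary occupancy k_on/(k_on+k_off), stationary
  helicity k_f/(k_f+k_u,eff));
- **pipeline / cli** — configuration-driven end-to-end runs emitting the
  full CSV report bundle (`abhelix build|simulate|analyze|report`).

No MD engine is involved: trajectories come from the generator (or from
multi-model PDB files you supply), which is what makes every statistic
testable against a known ground truth.

## Worked example

Build the models and check the construction invariants:

```sh
$ python analysis/01_build_models.py
ideal helix: 144 atoms, 10 backbone i,i+4 HBs over 13-26 (6 in 15-24), net charge +1e
dec_deta complex: ligand charge +2e, complex net charge +3e, 9 nonpolar ligand atoms
pep1b complex: ligand charge +0e, complex net charge +1e, 9 nonpolar ligand atoms
```

The canonical helix at (φ, ψ) = (−57°, −47°) carries ten O(i)–HN(i+4)
backbone hydrogen bonds over residues 13–26, six of them inside the
middle region — the defining property of the fully folded state. With
H13/H14/K16 protonated and E22/D23 deprotonated the peptide carries +1e;
adding Dec-DETA (+2e) or Pep1b (0e) gives complexes of +3e and +1e.

Classify the published per-trajectory endpoint averages shipped with the
package (last-2-ns middle-region RMSD and α-HB count for ten 20 ns runs
per system):

```sh
$ python analysis/04_endpoint_worked_example.py
group labels reproduced: 30/30
no_ligand  RMSD 3.30 +/- 1.35 A, alpha-HB 1.65 +/- 1.35, groups A/B/C = 1/6/3
dec_deta   RMSD 2.35 +/- 1.45 A, alpha-HB 2.97 +/- 1.53, groups A/B/C = 5/4/1
pep1b      RMSD 2.20 +/- 1.02 A, alpha-HB 2.69 +/- 1.08, groups A/B/C = 4/6/0
```

Group A (helical endpoint, RMSD < 2 Å) appears once without ligand but
five/four times with Dec-DETA/Pep1b; complete unfolding (group C) drops
from three occurrences to one/zero — the stabilization signal in table
form.

Generate and analyze synthetic trajectories for the three systems, then
compare:

```sh
$ python analysis/02_run_systems.py --n-traj 3 --n-frames 400 --window-ns 0.5
$ python analysis/03_compare_systems.py
   system  window  freq_class1  freq_class3  class1_vs_control  class3_vs_control
no_ligand   whole         0.11         0.53               1.00               1.00
 dec_deta   whole         0.31         0.24               2.90               0.46
    pep1b   whole         0.31         0.24               2.90               0.46
...
```

With protection factor ρ = 4 the ligand-present systems populate the
helical class ~3× more and the unwound class ~0.5× as much as the
ligand-free control — the directional effect the per-frame pipeline is
built to detect (exact numbers depend on the seeds and run length you
choose).

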