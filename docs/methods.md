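# Methods

## System and structural model

The analysis unit is the capped amyloid-β fragment Aβ(13–26)
(`HHQKLVFFAEDVGS`, biological numbering 13–26) with an N-terminal acetyl
cap at index 12 and a C-terminal amide cap at index 27, optionally
accompanied by one rigid ligand. Coordinates are Å, times ps, charges e.

Structures are built by internal-coordinate chain extension (NeRF) with
standard backbone geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å, N–H 1.00 Å; τ(N–Cα–C) 111.2°, ω fixed at 180°). The amide
hydrogen is placed anti to the preceding carbonyl oxygen. Sidechain
heavy atoms and the retained polar hydrogens are grafted per residue
from the CCD ideal residue templates shipped with biotite, superposed on
each residue's N/Cα/C frame; this fixes correct L-chirality and a single
realistic rotamer per residue type. Nonpolar hydrogens are not modelled:
every criterion in the pipeline uses heavy atoms and donor (polar)
hydrogens only, so the radius of gyration "over all atoms" runs over all
modelled atoms.

Protonation states are fixed at the fully charged forms: His (both ring
nitrogens protonated, +1), Lys (+1), Glu/Asp (deprotonated, −1), caps
neutral. This yields net +1e for the peptide, +3e with Dec-DETA (two +1
basic amine groups), +1e with Pep1b (two basic, two acidic groups).

Hydrogen-bond roles: acceptors are backbone O (caps included), Asp
Oδ1/Oδ2, Glu Oε1/Oε2, Ser Oγ, Gln Oε1; donors are backbone N–HN, His
Nδ1–H and Nε2–H, Lys Nζ–H×3, Ser Oγ–H, Gln Nε2–H×2, plus the amide-cap
NH2. Ligand roles come from its spec file (`src/abhelix/data/*.yaml`).

The built ideal helix at (φ, ψ) = (−57°, −47°) has an O(i)–HN(i+4)
distance of 2.115 Å, giving ten backbone i,i+4 bonds over residues 13–26
and six inside 15–24 at the 2.4 Å criterion (the caps extend the same
geometry by two more bonds, which the region-restricted counts exclude).

## Analysis criteria

All criteria are plain distance cutoffs with the boundary counted as a
contact (≤):

| quantity | rule | default |
|---|---|---|
| hydrogen bond | acceptor–hydrogen distance | ≤ 2.4 Å |
| α-helical HB (αHB) | O(i)–HN(i+4), both residues in 15–24 | ≤ 2.4 Å |
| residue–ligand contact | sidechain-COG to ligand heavy atom | ≤ 6.0 Å |
| nonpolar contact | peptide C (res 17–21, no backbone C=O carbon) to ligand nonpolar atom | ≤ 5.0 Å |
| conformation class | middle-region backbone RMSD | 1: < 2 Å, 2: < 4 Å, 3: ≥ 4 Å |

There is no donor–H–acceptor angular term, and bifurcated bonds count
once per (hydrogen, acceptor) pair. Before RMSD measurement each frame
is superposed on the reference (the trajectory's first frame unless an
explicit reference is supplied) by Kabsch least squares over all peptide
heavy atoms (caps excluded); the RMSD is then taken over backbone
N/Cα/C/O of residues 15–24 without re-fitting. Rg defaults to
mass-weighted over all atoms of residues 15–24; a flag switches to the
unweighted form, since published conventions vary. The sidechain COG is
the unweighted mean of sidechain heavy atoms, with Cα as the glycine
fallback.

Endpoint groups A/B/C apply the class thresholds to last-2-ns averages.
The αHB ranges conventionally quoted with the groups (A: 2–6, B: 1–4,
C: ≈0) overlap, so the RMSD interval alone decides the label and the
αHB range is reported as a consistency flag ("≈0" is operationalized as
< 0.5). This rule reproduces all 30 published endpoint labels in the
packaged reference table. "Second half" means frames with time strictly
greater than (t_first + t_last)/2. Column summaries use the sample SD
(n−1), which reproduces the published SD of 1.35 for the ligand-free
RMSD column; the published ligand-free αHB column mean prints as 1.6
while its printed values average to 1.65 — the package reports what it
computes and does not force agreement. Report tables round RMSD to 2
decimals, αHB to 1, fractions to 2; classification always uses unrounded
values.

## Synthetic trajectory generator

The generator produces the statistical structure the pipeline assumes,
with known ground truth, not thermodynamic realism. Hidden dynamics:
each residue is an independent helix/coil two-state continuous-time
Markov chain (unfolding rate k_u, refolding rate k_f), and the ligand a
bound/unbound chain (k_on, k_off); while bound, every residue's k_u is
divided by the protection factor ρ. Chains are sampled exactly at the
10 ps stride through the closed-form two-state transition probabilities
(no Euler discretization bias). Stationary expectations are
occupancy = k_on/(k_on+k_off) and helicity = k_f/(k_f+k_u,eff) with
k_u,eff the occupancy-weighted unfolding rate; within each stride
interval the ligand state at the interval start is held fixed when
propagating the residue chains.

Defaults (chosen once as the study conditions): 2000 frames × 10 ps
(20 ns), k_u = k_f = 0.5 /ns per residue (ligand-free stationary
helicity 0.5, unfolding on the nanosecond scale), k_on = 1.0 /ns,
k_off = 0.4 /ns (stationary occupancy 0.71, matching the ~73% bound
fraction typical of these complexes), ρ = 4, dihedral noise SD 0.8°.
Frame 0 is the noise-free ideal helix (the stand-in for the initial
energy-minimized structure), with the ligand bound when a binding
channel exists.

Coordinates: helical residues draw (φ, ψ) around (−57°, −47°), coil
residues around an extended basin (−135°, +135°), each with Gaussian
jitter, and the chain is rebuilt per frame. The helical-basin jitter is
deliberately narrow: the ideal-helix O–HN distance (2.115 Å) leaves only
~0.3 Å of margin to the 2.4 Å criterion, and at SD 0.8° a fully helical
stretch retains all six middle-region bonds in every frame (measured
maximum 2.31 Å over 2000 frames), so conformational fluctuation is
carried by the helix/coil chain rather than the jitter. At SD 3° the
bonds break spuriously (maximum 2.77 Å); anticorrelated φ/ψ jitter does
not widen the margin.

Ligand geometry is rigid. The packaged Dec-DETA and Pep1b templates are
synthetic stand-in layouts (realistic spacing and group arrangement; the
full bond graphs are not modelled). When bound, one representative donor
per basic group is pinned at hydrogen-bond range (H···acceptor drawn
uniformly from 1.7–2.2 Å) of its designed target (E22 Oε1, D23 Oδ1), and
for Pep1b one acceptor per acidic group is pinned at the K16/H13 donor
hydrogens; remaining atoms follow by rigid Kabsch fit with 0.15 Å
positional jitter, the nonpolar centroid aimed 4.5 Å off the designed
nonpolar residue's sidechain COG. Pinning guarantees that the hidden
bound state and the pipeline's polar-bound flag coincide exactly, which
is what makes occupancy recovery a clean estimator test. When unbound
the ligand is displaced at least 15 Å beyond the peptide's extent in a
random direction.

What the generator does **not** emulate: cooperativity between residues
(no Zimm–Bragg coupling), temperature or solvent effects, ligand
flexibility and realistic binding poses, β-strand inter-residue
contacts, or the kinetics of any particular force field. Consequently a
passing recovery test shows the *pipeline* measures what it claims on
data with the assumed statistical structure — not that real trajectories
have that structure. Absolute nonpolar-contact counts, in particular,
depend on the stand-in ligand geometry and should be read only
comparatively.

## Statistical checks and problem sizes

Occupancy-recovery tests use k_on = k_off = 20 /ns: the 3-binomial-SD
acceptance band presumes near-independent frames, and these rates give a
25 ps relaxation time against the 10 ps stride, keeping frame-to-frame
correlation small. Protection-factor recovery compares, for each of five
seeds, a ρ = 4 ligand system against a k_on = 0 control over 1000-frame
(10 ns) trajectories — long enough for the binding chain (relaxation
0.7 ns at the default rates) to mix; the test asserts strictly higher
class-1 and αHB ≥ 5 frequencies in every seed. The analysis drivers
under `analysis/` default to 3–4 trajectories of 400–500 frames per
system, a scaled-down rendition of the ten-trajectory design the
defaults emulate.

## Numerical and interface choices

- Ties at every distance boundary count as bonded/in contact, matching
  the ≤ criteria exactly; boundary tests use exactly representable
  coordinates.
- Kabsch superposition uses SVD with a determinant correction to exclude
  reflections; degenerate (collinear or < 3 atoms) fits are rejected.
- Trajectory formats: multi-model PDB for interchange (times implied by
  the stride, coordinates at the format's 3-decimal precision) and an
  npz array container for lossless round trips. Readers rebuild the
  annotated topology from the residue sequence (plus the ligand spec)
  and validate atom names atom-by-atom; per-model atom-count mismatches
  are rejected naming the model.
- Ligand charge bookkeeping is per functional group (+1 per basic group,
  −1 per acidic group), placed on the group's first atom.
- `run_analysis` writes byte-identical outputs for identical configs and
  removes partial outputs on failure; the manifest records config,
  version, and seeds. Every table is recomputable from the emitted
  per-frame metrics, and a test audits this.
- Contact-map rows are the peptide residues 13–26 (caps excluded);
  columns follow ligand-spec order so maps are comparable across runs.
- No automated classifier for "parallel vs bent" complex shapes is
  provided; the underlying atom-pair distances are available from the
  coordinate API instead.
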