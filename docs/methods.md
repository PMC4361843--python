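# Methods

## Scope and model

`jmlipid` analyses how the juxtamembrane (JM) region of single-pass
receptors — modelled as the transmembrane (TM) helix plus the first 20
intracellular residues — reorganises anionic lipids (PS, PIP₂) in the inner
leaflet of a membrane. The package has two halves:

1. a **synthetic membrane emulator**: seeded 2D Brownian dynamics of lipid
   headgroup beads around an immobile TM-JM footprint, built so that the
   statistical structure the analyses assume (annular shells, lipid
   preference ordering PIP₂ > PS > PC, charge-driven contacts) emerges from
   explicit physics rather than being painted into the data; and
2. the **analysis stack**: per-residue contact matrices, occupancy
   fractions, residence times, unit-area lateral RDFs, occupancy density
   maps, RMSF, clustering propensities, and family-wide positional
   aggregation.

## The emulator

### Representation

Each lipid is one headgroup bead with a species label, formal charge
(PC/PE/CHOL 0, PS −1, GM3 −1, PIP₂ −4 — the coarse net charge of the
bis-phosphorylated inositol headgroup), radius 2.35 Å and lateral diffusion
coefficient 10 Å²/ns (uniform across species; real CG lipid dynamics are of
this order and no per-species values are assumed). The protein footprint is
immobile: one TM anchor at the box centre and one anchor per JM residue at
3.5 Å spacing along +x, encoding the surface-lying pose of the JM arm.
Residue anchors carry the formal charge of their amino acid (R/K +1, D/E
−1, H 0).

The system is two-dimensional because every analysis in scope is lateral
(in-plane density, annular shells, contacts near a surface-lying arm); a
third dimension would add cost without adding a testable observable.

### Interactions and integration

* WCA excluded volume between all bead pairs and bead–anchor pairs,
  contact distance σ = 4.7 Å, strength 1 kT.
* Screened electrostatics between charged sites:
  U(r) = ε·qᵢqⱼ·exp(−r/λ_D)/r with Debye length λ_D = 7.8 Å (0.15 M NaCl)
  and coupling ε in kT·Å, truncated at 30 Å (≈4 λ_D).
* Overdamped Langevin update per bead:
  Δx = (D/kT)·F·Δt + √(2DΔt)·η, η ~ N(0,1) per component, timestep
  Δt = 5 ps, periodic wrapping, minimum-image convention.

Numerical regularisation: pair forces are evaluated at max(r, 0.9 σ). The
bare r⁻¹² WCA wall is stiffer than the overdamped update can follow at this
timestep, so a thermal kick that transiently lands a bead inside the core
would otherwise produce a divergent restoring displacement. The clamp point
lies ≈8 kT up the repulsive wall — thermally inaccessible at equilibrium —
so sampled statistics are unchanged; the integrator still raises an
instability error if any single-step displacement exceeds half the box.
Reproducibility: each replicate r uses PRNG seed `seed + r` for placement
and a derived stream for the noise; identical configuration and seed give
bit-identical trajectories.

### Default study conditions

Fixed once, as the package's standard desk-scale protocol:

| parameter | value | note |
|---|---|---|
| box edge | 150 Å | periodic square; fits the 70 Å JM arm with margin |
| lipids | 300 | 75 Ų per lipid, a realistic leaflet density |
| composition | PC:PS:PIP₂ 80:10:10 | simple asymmetric inner leaflet |
| equilibration | 15 000 steps (75 ns) | discarded burn-in |
| production | 300 frames every 100 steps | 150 ns sampled per replicate |
| replicates | 3 | independent seeds, pooled frame-wise |

These lengths keep a full 3-replicate production run to roughly a minute on
one CPU while giving stable first-shell statistics (seed-to-seed spread of
the pooled mean ≈ ±0.4 lipids).

### Calibration of the coupling ε

The emulator has one free parameter, ε. `calibrate_affinity` scans a
geometric grid, simulating the reference system at each value, and selects
from the values whose mean first-shell PIP₂ count (within 6 Å of the anchor
set) falls in the target window [4, 6]. The recorded 3-replicate scan at
the default conditions:

| ε (kT·Å) | 2 | 4 | 8 | 12 | 16 | 20 | 28 | 40 | 56 | 80 |
|---|---|---|---|---|---|---|---|---|---|---|
| mean first-shell PIP₂ | 0.81 | 1.33 | 2.27 | 2.76 | 3.32 | 4.13 | 4.16 | 4.89 | 4.14 | 4.14 |

Two selection rules are exposed: `"smallest"` (smallest in-window value,
the default contract) and `"centre"` (in-window value nearest the window
centre). The shipped constant `DEFAULT_EPSILON_ELEC = 40` uses the centre
rule: the smallest in-window value (20) sits at the window edge and its
pooled mean drifts below 4 under replicate noise on other seeds, whereas 40
stays at 4.5–4.9 across every seed tried. The plateau above ε ≈ 40 is real
physics, not noise floor: each bound PIP₂ (−4) locally neutralises basic
anchors and repels other PIP₂ with a charge product of 16, so the first
shell self-limits.

### Reference system

The calibration reference is a synthetic INSR-like receptor: a 20-residue
hydrophobic TM helix and the JM arm `KRSLKQNGRSTAPKLQSNTL` (basic residues
at positions 1, 2, 5, 9, 14; net charge +5). It is constructed to carry the
family-typical charge architecture — an N-terminal basic pair plus basics
distributed along the arm — not copied from any UniProt entry. A clustered
arrangement of 4 basics saturates near 3 first-shell PIP₂ in this emulator,
because a single PIP₂ neutralises the whole cluster; distributing the
basics lets each capture its own lipid, consistent with the observation
that evenly spread charge accommodates more lipids within contact range.

## Analyses

* **Contacts** — a bead is in contact with a residue when its
  minimum-image distance to that residue's anchor is ≤ 6 Å (boundary
  inclusive). A bead within range of several residues counts once per
  residue. Replicates are concatenated frame-wise.
* **Occupancy fraction** — percentage of frames with ≥1 contact, per
  residue.
* **Residence time** — per-residue occupancy is binarised; occupancy time
  divided by the number of association events (maximal runs of occupied
  frames; gap tolerance 0, i.e. no smoothing; runs never bridge the
  boundary between concatenated replicates; 0 with an explicit event count
  of 0 when never occupied). This is the per-residue-run definition; dwell
  tracking of individual lipid identities is a documented extension, not
  the default.
* **Lateral RDF** — per bead-frame minimum distance to the anchor set,
  histogrammed on [0, 30] Å with 1 Å bins, divided by each bin's annulus
  area, rescaled to unit area under the curve (the published convention,
  which removes dimensional prefactors and makes species directly
  comparable). Mean and SD over replicates; the unit-area invariant holds
  to 10⁻⁶ for every profile. The distance reference is the full anchor set
  (TM + JM); the first peak is the first bin strictly exceeding both
  neighbours (first bin qualifies by exceeding its right neighbour only).
* **Density map** — per grid cell (default 1 Å), the fraction of frames in
  which ≥1 bead of the species occupies the cell.
* **RMSF** — per labelled particle, √⟨|x − ⟨x⟩|²⟩ over frames, no
  superposition (anchors are fixed by construction; alignment of ingested
  external tracks is the adapter caller's responsibility).
* **Clustering propensity** — C = ⟨(beads of species within 6 Å)/(total
  beads of species)⟩ / (leaflet mole fraction of the species), the literal
  published normalisation. Note its no-enrichment baseline is the
  accessible-shell area fraction divided by the species fraction — i.e. it
  depends on the species' abundance — so C supports within-species
  comparisons (wild-type vs mutant, with vs without a competitor) rather
  than direct cross-species comparison; cross-species statements in the
  package use the RDF first-shell values or C·f (the own-population shell
  fraction) instead. Leaflet percentage means mole percent of all species
  in the leaflet, cholesterol included.
* **Family aggregation** — per-position mean contacts (sum over receptors
  divided by the receptor count), per-position residue-class and
  amino-acid probabilities (each summing to 1), emitted in a
  position-weight-matrix text layout. Pearson correlation (Spearman
  optional) between clustering propensity and net JM charge, restricted by
  default to receptors with net positive JM charge; degenerate inputs
  (zero variance) return NaN flagged rather than raising. Saturation of
  the propensity–charge relation is reported descriptively via a
  piecewise (rising/flat) least-squares breakpoint, with no inferential
  claim attached.

## Residue conventions

Four classes: basic (R, K), acidic (D, E), polar (S, T, N, Q, C, Y, H, W),
hydrophobic/non-polar (A, V, L, I, M, F, G, P). Histidine is counted
neutral and polar — net JM charge is #R/K − #D/E — and fragment termini
carry no charge. JM positions are numbered 1..20 from the first residue
after the TM helix in every positional output.

## What the emulator does and does not show

The generator reproduces: annular first-shell structure at the bead contact
distance (first RDF peak in the 4–6 Å bin), the preference ordering
PIP₂ > PS > PC, competition (PS clustering rises when PIP₂ is removed),
charge dependence (basic→Leu mutants lose anionic clustering; propensity
rises with net positive JM charge and flattens at high charge), and
first-shell occupancy calibrated into the 4–6 window.

It does not emulate: explicit solvent or ions beyond Debye screening, lipid
tails, protein flexibility (anchors are frozen, so anchor RMSF is zero by
construction and protein dynamics are out of scope), outer-leaflet species
dynamics (GM3/cholesterol enter composition bookkeeping only), binding
kinetics on real CG-MD timescales, or 3D effects. Second and third RDF
shells (10 Å, 15 Å) are present only weakly: single-bead headgroups
without tails produce less layering than a full bilayer. Likewise the PS
first-shell enrichment over PC is small in the three-species leaflet —
PIP₂ outcompetes PS for the basic sites (the same competition that makes
PS clustering rise sharply when PIP₂ is removed) — so resolving the
PS > PC leg of the preference ordering needs the full three-replicate
sampling rather than a single short run. Passing tests
therefore validate the analysis pipeline and the qualitative electrostatic
mechanism, not quantitative CG-MD observables.

## Degenerate inputs and tie-breaks

Largest-remainder apportionment breaks remainder ties by lexicographic
species name. Empty contact matrices raise; all-zero residue rows yield
residence time 0 with `n_events = 0` flagged. `first_peak` returns None on
monotone profiles. The RDF requires r_max ≤ half the box edge; the JM arm
must fit within half the box edge. Trajectory text files round-trip to the
written 3-decimal precision (0.001 Å, far below the bead radius); the
`.npz` container round-trips exactly.
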