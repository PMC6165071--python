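# Methods

This note records the models, numerical choices and known limitations of
`rinpipe` at the level of detail a user would need to interpret its
output or extend it.

## Ensembles and I/O

An ensemble is an ordered set of frames over a fixed atom table; model 1
of a multi-model PDB defines the table and later models are matched
positionally, so a model with a different atom count is rejected with an
error naming the offending model index.  Alternate locations other than
blank/'A' are dropped with a warning.  PDB parsing and serialisation go
through biotite; coordinates therefore carry the format's fixed-column
precision of 3 decimals (round-trips agree to 5×10⁻⁴ Å).  HETATM
ligand records are retained and addressable by residue name.  mmCIF,
compressed trajectory formats, insertion codes and multi-chain symmetry
are out of scope.

## Synthetic ensembles

The generators replace long MD trajectories with ensembles whose
statistical structure is known exactly, so each analysis stage can be
tested as a parameter-recovery problem.

**Backbone construction.** Chains are built residue-by-residue from
ideal internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
C–O 1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°,
CA–C–O 120.8°; ω = 180°) by NeRF placement, so the φ/ψ dihedrals
measured on the output equal the requested values to 10⁻³ degrees.  The
carbonyl O is placed in the peptide plane opposite the next residue's N
(torsion ψ + 180° about CA–C); the terminal residue's O uses its nominal
ψ the same way, so every residue carries exactly four atoms.  Side
chains, rotamers, solvent and energetics are not modelled; where an
analysis needs a side-chain atom (Ser OG, His NE2) or a ligand, pseudo
atoms are attached at fixed offsets and ride rigidly on their anchor.

**Displacements are residue-rigid.** Gaussian displacement fields are
sampled per residue (one 3-vector per residue per frame) and applied to
all atoms of the residue.  Residue-level correlations are then exact by
construction — appropriate because every downstream statistic
(cross-correlation, RMSF, PCA) operates on a per-residue Cα basis.  The
correlation structure is specified as within-set blocks and signed
cross-set blocks; the resulting correlation matrix is checked for
positive semi-definiteness at build time (tolerance −10⁻¹⁰ on the
smallest eigenvalue, reported on failure) and sampled through its
symmetric matrix square root, which makes draws bit-reproducible given
(spec, seed).

**Two-state cap switch.** The helix→turn transition of a cap segment is
a hard switch at a configurable frame — state A (φ, ψ) = (−57°, −47°),
state B (−75°, +150°) — matching the persistent, step-like switches seen
in secondary-structure timelines of cap-domain mutants.  A Markov-chain
alternative was considered and rejected as out of scope: the claims the
pipeline tests concern occupancy fractions, not kinetics.

**Planted observables.** H-bond plants reposition the acceptor along the
current donor→acceptor direction at 2.9 Å (bound) in a seeded random
subset of round(target·n_frames) frames and at 4.5 Å otherwise, so the
achieved occupancy equals the target to the nearest 1/n_frames.
Distance plants move the second atom along the existing axis to a
N(mean, sd) sample per frame; angle plants rotate the first atom about
the vertex in the plane of the current arms, preserving arm length.
Plants are applied after noise, in the order distances → angles, so a
later plant never disturbs an earlier one's target.

**Planted hub.** The network recovery construct folds an extended chain
so that 10 sequence-distant residues surround a hub residue on two
staggered rings (Cα–Cα 4.0 Å), each spoke rotated to point radially
outward so spokes touch the hub but not each other.  Motion follows a
single-factor model: hub–spoke correlation ρ = 0.65, spoke–spoke ρ² ≈
0.42.  With the conventional path-graph floor of 0.5 this makes the hub
the only conduit between spokes — the designed ground truth is "top
degree, hub flag, top betweenness".

## Observables

Superposition is a proper-rotation Kabsch fit (reflections corrected);
the essential-dynamics reference is the mean structure after an initial
fit to frame 0 and one refinement pass.  RMSD/RMSF default to backbone /
Cα bases respectively.  Rg is mass-weighted with a small built-in
element mass table.  SASA is Shrake–Rupley (via biotite) with radii
C 1.7, N 1.55, O 1.52, S 1.8, H 1.2 Å, probe 1.4 Å and 960 sphere
points (isolated-sphere error < 1 %, two-sphere overlap vs the analytic
spherical-cap formula < 2 %).  Series means ± sd discard a burn-in
fraction (default 5 %) to mirror the convention of excluding
pre-equilibration frames; set `burn_in: 0` to use the full series.
B = (8π²/3)·RMSF² is exact by definition.

## Geometry and occupancies

Angles are interior angles in degrees; dihedrals follow the IUPAC sign
convention (cis = 0°), with φ = C(i−1)–N(i)–CA(i)–C(i) and
ψ = N(i)–CA(i)–C(i)–N(i+1).  The attack-angle window is a closed
interval, default 110 ± 20°.

H-bond criteria are donor–acceptor distance ≤ 3.5 Å and, when a
hydrogen bonded to the donor is present, H–donor–acceptor angle ≤ 30° —
the conventional defaults of MD analysis tools.  Without hydrogens
(crystal-derived or synthetic backbones) the criterion falls back to
distance only.  Acceptors are restricted to N/O elements; carbon
"acceptors" occasionally reported in the literature can be scored with
an explicit opt-in (`allow_any_acceptor`), but are chemically
non-standard and excluded by default.  Note that histidine has an NE2
atom but no NZ2; the NE2 spelling is used throughout.

The secondary-structure classifier is deliberately *not* DSSP: a residue
is helix iff (φ, ψ) is within ±35° of (−57°, −47°) in a run of ≥ 4
consecutive such residues, strand iff within ±45° of (−120°, +130°) in a
run of ≥ 2, else "other"; chain termini are "other".  "Turn" is
approximated as not-helix over the segment of interest.  This preserves
the claim structure of helix→turn switching without hydrogen-bond-based
assignment; π/3₁₀ subclasses and exact DSSP parity are non-goals.

## Interaction network

The printed form of the interaction-strength formula omits the operator
between the contact count and its normalisation; the standard convention
I_ij = 100·n_ij/√(N_i·N_j) is used — it is dimensionless and makes the
2.5 % edge cutoff meaningful.  n_ij counts heavy-atom *pairs* within
4.5 Å; |i−j| ≤ 1 neighbours are excluded; N_i is per residue type,
dataset-derived (max observed n_ij for that type) unless a table is
supplied.  All of these are configurable.

Edge weights are w = −ln|C| (natural log — consistent with the
conventional printed value 0.69 at |C| = 0.5); the sign inside the log of
that printed expression is treated as a typo.  Betweenness is computed
on the weighted, correlation-filtered path graph, while degree counts
all retained contact edges; both raw (unnormalized) and normalized
betweenness are reported, the latter divided by (N−1)(N−2) with the sum
over unordered pairs j < k — note this is half the common undirected
convention, so the centre of a 3-node path scores 0.5.  The
Floyd–Warshall pass accumulates distinct shortest-path counts with a
10⁻⁹ tie tolerance on float path sums; zero-weight edges (|C| = 1) are
admissible but can make tie counts degenerate, which the planted
constructs avoid.  Closeness is (m−1)/Σd within a node's
m-node component.  By default one network is built from the
ensemble-average structure; per-frame networks can be built by passing
individual frames.  Community detection and suboptimal-path ensembles
are non-goals.

## PCA and free-energy landscapes

PCA diagonalises the 3n×3n covariance of superposed Cα coordinates
about the time mean.  Eigenvector signs are fixed by making each mode's
largest-magnitude component positive, for cross-platform determinism.
Per-residue contributions are the norms of each mode's 3-vector
components (squared contributions sum to 1).  The FEL is a 50×50
2-D histogram of the PC1/PC2 projections with ΔG = −k_BT·ln(P/P_max);
empty bins are masked (NaN), not ∞, and the most populated bin is
exactly 0.  Units are k_BT, with an optional temperature for kJ/mol
(300 K being the usual choice).  The basin-depth difference between two
planted basins estimates −ln(p₂/p₁); this peak-bin estimator is only
stable when basin widths exceed the bin width, which is how the recovery
checks sample their projections.

## Pipeline and determinism

The pipeline runs generate-or-load → observables → geometry → network →
PCA/FEL → report per system, then a side-by-side comparison.  A stage
failure aborts with the stage name and leaves prior outputs intact.
Floats in CSV/TSV/JSON outputs are written at 6 significant digits, and
each system's report carries a SHA-256 manifest of its output files, so
a config + seed reproduces byte-identical outputs (the config echo file,
which records the output directory, is deliberately outside the
manifest).  Per-system seeds are derived deterministically from the
master seed.

The built-in four-system demo emulates a wild-type/cap-mutant enzyme
bound to two substrate epimers on a 264-residue backbone at 150 frames —
sizes chosen so the full comparison runs in about a minute on one CPU.
Its planted conditions are the study conditions of the comparison it
mimics: cap (residues 161–190) turn fractions 3.4 / 62.8 / 4.6 /
84.1 %, backbone-expressible H-bond occupancies between the 161–165 and
240–245 regions, catalytic triad distance 3.7 Å for the active mutant
complex vs 7.0 Å otherwise, and attack angles 110° vs 75° (only the
former falls in the 110 ± 20° catalytic window).  Substrate-specific
distances (4.0 vs 6.5 Å for the substrate-oxygen–NE2 track) are
qualitative choices on the same pattern.

## What passing tests do and do not show

The synthetic generators share the analyses' own structural assumptions
(residue-rigid motion, ideal backbone geometry, hard conformational
switches, pseudo side-chain atoms).  Passing recovery tests therefore
demonstrates that the estimators are correct and well-calibrated on data
satisfying those assumptions — not that real trajectories satisfy them.
In particular: the demo's single unanchored helix amplifies cap motion
through a lever-arm effect (large absolute RMSD, PC1 share near 100 %,
many hubs in the regular helical contact lattice), so the demo's
absolute stability numbers are not comparable to a folded globular
protein's, while its occupancy and geometry recoveries are exact by
construction.  Reproducing trajectory-dependent absolute values (RMSD
means, PC percentages of real systems) is explicitly out of scope.
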