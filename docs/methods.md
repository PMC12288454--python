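# Methods

## The system and the questions

The package models a dimeric GntR/FadR-family repressor: each monomer has
an N-terminal winged helix-turn-helix DNA-binding domain (DBD, residues
1–63 of the 229-residue chain), a linker (64–79), and a C-terminal
effector-binding/oligomerisation domain (E-O, 80–229). Effector binding at
the C-terminal domain allosterically weakens operator binding at the
N-terminal domain. Three layers of analysis quantify how natural variants
perturb this machine: per-residue dynamics of the dimer in four ligand
states (APO, effector-bound E, DNA-bound D, doubly bound ED), a census of
substitutions across a panel of natural isolates, and equilibrium/kinetic
models of the binding and growth assays.

The domain boundaries above are a reconstruction: they are the unique
contiguous ranges consistent with the published residue→domain assignments
(positions 3, 15, 19, 24 in the DBD; 71 in the linker; 92, 128, 152, 180,
186, 220, 222 in the E-O domain) and with the 4/1/7 per-domain variant
split; no boundary table is published.

## Synthetic trajectories: elastic-network Gaussian sampling

Real microsecond all-atom trajectories are replaced by a Gaussian model
with exactly known second moments, which is precisely what the DCC, PCA
and network stages consume.

**Geometry.** Each monomer is a Cα bead chain laid on an α-helical curve
(radius 2.3 Å, 100° twist, 1.5 Å rise ⇒ 3.8 Å consecutive spacing and
near-in-sequence spatial contacts); the second chain is the first
translated 11 Å perpendicular to the helix axis, giving inter-chain
contacts of 6.5–8 Å at the interface. A seeded 0.02 Å jitter breaks exact
symmetry. This is a deliberately minimal architecture: it has the right
local contact statistics and a connected dimer interface, not the fold.

**Model.** An anisotropic elastic network is built on the beads: springs
of constant k (default 1 energy/Å²) join all pairs within 12 Å, plus any
planted "extra couplings". Displacements are drawn from N(0, Σ) with
Σ = τ·H⁺, where H is the 3n×3n Hessian, τ the temperature scale (default
1 Å²) and H⁺ the eigendecomposition pseudo-inverse with relative
tolerance 1e-8, which removes exactly the six rigid-body modes of a
connected network. More than six near-zero modes means a disconnected
network; the error names the residues outside the largest component.
Frames are reference + displacement; the exact Σ is returned with the
trajectory and serves as the oracle for every downstream stage. Sampling
is a pure function of spec + seed.

**Ligand states.** The four states differ only in planted springs: E adds
effector springs across the E-O domains, D adds DNA-clamp springs across
the DBDs, ED adds both; APO adds none. Clamps tie every even-separation
residue pair within the domain in each monomer plus every second residue
to its counterpart in the other monomer, at 20× the base spring constant.
State seeds are base seed + state index.

A mechanical subtlety fixed this design. In a superposed harmonic model,
long-range |C| is carried by the softest collective modes, so adding a
stiff *bridge* between two domains usually damps exactly those modes and
lowers the cross-domain correlation block — and a single spring acts only
along the bond direction, so it cannot beat strong baseline
anti-correlated bending either. Internal *rigidification* of the
ligand-engaged domain does the opposite: it concentrates the dimer's
fluctuations into coherent inter-domain motion and raises the DBD×E-O |C|
block, which is the planted direction downstream stages must recover.
Consequently a planted direct spring raises the pairwise |C_ij| only for
pairs whose baseline coupling is weak (e.g. a DBD residue of one monomer
against an E-O residue of the other); the property tests use such a pair.

**What the generator does not emulate:** anharmonicity, solvent and
thermostat effects, ligand chemistry, conformational switching, and the
actual fold. Passing tests show that the analysis stack recovers known
second-moment structure from finite sampling — not that it would resolve
the real system's biology.

## Trajectory metrics

Superposition is single-pass least-squares (Kabsch SVD, proper rotations
only) onto a user-supplied reference; an iterated-mean option exists but
the deterministic single pass is the default. RMSD is per frame against
the reference; RMSF per residue about the trajectory mean; no
equilibration discard by default because the synthetic process is
stationary (a frame slice is available for real data). DCC uses full 3D
displacement dot products per Cα (not per coordinate). Residues with zero
displacement variance get diagonal 1 / off-diagonal 0 by convention and
are flagged. Essential dynamics diagonalises the 3n×3n coordinate
covariance (population normalisation, matching DCC); eigenvector signs
follow a fixed convention (largest-magnitude component positive) so that
porcupine arrows are reproducible. Porcupine arrows scale the chosen mode
by the observed projection range (max−min), i.e. the trajectory's full
excursion along that PC — there is no single standard convention for
arrow magnitude, so this documented choice is configurable — and are
masked below 3.5 Å by default.

## Dynamical networks and suboptimal paths

Nodes are residues; an edge joins pairs within 8.0 Å Cα–Cα in ≥ 75% of
frames (both configurable; the classic 4.5 Å heavy-atom criterion is
meaningless on Cα-only models) with |C_ij| ≥ 0.01, weighted
w = −ln|C_ij| (natural log, the standard dynamical-network convention).
Sequence-adjacent pairs within a chain are excluded by default so trivial
backbone correlation does not dominate paths. Communities come from
Girvan–Newman divisive clustering with distance-weighted edge betweenness;
the returned partition is the dendrogram level (including the trivial
one-community level) maximising weighted modularity, computed on the
affinity 1/max(w, 1e-6); ids are assigned by lexicographically smallest
member, making the labelling deterministic and permutation-invariant.

Suboptimal paths: sources default to all DBD residues, sinks to all E-O
residues, over both monomers. L_opt is the minimum Dijkstra weight over
all source–sink pairs; the ensemble is every simple source→sink path with
weight ≤ L_opt + δ, enumerated depth-first with branch-and-bound pruning
on exact remaining-distance lower bounds (multi-source Dijkstra from the
sinks), so the enumeration is exhaustive, and verified against brute-force
simple-path enumeration on small random graphs. δ defaults to 0.2·L_opt
(the study's tolerance is not published); the cap of 100,000 paths sets an
explicit truncation flag rather than failing silently. Histograms use 20
equal bins with origin fixed at L_opt. Cross-state comparison reports
count, L_opt, mean/median weight, classifies right/left shifts by median
difference against a stated tolerance, and ranks states by count.

On the default wild-type fixtures, the APO state (the loosest
construction) carries the most suboptimal paths in the network built from
the analytic covariance and reference-geometry contacts; this is a
property of the packaged construction, documented and tested as such, not
a theorem about elastic networks. Empirical path counts from
1500-frame trajectories are small integers with sampling noise and are
reported rather than asserted; the robust trajectory-level signatures are
the raised DBD×E-O |C| block and the right-shifted (longer) path
distributions of the effector-bound states.

## Variant census

Records are filtered to exactly 229 residues before alignment (a
permissive mode disables this), mirroring the upstream retrieval
procedure; records with non-amino-acid characters are dropped with a
warning. Each record is aligned to the reference by global
Needleman–Wunsch (BLOSUM62, gap open 10, extend 0.5 — Biopython
`PairwiseAligner`); substitutions are called only at columns where both
residues are aligned and differ, in reference coordinates; indels are
reported separately and excluded from the substitution census; alignment
identity < 50% attaches a low-homology warning. Pairwise-vs-reference
alignment was chosen over an MSA for determinism and O(panel) cost; an
MSA mode is future work. Unique variants are keyed by (position, ref,
alt) with sorted carrier lists, so the report is invariant to record
order.

The packaged default panel plants the 12 published substitutions among
340 isolates with disjoint carrier sets summing to 42 — the published
census prints only the totals, so the per-variant split (2, 6, 3, 2, 4,
2, 5, 6, 4, 3, 2, 3) is a fixture, not biology.

## Assay models

Gel-shift DNA titrations use the Hill form f = Pⁿ/(K_Dⁿ+Pⁿ);
thermophoresis effector titrations use the exact 1:1 quadratic isotherm
(rationalised root, numerically stable for P ≪ L) because protein is
held at 500 nM, which is not negligible against all variant K_Ds; the
depletion-free form is retained for comparison. Fits are nonlinear least
squares (scipy, trust-region with positivity bounds) with deterministic
initialisation — K_D starts at the x whose response is nearest 0.5, n at
1 — standard errors from the Jacobian, and an explicit convergence flag.
Hill coefficients are treated as free parameters throughout; no published
value is assumed.

"Complete release" in effector titrations is bound fraction ≤ 0.05 at the
lowest tested concentration (the gel-based published call is qualitative;
the threshold is configurable), with an explicit not-released result and a
warning on increasing series.

Growth kinetics: the maximal specific rate is the slope of ln(OD) over
the sliding window (default 5 points) with the highest R²; doubling time
is ln 2 / rate. Two lag definitions are implemented: the default
threshold rule (first time smoothed OD exceeds 2× its initial value,
robust to plate-reader noise) and the classic tangent intercept
(extrapolating the max-rate window back to the initial ln OD), which
recovers the generative lag of a lag+exponential curve exactly; the
threshold lag trails it by about one doubling. Constant or non-growing
series return a degenerate flag instead of numbers. Fluorescence is
reported as (F − F_bg)/OD with optional background subtraction.

Curve noise is multiplicative Gaussian (responses are positive);
truth parameters are stored beside every synthetic curve.

## Problem sizes and numerical tolerances

The test suite runs the dynamics stack on a 40-residue dimer (20 per
monomer) — large enough for three domains, a dimer interface and
non-trivial networks, small enough that 5000-frame covariance recovery
(max-norm 0.05 on DCC, 10% on top-5 eigenvalues, 10% on RMSF), the
1500-frame four-state suites, and full Girvan–Newman dendrograms all run
in seconds. The end-to-end pipeline demo uses 16 residues per monomer and
300 frames. Path-enumeration equivalence is checked against brute force
on 50 random connected graphs of ≤ 12 nodes at δ ∈ {0, 0.2·L_opt, ∞}.
Binding-fit recovery uses 100 seeded curves per model at 5% noise
(median relative K_D error < 10%) plus a grid-search cross-check
agreeing within one grid cell. Superposition is verified against a
multi-start numeric minimiser over rotations to 1e-3 Å.

## Known limitations

Gaussian trajectories cannot show anharmonic or switching behaviour, so
state differences are strictly second-moment constructions. The toy
geometry shares only local statistics with the real fold; community
counts and path counts are not comparable to figures derived from real
trajectories. The variant scanner is substitution-oriented; indels are
reported but not classified into the census. Live-database homolog
retrieval is out of scope — the scanner consumes any FASTA panel.
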