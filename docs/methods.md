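# Methods

## Conventions

Coordinates are in Å, times in ns, masses in Da, voltages in mV, currents in
pA, conductances in nS, capacitances in pF (so nS × mV = pA). The membrane
normal is +z, leaflets sit at ±z, and the channel axis is on z; all angle
conventions follow from this. A "heavy atom" is any atom whose element is
not H; when a topology lacks elements they are inferred from the leading
alphabetic character of the atom name, with an override table for two-letter
elements. Selections always resolve in ascending atom-id order so that
every reduction (COM, minimum distance, correlation) is deterministic.
Analyses operate on unwrapped, whole-molecule coordinates; the distance
primitives optionally apply the minimum-image convention for an orthorhombic
box, but the synthetic systems are built whole and never need it.

## Lipid-binding analysis

**Contacts.** A residue contacts a headgroup moiety in a frame when any of
its heavy atoms lies within the moiety-class cutoff of any moiety atom:
4.0 Å for the P1/P4/P5 phosphates, 3.5 Å for the 2-/3-/6-hydroxyls. Any
heavy atom of the residue counts by default; a side-chain-only option
exists because conventions differ. Contact probabilities are fractions of
frames in the analysis window, which defaults to the trailing 40 % of the
trajectory (the convention of analysing the last 200 ns of a 500-ns run);
an absolute window can be supplied.

**Binding events.** The criterion is deliberately explicit because event
counts feed the SEM: a bound run is a maximal stretch with headgroup-COM to
site-COM distance ≤ d_bind (default 6 Å), unbound gaps ≤ rejoin_gap
(default 5 ns) are merged, and runs shorter than min_dwell (default 50 ns)
are discarded. The 6-Å default separates states cleanly at toy scale, where
bound poses sit near 4 Å and initial placements are ≥ 15 Å away; all three
numbers are configurable. One surviving (lipid, site, monomer) run is one
event; event tables aggregate as mean ± SEM with SEM = sample SD/√n (0 for
n = 1).

**Occupancy.** The occupancy grid spans the selection's bounding box over
the window, padded by one voxel, with default 1.0-Å spacing. Voxel
membership is half-open [lower, upper) per axis so boundary atoms are
assigned deterministically; a voxel's value is the fraction of frames in
which it holds at least one selected atom centre.

## Correlation networks and communities

Nodes are Cα atoms (the toy protein has exactly one bead per residue).
Edges connect residue pairs whose distance stays within a cutoff for at
least a persistence fraction of frames — literally Cα–Cα ≤ 4.5 Å for ≥ 75 %
of frames by default, with a residue-minimum-heavy-atom mode provided
because 4.5 Å is tight for Cα pairs. Each edge carries the Pearson
fluctuation correlation C_ij and the conventional dynamical-network edge
length w_ij = −log |C_ij| (|C| clipped at 1e-6).

**Alignment.** Before correlating, frames can be rigid-body superposed
(all selected nodes, unit weights). Every frame is first superposed onto
frame 0, then iteratively onto the running mean structure to a fixed point.
Seeding from a single canonical frame matters: starting from the mean of
arbitrarily oriented frames makes the fixed point depend on those
orientations, whereas the canonical seed makes the whole procedure
equivariant — per-frame rigid motion only rotates the result globally,
which dot-product correlations cannot see. For synthetic trajectories the
generator adds no global motion, and alignment is disabled in the planted
round-trips: superposing a small node subset would project out exactly the
shared displacement modes that constitute the signal.

**Community detection.** The detector runs divisive edge-betweenness
(Girvan–Newman) with betweenness computed on the w_ij edge lengths; among
betweenness ties — ubiquitous in dense graphs, where every node pair uses
its direct edge — the longest (weakest-correlation) edge is removed first,
then ties break on edge id. Because a divisive sequence only reaches
hierarchical partitions, the candidate set is augmented with agglomerative
(Clauset–Newman–Moore) and Louvain partitions (eight fixed seeds), and the
best candidate receives deterministic greedy single-node refinement. The
returned partition maximises Newman–Girvan modularity computed with edge
strength |C_ij|; ties prefer fewer communities, and community ids follow
each community's smallest node index. On a reference family of ≤ 8-node
graphs this matches brute-force enumeration over all partitions. Graphs
with no edges return singleton communities with Q = 0.

**The coupling observable.** The VSD–pore coupling readout is the number of
distinct communities covering a tag set — 1 when S4, the S4–S5 linker, S6
and pre-Helix-A move as a single community (coupled), several when they
fragment (decoupled). In the synthetic round-trips this is computed over
the Site-O4 interface residues of one monomer with a 13-Å neighbour cutoff:
the pseudo-channel has one bead per residue on ~3-Å spacing, so the
atomistic 4.5-Å criterion would produce chain-like graphs, and modularity
maximisation always fragments long chains regardless of how uniform their
correlations are. The compact interface cluster (which is where the
physical community lives) yields a dense graph on which the coupled plant
is genuinely one community and a three-group plant splits by correlation
strength. The 4.5 Å / 75 % defaults remain untouched for atomistic input.

## Helix-pair orientation

The helices A+B axis is the dominant principal axis (top singular vector)
of the combined Cα cloud, sign-fixed to point from the Helix-A centroid
toward the Helix-B centroid; at least three Cα per helix are required and a
near-spherical cloud is a geometry error. θ(t) = arccos(axis·ẑ) is reported
unfolded on [0°, 180°] — not reflected at 90° — because the solvent-exposed
and bilayer-interacting poses straddle 90°. Reported statistics are the
frame-level mean and SD over the analysis window; pooling across monomers
is available, and the alternative (SD across monomer means) is deliberately
not the default. The membrane normal is fixed to +z; for real trajectories
a per-frame normal can be supplied.

## Synthetic trajectory generator

The toy system is a tetramer of pseudo-helices: transmembrane domains as
vertical 10-bead rods around the pore axis, intracellular domains below the
lower leaflet, and helices A+B as a single collinear in-plane rod (rest
angle ≈ 90°). Each residue is one "CA" bead carrying its domain tag. Per
monomer, two binding sites are declared: a Site-O4 analogue (cytoplasmic
ends of S4 and S6, the S4–S5 linker, pre-Helix-A) and a Site-O2 analogue
(distal Helix-B). Lipids are bead chains — one head bead plus two tail
beads — at 17 Å above/below the membrane centre; PIP₂ lipids additionally
carry the six headgroup moieties as distinct beads (P beads for P1/P4/P5, O
beads for the hydroxyls) on a 1.2-Å ring. The default composition mirrors
the study conditions: 364 lipids per leaflet with a 2.2 % PIP₂ fraction
(8 PIP₂ per leaflet), every PIP₂ headgroup initially ≥ 15 Å from every site
COM. Tests use a smaller patch (60 lipids/leaflet in a 110-Å box) purely
for speed; the placement constraints are identical.

Free lipids random-walk in their leaflet plane (σ = 0.5 Å/frame) and are
reflected out of a 9-Å shell around every site COM, so unplanned lipids can
never satisfy the 6-Å binding criterion. A planted lipid walks until its
approach start, interpolates to its bound pose, then holds the prescribed
headgroup-COM distance (default 4 Å) with 0.3-Å Gaussian jitter for the
dwell. Planted per-moiety contact fractions are realised exactly (to frame
rounding) over the analysis window ∩ dwell: on "contact" frames the moiety
bead sits 0.7–0.8 Å inside its class cutoff from the planned residue, on
the remaining dwell frames 2 Å outside it. Frames are stored every 1 ns by
default.

Correlated-motion trajectories displace each residue by its group's shared
3-vector latent mode (per-group amplitude, default 1 Å) plus independent
Gaussian noise (default 0.1 Å); an inter-group coupling c mixes a common
latent into every group as √(1−c)·independent + √c·common. Planted tilt
rebuilds each monomer's A+B rod every frame along a direction whose angle
to +z is drawn from N(θ_mean, θ_sd), preserving the A→B bead order so the
sign convention is testable. All generators are bit-reproducible for a
fixed seed.

**What the generator does not emulate.** There is no force field, solvent,
electrostatics, or conformational change; the protein is rigid outside the
planted modes; lipids do not exchange leaflets or crowd each other; binding
is scripted, not emergent. Passing round-trips therefore demonstrate that
the *analysis* machinery recovers known truth — occupancies, contact
fractions, dwell intervals, partitions, tilt distributions — not that the
physics of PIP₂ binding is reproduced.

## Gating model and voltage-clamp analysis

The channel is a single non-inactivating first-order gate, dp/dt =
(p∞(V) − p)/τ_act(V) with p∞(V) = 1/(1 + exp((V₁/₂ − V)/k)), solved in
closed form per constant-voltage segment with the gate state carried across
segments (no integrator error). Current is I = g_max·p·s·(V − E_K) +
g_leak·(V − E_leak) + Gaussian noise (default SD 2 pA); s(t) is the
VSP-style depletion factor exp(−t/τ_dep(V)) during the long depolarizing
segment, reset between sweeps (the 2-min inter-sweep interval regenerates
PIP₂). A single gate rather than a p⁴ (sigmoidal-onset) model is used
because only the analysis mathematics is under test and the current is
non-inactivating; capacitive transients and series resistance are not
modelled. E_K defaults to −84 mV, the Nernst potential at room temperature
for 140 mM internal / 5.4 mM external K⁺; the driving-force convention is
recorded in every output.

The analysis chain mirrors standard whole-cell practice. Leak is linear:
either fitted through the channel-free segments of each sweep (holding and
the brief −60 mV step of the VSP protocol) or through the mean currents of
a channel-free reference cell line. Conductance uses the steady-state
current (mean of the final 10 % of the step) divided by (V − E_K) and is
normalised by its maximum. The Boltzmann fit is deterministic: V₁/₂
initialised at the voltage whose G/G_max is nearest 0.5, k at 8 mV,
trust-region least squares with tight tolerances, and a convergence flag
(gradient norm < 1e-8) instead of exceptions. Activation τ is a
single-exponential fit A(1 − e^(−t/τ)) + B over the 10–100 % window of the
step (skipping any residual fast component); non-rising traces are flagged,
not raised. The depletion readout is I(end)/I(peak) per voltage, with
I(end) the mean of the final 100 ms and the peak taken after step onset.

Note one bias worth knowing: normalising by the maximum over a finite
voltage grid understates G_max whenever the curve has not saturated by
+20 mV, shifting a subsequent fit slightly depolarized. For a V₁/₂ near
−30 mV the effect is ~0.003 mV; for a right-shifted variant (V₁/₂ ≈ −14 mV)
it reaches ~0.1 mV. The worked-example refits therefore operate on the
generated G/G_max curve itself, which is how such curves are fit in
practice once normalised.

## Problem sizes

The shipped tests and the acceptance script run at toy scale by design:
60-lipid leaflets, 150–1250-frame trajectories, 12-node community networks,
13 voltage steps. These sizes give exact or 3σ-tight recoveries for every
planted quantity while keeping the whole suite in the tens of seconds.

## Known limitations

- The baseline trajectory reader handles multi-model PDB (plus a JSON
  sidecar for times, box and domain tags); binary dialects (DCD/XTC) are
  accepted only through the same in-memory contract, not parsed natively.
- Non-orthorhombic boxes, energies and kinetics (k_on/k_off) are out of
  scope.
- Whether real contact analyses should use side-chain-only atoms, and
  whether replicate correlation matrices should be averaged rather than
  concatenated, are left as options (`side_chain_only`, per-replicate
  analysis) with the stated defaults.
- The tail-current route to G–V curves is not implemented; steady-state
  step currents are used.
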