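# Methods

This note documents the models, estimators, numerical choices and known
limitations of `tgblister`. It is written for a reader who wants to know
exactly what each reported number means and what the passing test suite does
— and does not — demonstrate about real coarse-grained (CG) trajectories.

## The system and its conventions

The package analyses hydrated POPC bilayer patches containing a few percent
triolein (TO), represented at CG resolution: each bead is the only
observable, positions are in nm, and the membrane normal is z. After
centering, the midplane is z = 0 and the phosphate planes sit near ±1.9 nm.
CG dynamics sample configuration space faster than atomistic dynamics; all
rates and durations are quoted in *scaled* time, simulation time multiplied
by a conventional factor of 4. The factor is a single configuration constant
(default 4), stored in every trajectory and echoed in every report.

Trajectories are multi-frame fixed-width GRO (velocities ignored); the
per-bead role table (molecule id, species ∈ {POPC, TO, W}, role ∈ {PHOS,
GLYC_A1, GLYC_B, GLYC_A3, TAILc_k, W}) travels either as a TSV or encoded in
the GRO atom/residue names, from which it can be reconstructed exactly.
POPC carries one phosphate, two glycerol beads and two 4-bead tails; TO
carries three glycerol beads (two α, one β) and three 4-bead tails. Binary
formats (XTC/TRR) are out of scope.

## The synthetic trajectory generator

The generator is a statistical emulator, not a simulator: no force field, no
integrator, no energies. It places beads so the distributions the analyses
estimate are *planted* with known values, and writes those values to a
ground-truth manifest. Every preset mirrors a row of the published
simulated-system table (lipid counts, patch size, scaled duration, measured
flip-flop rate used as the planted hopping rate). The 9× and 16× rows print
no rate; those presets reuse the 4×5.2% value (0.31 µs⁻¹).

Placement model, per frame:

* **POPC** — phosphate at ±1.9 nm on a jittered lattice; glycerol beads 0.45
  and 0.70 nm deeper; each tail is a straight 4-bead chain (0.47 nm spacing)
  along a direction drawn from a von Mises–Fisher (vMF) distribution about
  the inward leaflet normal.
* **Interfacial TO** — glycerol COM 0.55 nm below the phosphate plane; the β
  bead 0.25 nm deeper than the α beads (this depth offset is what the
  hydration analysis must detect); tails vMF about the inward normal.
* **Midplane TO** — COM z uniform in ±0.4 nm, xy uniform outside the
  aggregate footprint; tails uniformly random axes (isotropic).
* **Aggregate TO** — a planted disc: molecule COMs resampled each frame
  uniformly inside radius R − 0.1 nm and |z| ≤ thickness/2 − 0.15 nm, with
  bounded bead offsets so every glycerol bead lies strictly inside the
  planted cylinder (the planted-count oracle is exact). Membership is fixed.
* **Water** — an ideal gas filling the two slabs beyond ±(1.9 + 0.25) nm at
  8.35 beads/nm³ (the MARTINI 4-water bead convention), resampled every
  frame. The exclusion gap around the membrane is the only water–lipid
  correlation.
* **Thermal noise** — Gaussian jitter (σ = 0.1 nm) on every lipid bead
  except aggregate glycerols (bounded offsets there, see above).

**Hopping.** Inter-leaflet translocation is a homogeneous Poisson process at
the *system-wide* planted rate (the published rates are per system, in
events/µs), each event assigned to a uniformly chosen non-aggregate TO and
given the only admissible direction, so directions alternate per molecule.
A hop is realised as a deterministic 3-frame transit through the middle
region (z = ∓0.45, 0, ±0.45 nm) followed by one guaranteed interfacial frame
in the destination leaflet; without that frame, two back-to-back hops of the
same molecule could hide the intermediate arrival from any detector and bias
rate recovery low by a few percent. Per-molecule clocks are not independent
— only the system-wide rate is calibrated, matching what the published table
reports.

**Occupancy.** Outside transits, each free TO is in the middle region with
per-frame probability `to_center_fraction` (i.i.d. Bernoulli; default
0.27/1.27 so the middle/interface occupancy *ratio* is 0.27). Because
transits also occupy middle-region frames, the measured occupancy slightly
exceeds the Bernoulli parameter when hopping is on; occupancy-recovery
checks therefore run with hopping off. The i.i.d. choice makes frames
independent, which is what makes the binomial standard errors in the tests
exact; real trajectories are autocorrelated and would need block averaging.

**Splay calibration (frozen).** Tail *directions* are vMF; the analysed
observable is the tail *vector* (terminal bead − glycerol bead). Since the
chain is anchored at the jittered glycerol bead itself, the vector carries
one endpoint's N(0, σ²) jitter on top of the direction. The vMF
concentrations were calibrated once against this observable by 3×10⁷-sample
Monte Carlo and then frozen: κ = 3.025 for interfacial TO (fully-splayed
fraction 5.00%, partially-splayed 23.6% at the 90° threshold) and κ = 6.0
for POPC (inter-tail angle > 90° in 3.1% of molecule-frames). Midplane tails are
isotropic, for which the class fractions are 25/50/25% in closed form
(isotropic noise leaves an isotropic vector isotropic).

What the generator does **not** emulate: lateral diffusion (anchors are
static), semi-isotropic box fluctuations (the box is fixed), water–lipid
structure beyond the exclusion gap, aggregate growth/exchange (membership is
planted), and any energetics. Passing recovery tests therefore demonstrate
estimator correctness against known truth — not force-field realism.

## Region partitioning

Number-density profiles along z use midplane-centred bins (default 0.1 nm)
normalised per bin volume and per frame; the bin grid always covers all
selected beads, so the profile integral equals the mean group count exactly.

The bilayer is divided into two interfacial regions and one middle region
from the TO-glycerol profile: the profile is smoothed (3-bin moving
average); the interfacial peak on each side is located — inside a window of
0.4–1.6× the phosphate half-distance when a phosphate profile is available
(necessary because in the large patches the interfacial TO population is
two orders of magnitude below the central one), otherwise as the outermost
local maximum above 2% of the side maximum — and each boundary is placed at
the minimum of the smoothed density between the central maximum and that
peak. Ties across a flat plateau resolve to the plateau centre, which keeps
mirror-symmetric profiles mirror-symmetric. If there is no central
population (central density below 5% of the mean interfacial peak), the
boundaries fall back to ±0.5 × (half the phosphate peak-to-peak distance).
A COM exactly on a boundary is classified MIDDLE (conservative tie-break).

The **partition coefficient** is defined as the time-averaged middle-region
TO glycerol-COM count divided by the time-averaged interfacial count. The
standard error is the delta-method propagation of the binomial occupancy
fraction under frame independence — exact for the generator, optimistic for
autocorrelated data. Zero interfacial occupancy in every frame makes the
ratio undefined and is reported as such.

**Bilayer geometry**: thickness is the distance between per-leaflet
phosphate density peaks, refined by the phosphate COM within ±2 bins of the
peak bin (recovering planted jitter-free planes exactly rather than to bin
precision); area per lipid is 2·Lx·Ly/N with and without TO in N.

## Flip-flop detection

A molecule's per-frame region state (LOWER/MIDDLE/UPPER) is classified from
its glycerol-backbone COM z. The detector is a three-state machine with a
"last interfacial state" memory: an event fires when the opposite interface
is first reached; interface → middle → same-interface excursions count
nothing (excursions are counted as zero events, not fractions); initial
middle frames are skipped. No minimum-dwell filter is applied — the memory
already suppresses boundary-recrossing double counts. Rates are system-wide
events per µs of scaled sampling time with Poisson standard error √N/T; a
per-molecule normalisation is also reported. Deleting frames can only
destroy alternations of the interfacial subsequence, never create them, so
subsampling never increases the event count (property-tested).

## Conformation

Each tail vector joins a chain's glycerol bead to its last tail bead, under
the minimum image. TO conformations are classified from the two
adjacent-tail angles θ₁₂ (sn1–sn2) and θ₂₃ (sn2–sn3): FULL if both exceed
the threshold, PARTIAL if exactly one, NOT otherwise. The threshold is 90°
by default — chosen because the published POPC comparison uses 90° — and is
configurable and echoed in every report. Region assignment per
molecule-frame reuses the flip-flop region machinery (single source of
truth). Bond order parameters are the standard P₂ = ½(3cos²θ − 1) against
the leaflet normal (±z by glycerol-COM sign; P₂ itself is sign-insensitive).

## Hydration

g(r) of water around each TO glycerol bead role uses minimum-image
distances, exact shell volumes 4π/3·(r₊³ − r₋³) (the 4πr²dr approximation
fails in the first bins), and the global mean water density; defaults
dr = 0.02 nm, r_max = 1.5 nm. Only interfacial TO molecule-frames enter the
α/β comparison (configurable). Coordination numbers integrate 4πρ∫g r²dr by
trapezoid over the full [0, r_cut] interval (endpoint interpolated);
"first-minimum" cutoffs locate the minimum after the first maximum of the
smoothed g(r) and refuse to guess when g is monotone. With slab water the
g(r) of a buried bead does not plateau at 1; the α/β *ordering* of
coordination numbers is the meaningful readout, mirroring the planted β
depth offset.

## Aggregate detection and sizing

Midplane TO glycerol COMs are clustered by single linkage at a fixed
xy-distance cutoff under the minimum image (connected components of the
threshold graph — deterministic, with an exact planted-partition oracle).
Clusters are unwrapped across the periodic boundary by breadth-first
traversal with minimum-image displacements. The largest cluster's diameter
uses the uniform-disc relation D = 2√2·Rg (Rg² = R²/2 for a disc), with the
convex-hull diameter reported alongside; its area fraction is π(D/2)²/area.

Cutoff choice: the function default is 0.8 nm (a first-neighbour CG bead
distance). At the planted aggregate densities (0.7–0.9 molecules/nm² in xy)
a 0.8 nm COM graph is far below the continuum percolation threshold (mean
degree ≈ 1.9 versus the ≈ 4.5 needed) and the planted disc would fragment;
pipeline-level analyses therefore use 1.8 nm, which gives mean degree ≥ 7 at
every planted density and a measured sizing bias ≤ 4% (−0.2% at the 17 nm /
224-molecule geometry). Clusters below `min_size` (default 5) are excluded
from aggregate counts but still listed, so cluster sizes always sum to the
midplane TO count.

The interface↔middle **exchange rate** counts boundary crossings of TO COMs
in both directions per scaled µs; a direct interface-to-interface jump
between consecutive frames counts as two crossings, so every completed
flip-flop contributes exactly two exchanges.

## Blister theory

The monolayer interfacial free energy is F = A·[γ + 2κ_m(H_m − H₀)²]; for
insoluble amphiphiles γ → 0 and F is minimised at H_m = H₀, giving a
characteristic blister radius 1/H₀. H₀ comes from the packing parameter
P = v/(a·l) through a spherical-shell relation. Two standard candidates
were evaluated against the expected POPC blister radius ≈ 13.9 nm with the
frozen POPC geometry (v = 1.26 nm³, a = 0.64 nm², l = 1.75 nm, P = 1.125):
linear (P − 1 = H₀l → 14.00 nm) and quadratic shell
(P − 1 = H₀l + (H₀l)²/3 → 14.56 nm). Both land within ±1 nm; the linear
relation is the closer one and is frozen as the default. The relation used
is echoed in every output; H₀ = 0 returns a planar/unbounded sentinel rather
than raising. γ defaults to 42.5 mN/m (midpoint of the 35–50 mN/m bare
oil–water range) where a bare interface is modelled and to 0 for
lipid-coated interfaces; unit conversion uses k_BT at 323 K.

## Pipeline

`BilayerAnalysis` runs centering → profiles → region partition → partition
coefficient → flip-flop (TO and POPC) → splay → hydration → aggregate →
theory, and returns a results object whose `summary()` prints the standard
table and whose `save()` writes a versioned JSON report plus TSV tables (and
SVG plots on request — all outputs are text). Every default is echoed into
the report metadata; the generator config, when used, is stored with its
SHA-256. The default equilibration discard is the first 2 µs of scaled
time, overridable; if the discard would leave fewer than two frames the full
trajectory is used and a warning is recorded. Reports are byte-identical
under a fixed seed.

## Problem sizes

The verification suite runs at desk scale by design: rate-recovery checks
use the full tabulated durations of the small systems (192/180/24 µs scaled,
20 seeds each); occupancy and splay checks use ~2000-frame runs; aggregate
sizing uses 101 frames of the 37×37 nm patch. These sizes put the planted
values well inside three standard errors of their estimators, which is the
acceptance tolerance throughout.

## Known limitations

* The generator's frame-independence makes all quoted standard errors
  exact for synthetic data but optimistic for real, autocorrelated
  trajectories.
* The partition-coefficient estimator is one admissible reading of a
  middle/interface occupancy ratio; other estimators (free-energy based,
  per-molecule) would differ.
* The splay-class rule (both/exactly-one/neither above one threshold) is the
  most parsimonious three-class scheme over (θ₁₂, θ₂₃); richer TO conformer
  taxonomies (tuning fork, chair, trident) are intentionally not
  reproduced.
* Aggregate sizing assumes a roughly disc-shaped largest cluster; strongly
  anisotropic aggregates would need the convex-hull diameter instead.
* Orthorhombic, fixed boxes only; no pressure-coupling fluctuations.
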