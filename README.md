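# tgblister

Quantitative analysis of **triglyceride "blisters" in lipid bilayers** from
coarse-grained (CG) trajectories — with a seeded synthetic-trajectory
generator that plants known ground truth so every estimator can be verified
by parameter recovery.

## The scientific problem

Triolein (TO) dissolves in a POPC bilayer only up to ~3%. Above that limit
the excess neutral lipid is sequestered between the two leaflets as a
disordered, disc-shaped midplane aggregate (a "blister") — the same physics
proposed for nascent lipid droplets in the ER membrane and for the mobile
lipid NMR signal of activated cells. Characterising this behaviour from CG
trajectories requires a specific set of measurements, all provided here:

* **Density profiles & region partition** — number densities of the TO
  glycerol backbone, POPC phosphate and glycerol along the bilayer normal;
  the bilayer is split into two interfacial regions and a middle region at
  the minima of the (smoothed) TO-glycerol profile.
* **Flip-flop kinetics** — an event is recorded each time a TO
  glycerol-backbone centre of mass translocates from one interfacial region
  to the other; rates are events per µs of scaled sampling time (CG time ×4).
* **Partition coefficient** — time-averaged middle/interfacial occupancy
  ratio of TO glycerol COMs (≈0.27 below the solubility limit).
* **Tail splay** — the angles θ₁₂, θ₂₃ between adjacent tail vectors
  classify TO molecule-frames as fully / partially / not splayed (threshold
  90°); POPC inter-tail angles provide the two-tailed reference.
* **Glycerol hydration** — water RDFs g(r) and first-shell coordination
  numbers around the α1, β, α3 glycerol beads; the β bead sits deeper and is
  the least hydrated.
* **Aggregate detection** — PBC-aware single-linkage clustering of midplane
  TO; disc diameter D = 2√2·R_g, area fraction, coalescence (cluster-count
  series) and interface↔aggregate exchange rate.
* **Blister theory** — Helfrich interfacial free energy
  F = A[γ + 2κ_m(H_m − H₀)²] with the spontaneous curvature H₀ estimated
  from the packing parameter P = v/(a·l); for POPC defaults the
  characteristic blister radius is 1/H₀ ≈ 14 nm.

The synthetic generator emulates every published system (2.3% and 5.2% TO,
4×/9×/16× patches up to 37×37 nm, symmetric-leaflet controls), planting the
hopping rate, centre occupancy, splay-dispersion parameters and — for the
large patches — a 17 nm disc aggregate, and exports a ground-truth manifest.
See `docs/methods.md` for the full model and estimator documentation.

## Worked example

```python
from tgblister import BilayerAnalysis

model = BilayerAnalysis.from_preset(
    "UNI2", seed=7, generator_overrides={"duration_scaled_us": 30.0})
results = model.fit()
print(results.summary())
```

prints

```
Triolein–POPC bilayer analysis
==================================
frames analysed       : 518 (discarded first 2.0 µs scaled)
time scale factor     : 4.0
region boundaries (nm): [-0.75, +0.85]
bilayer thickness (nm): 3.80 ± 0.001
area per lipid (nm²)  : 0.689
partition coeff (mid/interface): 0.305 ± 0.013
flip-flop rate TO    : 1.146 ± 0.203 events/µs (32 events / 27.9 µs)
flip-flop rate POPC  : 0.000 ± 0.000 events/µs (0 events / 27.9 µs)
splay interface      : NOT=0.714  PARTIAL=0.235  FULL=0.051
splay middle         : NOT=0.268  PARTIAL=0.502  FULL=0.230
splay overall        : NOT=0.610  PARTIAL=0.297  FULL=0.093
POPC inter-tail >90°  : 0.0319
hydration N (α1, β, α3): 19.67, 9.80, 19.86
aggregate: modal count 0, mean diameter 0.00 nm, area fraction 0.000, exchange 38.61 /µs
theory: P = 1.125, 1/H₀ = 14.0 nm (linear relation)
```

Reading it: this 2.3% TO patch (6 TO / 256 POPC, 30 µs scaled) has a 3.80 nm
bilayer with region boundaries at the TO-density minima; the detector
recovers the planted flip-flop rate of 1.15 events/µs within its Poisson
error while POPC never flips; interfacial TO tails are fully splayed 5% of
the time versus 23% in the isotropic midplane; the β glycerol bead
coordinates half as much water as the α beads; and no midplane aggregate
exists below the solubility limit (modal cluster count 0). The
middle/interface partition ratio (0.305) sits above the planted occupancy
odds (0.27) because hop transits also occupy the middle region.

`results.save("run_dir")` writes a versioned JSON report and TSV tables.
The same pipeline runs from the shell:

```bash
tgblister gen --preset SIXTEENX5 --seed 7 --out traj.gro --manifest truth.json
tgblister run --config run.yaml      # preset or GRO+TSV inputs
tgblister theory --v 1.26 --a 0.64 --l 1.75 --gamma 0
```

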