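# Methods

This note documents the models implemented in `engulf`, the choices made
where the design was genuinely open, and what the synthetic test
conditions do and do not establish about real data.

## Coarse-grained wall mechanics

The germ-cell wall is a network of beads connected by Hookean glycan
springs (constant `kgly`, default 200 pN/nm) along strands and Hookean
peptide springs (`kpep`, default 25 pN/nm, equilibrium length
`d_pep = 2 nm`) across strands. Strand stiffness is a discrete worm-like
chain: bending energy `(lp·kBT/l0) Σ(1 − cos θ)` over interior bead
triples, which converges to the continuum value `lp·kBT·L/(2R²)` for a
hoop of radius `R` (verified to 2 % at 100 beads). Each simulated
filament stands for a bundle of `n_bundle = 7` glycans; the effective
persistence length defaults to the strong-cross-linking rule
`n²·lp0 = 1960 nm` (the weak rule `n·lp0` is selectable).

Turgor (`delta_p`, default 86.31 kPa = 0.08631 pN/nm²) loads a zipper
triangulation of the bead rows: each triangle contributes
`Δp·A·n̂` split equally over its vertices, so pressure forces on any
closed surface cancel identically and converge to `Δp` per unit area as
O(h²) under refinement. Triangles are wound away from an interior
reference point; triangles that would stitch across the open part of a
partially grown hoop are dropped. The old cell wall (cylinder of radius
`R` plus hemispherical pole cap) is static; beads crossing it feel a
half-harmonic restoring force (`k_wall`, default 100 pN/nm, a stiffness
chosen to be rigid relative to `kpep` — not a measured constant).

Dynamics are first-order Euler–Maruyama on the overdamped equation with
uniform drag `ζ = 4π·η_med·l0` and thermal forces of variance
`2·kBT·ζ/dt`. The default time step is derived from the stability limit
of the stiffest spring (`dt = 0.1·ζ/k_max`, safely below `ζ/2k`); a
guard aborts any step that would move a bead more than `l0/2`. A single
bead in a harmonic trap reproduces `⟨x²⟩ = kBT/k` to within 5 %. The
medium viscosity default (`1e-6 pN·s/nm²`, ~1 Pa·s, a cytoplasmic scale)
makes free-bead diffusion negligible over engulfment times; absolute time
calibration of the mechanics is not attempted — the trace clock is the
insertion event clock set by `VIDC`.

Fresh meshes are built with every spring at its as-built rest length, so
the stretch energy of a new septal disc is exactly zero. Bending energy
of curved hoops is intrinsically positive (a circle is not straight);
"construction at rest" therefore refers to the spring terms.

## Remodeling rules

Insertion is event-driven: with `NIDC` complexes each inserting at
`VIDC` nm/s, one bead-length `l0` is added somewhere every
`l0/(VIDC·NIDC)` seconds. The stochastic rules are shared between the 3D
engine and the 2D lattice model and are a reconstruction (the original
rule set is not published in the available text), constrained by the
reported limits: zero roughness in the perfect-repair limit, smooth
leading edges for repair/processivity probabilities above ~0.8,
insensitivity to a tenfold change in complex count in the smooth regime,
and uncoordinated, asymmetric fronts below the threshold. The rules:

* Each complex is an autonomous agent on the leading-edge ring with a
  fixed circumferential handedness (matching processive circumferential
  motion of the PG-synthesis machinery).
* A polymerizing complex advances one site per event and inserts when
  both templates exist: the old-wall site of its row and the germ-wall
  site one row below. Old-wall holes (static field, fraction `f0` per
  row, default 1 %) are crossed with probability `ppro`; a missing
  germ-wall support always terminates the strand (nothing to cross-link
  to). Collisions with existing material also terminate.
* An idle complex walks the ring one site per event. At a down-step of
  the height profile it re-initiates from the exposed strand end: freely
  at a clean end (collision leftover), with probability `prep` at a true
  end defect — and each failed attempt degrades the end further (the
  k-th retry succeeds with probability `prep^(k+1)`), so repeatedly
  passed-over defects become effectively irreparable. After one
  fruitless lap of the ring the walker nucleates a fresh strand in the
  leading-edge trough; only after two fruitless laps does it nucleate
  anywhere, abandoning dead sectors.

Two structural consequences follow. With `prep = ppro = 1` no end is
ever left behind and nucleation stays in the trough, so rows complete
strictly sequentially and the profile is exactly flat whenever the mean
height is integral — the lattice benchmark's zero-roughness limit is a
theorem of the rules, not a numerical coincidence. Below the threshold
the compounding degradation wins: sectors stall while the front escapes
through second-lap nucleation, reproducing asymmetric engulfment. The
compounding exponent and the two-lap escape are the two calibration
choices made to place the smooth/rough boundary at the reported ~0.8.

Degradation: in coupled mode, inserting at row `k` severs the junction
cross-link of row `k−1` at the same sector in the same event, so a
junction is never cut before its replacement exists (make-before-break,
asserted per event in tests). In decoupled mode each junction is severed
after an exponential delay of mean `tau_delay` once its replacement is
synthesized, and with probability `ppcut` the erroneous vertical peptide
is cut instead. The insertion–degradation separation is measured as the
distance from each complex's synthesis site to the oldest unsevered
junction in its wake — the local position of the engulfing membrane,
which cannot pass an intact cross-link. With `tau_delay = 0` this stays
within about one bead spacing; it grows monotonically with the delay.
With synthesis halted, random peptide degradation severs every intact
cross-link as an independent Poisson process at rate `prpep` (per
minute) and records the forespore volume as the mesh swells.

The old wall itself is not meshed: the spec-level "horizontal" peptide
bonds between old and new strands are springs from germ-wall beads to
fixed anchor points on the wall surface, and template strands are
"degraded once the complexes move past" by severing those anchors.

## Geometry and observables

The long axis is +z, the septal plane z = 0, the forespore at z > 0; the
default radius comes from the printed inverse cell-wall radius
(1/R = 2.3 µm⁻¹ → R ≈ 435 nm). Simulated V, S and percent engulfment are
computed by the same surface-of-revolution reduction applied to
experimental contours: conical-frustum formulas on the medial (r, z)
profile (exact for frusta, O(h²) for smooth profiles), and engulfment as
the angle subtended at the forespore centroid by the covered boundary
over the full angle. A flat-septum forespore already measures ~37 %
engulfment under this definition; completion is declared at 95 % by
default because the simulated hoop lattice stops where the pole hoops
become shorter than a few beads. Pole curvature is a Kasa circle fit to
the polar 20 % of the profile, referenced to the hemispherical cap on
the profile's equatorial radius. Septum-curving onset uses a chord-frame
parabola fit (apex curvature 2|c|), which unlike an algebraic circle fit
is unbiased on shallow noisy arcs.

## Fitting and classification

χ² sums the standardized squared residuals of V, S and E over
experimental time points, with the simulation linearly interpolated to
the experimental grid (the σ are defined there). Grid sweeps report the
mean surface and its argmin; failed cells are marked missing, never
imputed. Phenotypes: *stalled* if the final engulfment is below the
completion threshold with no progress over the last fifth of the trace;
*asymmetric* if the angular spread of leading-edge height exceeds 25 %
of the forespore circumference (thresholds configurable and reported
with every call); otherwise *symmetric*.

## Synthetic test conditions and problem sizes

All tests run on generated inputs. The contour fixtures are ideal
geometric sporangia (circular forespore, stadium mother, prescribed
engulfment schedule, Gaussian intensity painting); they exercise every
analysis code path with exact ground truth but contain none of the
segmentation error, focal-plane drift or photobleaching of real movies,
so passing round trips demonstrate correctness of the measurement
operators, not robustness to imaging artefacts. Noisy engulfment traces
carry i.i.d. Gaussian noise with recorded σ; real population averages
have correlated, heteroscedastic errors.

3D simulations in the test suite use a reduced geometry (R = 120 nm,
l0 = 24 nm, hoop spacing 10 nm, ~15 rows of ~31 sectors) so a full
engulfment takes a few seconds; the old-wall hole fraction is raised to
`f0 = 0.2` there so the expected number of template gaps per strand
matches the full-size geometry (at biological scale, ~1 µm strands meet
several holes each at `f0 = 0.01`). The parameter-recovery sweep uses a
5×5 grid spanning a factor of ~16 in each spring constant, a shared
remodeling seed across cells (variance reduction: cells differ only
mechanically), and per-point σ of a few percent of signal, the regime in
which adjacent cells differ by a few σ per time point. The
delayed-degradation comparison slows the insertion clock (VIDC = 2 nm/s)
so the printed delays of 0–18 minutes are short relative to the run. The
lattice benchmarks alone run at the full published size (1570 segments,
500 rows, 100 replicates).

## Known limitations

* The lattice rule set is a constrained reconstruction; absolute
  roughness values in the rough phase depend on the compounding-repair
  choice and should be compared qualitatively, not digit by digit.
* In the smooth regime the reconstruction is *exactly* flat at stop
  time, so the complex-count comparison registers literally zero change;
  models with residual smooth-phase roughness would show a small finite
  percentage instead.
* Released hoops remain pressed against the old wall by turgor, which
  mutes the axial elongation response to soft peptides relative to a
  free sac; `kpep` sensitivity of the traces is correspondingly weaker
  than `kgly` sensitivity.
* The quasi-static interleaving (a fixed number of Langevin steps per
  insertion event) assumes mechanics relaxes faster than remodeling;
  the event clock, not the Langevin clock, is the physical time axis.
* No membrane, no SpoIIQ–AH ratchet, no membrane fission, no explicit
  PG chemistry, and no glycan-strand-degrading (multi-strand) template
  variants.
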