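# Methods

This note documents the models, conventions and numerical choices behind
`amorphnmr`, in the order the pipeline applies them.

## Periodic geometry

All coordinates are Cartesian ångströms; fractional coordinates appear only
inside the minimum-image computation and at I/O boundaries. Distances use
the minimum-image convention (MIC): a displacement is reduced by rounding
its fractional coordinates. Rounding returns the true nearest image
whenever that image is closer than half the smallest perpendicular cell
width, so every analysis entry point checks `width > 2 × cutoff` and raises
on cells too small for its cutoff rather than silently enumerating more
images. The scalar `minimum_image_displacement` additionally scans the 27
adjacent image candidates, making it exact for arbitrarily skewed cells and
for separations beyond half the cell width; the vectorised internal path
relies on the guarded rounding alone. The test suite and the acceptance
script compare both search paths against exhaustive 27-image enumeration on
random triclinic cells.

Molecule membership is inferred from the topology's covalent label pairs:
each atom is linked to its nearest partner of the complementary label
within a covalent cutoff (1.25 Å when a hydrogen is involved, 2.75 Å
heavy–heavy), and connected components become molecules. Nearest-partner
matching is what keeps intermolecular hydrogen-bond contacts (O···H ≥
~1.6 Å) from merging molecules. Water components must be exactly O + 2 H.
PDB files carry the same information through gemmi; because PDB atom-name
fields hold four characters, underscores in site labels are dropped on
write and restored against the topology on read.

## Hydrogen bonds and motifs

A hydrogen bond is an N-H···X contact (X = O or N) with H···X strictly
below 2.5 Å and the N-H-X angle strictly above 130°. Both inequalities are
strict: a contact at exactly 130° (or the known crystal-like intramolecular
contact at 128.8°) is not identified. Intramolecular bonds are detected and
flagged, never dropped. Each donor contributes exactly one motif per
snapshot; when several acceptors pass, the shortest H···X distance wins
(ties broken by atom index). A water primary acceptor triggers the
secondary search: each water hydrogen is treated as a donor under the same
criteria, and its nearest passing acceptor becomes a secondary neighbour.
The canonical label joins secondary sites with `/` in lexicographic order
and appends `*` when both belong to one molecule; water is rendered `OH2`
and the empty case `(none)`. Census fractions are counts over all donor
instances including the no-neighbour class, and therefore sum to one.

High-shift filtering keeps donor instances with predicted shift strictly
above 11 ppm; the "top patterns" selection sorts motifs by descending count
(ties lexicographic) and returns the smallest prefix covering 75 % of the
filtered instances. Both thresholds are parameters.

## Shifts and spectra

Shielding-to-shift referencing is an ordinary least-squares fit of
experimental shift on computed shielding, per element, applied as
δ = a·σ + b. The slope is left free rather than fixed at −1; with exact
linear input the fit recovers the relation to machine precision, and
applying the model and refitting yields the identity map. Spectra are sums
of unit-area Gaussians, one per proton, evaluated on a fixed ppm grid
(default bin width 0.05 ppm, broadening σ = 0.25 ppm — the broadening is a
display parameter, configurable, chosen to resolve ~1 ppm features).
`per_proton` normalization integrates to the proton count, so conditional
spectra partitioned by motif sum bin-wise to the unconditional spectrum
exactly. Candidate structures are ranked by per-element RMSE over assigned
sites; when several elements are requested jointly, per-element RMSEs are
z-scored across candidates and averaged with equal weights — a deliberately
simple, documented combination (probabilistic multi-element selection is
out of scope).

## Environments and formation energies

The environment of a probe molecule is every molecule with at least one
atom within 5 Å (MIC) of any probe atom. Environment molecules are made
whole and translated to the image nearest the probe, so the cluster handed
to the energy backend is geometrically contiguous and non-periodic. The
formation energy is E(probe ∪ environment) − E(environment), both terms on
identical frozen coordinates (single-point; no relaxation), so it contains
the probe's own ground-state/conformational energy plus its interaction
with the environment. Relative formation energies subtract the mean over
instances whose *selected donor* found no acceptor — the baseline is
donor-site-specific, and the no-acceptor class has mean zero exactly by
construction. Aggregation groups by the primary acceptor (the
intramolecular case forms its own `(intra)` category), reports SEM with the
n−1 sample standard deviation, and flags categories below 1 % of instances
as not displayed while keeping them in the raw table.

The backend is a contract: any deterministic callable mapping a list of
molecules (atoms + positions) to a scalar energy, size-consistent for
separated fragments. The shipped surrogate is pairwise additive.

## The synthetic generator

The generator emulates the statistical structure of an amorphous MD
ensemble without running MD. Each frame is built constructively: rigid
ten-site API surrogates (hub, three N-H donors at 1.9/2.9 Å, acceptors
O20/O29/N5 at 2.4 Å) are placed on a jittered grid (default spacing 12 Å)
with random orientations; each donor's motif is drawn from a target
probability table and realized geometrically — the acceptor placed at
1.8–2.3 Å from the donor H within a ≤ 42° cone of the N-H axis (angle
≥ 138°, safely above the 130° criterion), water bridges built with rigid
0.957 Å / 104.52° waters, and partner molecules approached hub-beyond-
acceptor so no other heavy atom comes nearer the donor proton than the
planted acceptor. Every placement is screened against unplanned contacts
with a guard band deliberately wider than the detection criteria (H···X <
2.6 Å with angle > 115°, no intermolecular H-to-heavy contact below 1.6 Å,
no heavy–heavy contact below 1.8 Å), so the downstream census recovers the
planted assignment of every donor exactly; a small Gaussian jitter
(σ = 0.05 Å) roughens the geometry without crossing the guard margins.

Molecule bookkeeping is exact: a cell contains precisely the requested
number of API molecules and waters. Hydrogen-bond partners consume the same
molecule budget, so when it runs out, a bond-free molecule (all donors
unbonded, serving no one) is relocated to serve as the acceptor; demands
that still fail geometrically are re-realized on another free donor of the
same site in a top-up pass, keeping realized motif counts at the sampled
counts. Residual deviations of realized from target fractions are below
about one percentage point, well inside the 3-standard-error bands the
recovery tests use (at n ≈ 500–1500 donor instances). Successive trajectory
frames re-draw all motifs independently — frames are exchangeable samples
of the equilibrium motif distribution, not time-correlated dynamics; a
frozen mode replicates one frame with positional jitter only.

What the generator does *not* emulate: real molecular geometry and
flexibility, realistic density (the grid spacing is a packing convenience,
not a physical density), time correlation between frames, C-H···O weak
bonds, and bridges deeper than one water. Passing recovery tests therefore
demonstrate that the analysis chain measures what was planted — they say
nothing about force-field accuracy or real spectra.

The surrogate shift model is linear: shift = base(donor) +
c·(d(H···X) − 2 Å) + offset(acceptor class) + Gaussian noise, with defaults
base = 9.8/8.6/8.2 ppm for the three donors, c = −2 ppm/Å, offsets
+2.4 (water), +1.6 (O20), +1.4 (O29), +1.1 (N5) ppm and noise σ = 0.3 ppm.
Water is the most deshielding class by default, so water-bonded donors
populate the region above 11 ppm preferentially, and the population above
11 ppm grows with water content because the default motif targets scale the
water-bonding probability with the cell's water count. The surrogate energy
backend is a pairwise Morse well, D·((1 − e^(−α(r−r₀)))² − 1) with α =
2 Å⁻¹, r₀ = 2 Å, truncated at 6 Å, with well depths 5.0 (donor-H···water O),
3.0 (O20), 2.8 (O29), 2.2 (N5) and 0.05 for all other pairs — water binding
is planted as the most favourable interaction, and the ordering is
recovered through the full formation-energy pipeline within 3 SEM.

Default ensemble composition follows the study conditions: five cells each
at 0 / 0.5 / 1.0 / 2.0 % w/w water (0/16/32/65 waters beside 128 API
molecules) and two cells at 4 % (132 waters); 1001 snapshots per trajectory
(100 ns window, 100 ps spacing, endpoints inclusive) and an 11-snapshot
coarse schedule at 10 ns spacing. The average water content reported by the
accounting (1.16 % w/w) is the unweighted mean of nominal per-cell
percentages over the 22 cells; a mass-based alternative would weight by
realized cell masses and is intentionally not the default.

## Numerical and interface choices

Tables are tab-separated text with header lines; stages of the CLI are
independently re-runnable from on-disk artifacts, write outputs atomically
(temp file + rename) and accompany them with a JSON manifest recording
stage, parameters, seed and package version. All randomness flows from one
integer seed through named `SeedSequence` spawn keys (content, cell,
snapshot), so every generator product is bit-reproducible. Degenerate
inputs fail loudly: empty snapshots, missing lattice records, unresolvable
site labels, cells too small for the MIC at the requested cutoff, fewer
than two referencing points, and missing no-acceptor baselines are all hard
errors rather than silent fallbacks.

Test problem sizes (32-molecule cells, 14–16 frames, ~500–1500 donor
instances) were chosen as the smallest ensembles at which the 3-standard-
error recovery bands are meaningfully narrower than the planted effects;
the full-scale 128-molecule default spec is exercised for composition and
I/O, with statistics gathered on the smaller cells.

## Known limitations

* The MIC path used in bulk searches assumes reasonably compact cells; the
  guarded width check rejects pathological cells instead of handling them.
* PDB round-trips quantise coordinates to 10⁻³ Å and lose lattice
  orientation (lengths and angles only), as the format dictates.
* The multi-element candidate ranking is a pragmatic score, not a
  probabilistic model; use single-element rankings when in doubt.
* The energy surrogate has no polarisation, no three-body terms and no
  periodic evaluation; it exists to provide a controllable, size-consistent
  stand-in for a quantum-chemical backend behind the same interface.
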