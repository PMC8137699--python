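# amorphnmr

Hydrogen-bond motifs, predicted ¹H NMR spectra and intermolecular formation
energies for hydrated amorphous molecular solids.

## The problem

Amorphous drug formulations lack long-range order, so their local structure
has to be inferred indirectly. One productive route combines molecular
dynamics (MD) models of the amorphous cell with predicted NMR chemical
shifts: the ¹H shift of an N-H donor proton is exquisitely sensitive to its
hydrogen-bonding environment, so the distribution of predicted shifts —
resolved by the hydrogen-bonding motif each donor participates in — can be
compared against the experimental spectrum to identify which motifs dominate
the real material. The same snapshots also yield the energetics of each
motif, via the formation energy of every molecule with its local
environment.

`amorphnmr` implements that analysis chain for periodic MD snapshots of a
hydrated amorphous molecular solid (an active pharmaceutical ingredient,
"API", with three N-H donors, two carbonyl oxygens and a ring nitrogen,
plus a variable number of waters):

1. **H-bond detection** — N-H···X contacts (X = O, N) with N-H-X angle
   strictly above 130° and H···X distance strictly below 2.5 Å, under the
   minimum-image convention.
2. **Water-bridged motifs** — when the first neighbour is a water oxygen,
   the search continues through the two water hydrogens with the same
   criteria, giving canonical labels such as `N6-H···OH2···O20/OH2`
   (secondary sites in lexicographic order, `*` when both belong to one
   molecule).
3. **Census statistics** — one motif per donor per snapshot (shortest
   H···X wins), with fractions that include the no-neighbour class.
4. **Spectra** — shielding→shift conversion by linear referencing
   (δ = a·σ + b, ordinary least squares against assigned experimental
   shifts), Gaussian-broadened spectrum aggregation, motif-conditional
   decomposition, the population of shifts above 11 ppm, and per-element
   RMSE ranking of candidate crystal structures.
5. **Energetics** — 5 Å environments, formation energy
   E(complex) − E(environment) through a pluggable single-point backend,
   and per-motif relative formation energies (baseline: mean over
   instances whose selected donor found no acceptor).
6. **Synthetic data** — a generator that builds periodic cells in which
   every donor's motif is drawn from a target probability table and
   realized geometrically, plus surrogate shift and energy models with
   planted, recoverable ground truth. External MD, machine-learned
   shielding and tight-binding energy engines are deliberately out of
   scope; their roles are filled by inputs and surrogates.

## Worked example

Generate a small synthetic ensemble (16 API molecules, 20 waters, 5
snapshots), run the motif census and the formation-energy aggregation:

```
amorphnmr generate --out-dir demo --seed 7 --n-api 16 --water-count 20 --n-snapshots 5
amorphnmr census   --out-dir demo --snapshots 'demo/snapshots/*.xyz' --topology demo/topology.yaml
amorphnmr energies --out-dir demo --snapshots 'demo/snapshots/*.xyz' --topology demo/topology.yaml --donor-site N6
```

`demo/census.tsv` starts:

```
motif	count	fraction
N28-H···(none)	64	0.26666666666666666
N21-H···(none)	60	0.25
N6-H···(none)	50	0.20833333333333334
N6-H···O20	15	0.0625
N21-H···O29	10	0.041666666666666664
```

Each row is one motif with its count over all donor instances (one per
donor per snapshot; 16 molecules × 3 donors × 5 snapshots = 240 here) and
its fraction of that total — the no-neighbour class included, so the
fractions sum to one. `demo/energy_by_motif.tsv` gives, per primary
acceptor of the N6-H donor, the mean relative formation energy ± standard
error of the mean:

```
acceptor	n	fraction	mean_relative_energy	sem	displayed
(none)	50	0.625	0.0	0.395782	True
O20	15	0.1875	-2.863315	0.515002	True
O29	8	0.1	-1.821294	0.887439	True
N5	5	0.0625	-0.384082	0.701264	True
OH2	2	0.025	-5.23241	2.519709	True
```

The no-acceptor mean is zero by construction (it defines the baseline), and
with the surrogate energy backend's default well depths, water (`OH2`) is
the most favourable acceptor — the behaviour the pipeline is designed to
detect. The `displayed` column implements the ≥1 %-of-instances display
filter; rare acceptors stay in the raw table.

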