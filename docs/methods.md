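# Methods

## Scope and model

`pigmentnet` analyses pigment geometry and pairwise Förster
excitation-energy transfer (EET) in antenna supercomplexes of the
PSI–IsiA type: a photosystem I core (trimeric or monomeric) surrounded
by one or two concentric rings of the CP43-like antenna protein IsiA,
each protomer binding 17 chlorophyll *a* and 4 carotenoid molecules.
The analysis is purely structural: every quantity is computed from
deposited (or generated) atomic coordinates.

The transfer rate between two chlorophylls is the point-dipole Förster
expression

    k = C κ² / (n⁴ R⁶),   κ² = [û_D·û_A − 3(û_D·R̂)(û_A·R̂)]²

- **û_D, û_A** — unit Qy transition-dipole vectors, taken along the
  NB→ND nitrogen axis of the chlorin ring. κ² is invariant under
  flipping either dipole, so the NB→ND sign convention carries no
  physics.
- **R** — distance between the central Mg atoms. Coordinates are kept
  in Å throughout; the rate expression converts R to nm.
- **C = 32.26** — spectral-overlap factor for Chl *a* → Chl *a*
  transfer; treated as a constant (no overlap integral is computed from
  spectra).
- **n = 1.55** — refractive index of the protein matrix.

With R in nm, k is in ps⁻¹ and the pairwise lifetime τ = 1/k is in ps.
This unit choice puts neighbouring-chlorophyll transfer (R ≈ 1–2.3 nm)
at τ ≈ 0.1–40 ps, the scale addressed by the τ < 40 ps display filter
and τ < 20 ps fast-pathway filter. Both the unit convention and the
constants are carried explicitly in `FretParameters`. Only pairwise
rates are computed: no exciton coupling, no back-transfer kinetics, no
master-equation dynamics, and no multi-step effective lifetimes — the
per-pair τ = 1/k is the only lifetime reported.

Because a single C is used, k(d→a) = k(a→d) and the network is stored
undirected; asymmetric donor/acceptor constants would require a
directed variant (not implemented). Pairs beyond the geometric cutoff
are excluded from the network rather than computed and hidden; a
diagnostic flag (`all_pairs=True`) computes the dense matrix.

## Membrane frame and sidedness

Antenna chlorophylls lie in two thin layers parallel to the membrane,
so the membrane normal is estimated as the direction of least spread of
the chlorophyll Mg cloud (the smallest principal component of its
covariance). The sign is fixed so that the cytoplasmic extrinsic
subunits (roles PsaC/PsaD/PsaE by default) project to the positive
side; models without markers must declare the sign in the config.

The midplane is the package's own convention (no structural feature
defines it canonically): Mg projections onto the normal are split by an
exact 1-D two-means clustering (contiguous-split scan, deterministic
and seed-free), and the midplane is the midpoint of the gap between
the two clusters. A pigment exactly on the midplane counts as
cytoplasmic (documented tie-break). This rule reproduces the clean
two-layer split of the double-ring architecture; on real deposits with
stragglers near the midplane the counts may shift by a few pigments —
the per-pigment labels and the midplane offset are exposed so the
criterion can be audited.

## Ring assignment

Antenna protomer centroids (mean Cα, falling back to mean pigment
position) are reduced to radial distances from the ring axis. The axis
runs along the membrane normal through the reaction-centre subunit
centroid (PsaA/PsaB) when core subunits are present, else through the
chlorophyll centroid. Anchoring on the core rather than the pigment
centroid matters for open arcs (the monomeric double layer): the
chlorophyll centroid of a 100° arc lies far off the arc's centre of
curvature and would scramble a radius-based split.

Sorted radii are split at their largest gap; a gap below
`min_ring_gap` (default 15 Å, roughly half the inter-ring spacing)
yields a flagged single-ring result rather than a forced split. An
explicit chain→ring map can override the geometric split entirely.
Within each ring, protomers are indexed 1..N by angle, anticlockwise
as viewed from the lumenal side (equivalently, about −normal), starting
at a reference subunit — by default the direction of the first
PsaK-role chain, mirroring the field's "PsaK pole" numbering
convention.

## Interfacial pairs and thresholds

Chlorophyll pairs from different subunits with Mg–Mg distance
≤ 23 Å (inclusive boundary) are interfacial; distances < 18 Å (strict)
are highlighted. The defaults mirror the conventional display cutoffs
for this system and are configurable. The search uses a k-d tree and
is tested edge-for-edge against an O(N²) scan.

## Structure comparison

Two models are superposed by least-squares rigid (Kabsch) fit of the
Cα pairs of a reference core subunit (PsaA by default), matched by
residue number; reflections are rejected. When several copies of the
reference exist (a trimeric core has three PsaA chains) and none is
named, every chain combination is fitted and the lowest-RMSD one wins.

Matched antenna subunits (by ring and ring index, or an explicit map)
yield centroid displacements decomposed along the membrane normal
(vertical, signed, + = cytoplasmic) and in-plane (horizontal norm);
`total² = horizontal² + vertical²` holds by construction. Summaries
report both the maximum and the mean over a subunit set.

The ring-rotation angle is the rotation-only 2-D orthogonal Procrustes
solution on subunit-centroid projections into the membrane plane, after
centring each projected set (a rotation about the ring axis equals a
rotation about the set centroid plus a translation, so centring makes
the recovery exact for arcs as well as closed rings). The returned
angle maps the second model's projections onto the first's, positive
anticlockwise viewed from the lumenal side; per-subunit angular offsets
are available alongside the Procrustes headline value.

The curvature profile reports each antenna protomer's vertical centroid
offset (relative to the mean core-subunit height) versus its angular
position, with the per-ring peak-to-peak amplitude as summary. A rigid
tilt of the whole complex tilts the estimated normal with it and
therefore does not register as curvature; only differential vertical
displacement does.

## Synthetic complexes

The generator emulates the double-ring architecture with everything
known by construction. Defaults are the study conditions of the
trimeric supercomplex:

| parameter | default | meaning |
|---|---|---|
| inner/outer protomers | 18 / 25 | closed double ring (43 protomers) |
| chlorophylls per protomer | 17 (11 cytoplasmic + 6 lumenal) | gives 731 antenna Chl, 473/258 per side |
| carotenoids per protomer | 4 | centroid-only placeholders |
| ring radii | 110 / 150 Å | ~380 Å outer diameter, ~40 Å inter-ring centre gap |
| layer heights | ±14 Å | two Mg layers across the membrane |
| NB–ND span | 4.2 Å | approximate chlorin NB–ND distance; any positive value gives the same unit dipole |
| dipole rule | tangential | radial / random (seeded) also available |
| coordinate noise | 0 Å | Gaussian, seeded |

Chlorophylls occupy a deterministic ring-sector lattice per layer
(three radial rows spanning ±12 Å, 7 Å tangential spacing), so the
outer face of an inner protomer approaches the inner face of its outer
neighbours to ~16 Å and genuine inter-ring pairs exist at the 23 Å
cutoff. Protomers are poly-alanine Cα traces sufficient for centroids
and superposition; each core moiety carries a PsaA blob with two
chlorophyll layers, a PsaK pole marker, and a PsaC extrinsic marker at
+28 Å. The monomeric preset (6 + 7 protomers) uses the closed-ring
angular spacings, i.e. it is a sector of the full double ring around
its own core. Optionally, `plant_close_pairs` repositions chosen
outer-ring chlorophylls 12, 13, ... Å from inner-ring partners with
collinear dipoles (κ² = 4), giving inter-ring edges of known, strictly
decreasing rate for ranking tests.

Generation is fully deterministic given the seed; at zero noise the
seed has no effect (except under the random-dipole rule), and the noise
stream is independent of the dipole stream.

What the generator does **not** emulate: real protein geometry,
chemically realistic chlorin poses and dipole directions, the
asymmetric outer-ring register of the deposited trimer, resolution-
dependent coordinate error, or the deposited monomer's placement
relative to a trimer moiety (the synthetic monomer is concentric about
its own core). Passing tests therefore demonstrate the correctness of
the geometry and network machinery under known ground truth, not the
biological values a real deposit would give; deposit-level checks
require the deposited files (`scripts/validate_deposits.py`).

## Numerical choices and degenerate inputs

- Pair/cutoff boundaries: ≤ for the 23 Å pair cutoff, strict < for the
  18 Å highlight and the lifetime filters, mirroring the usual wording
  ("up to", "under").
- κ² = 0 gives rate 0 and an infinite lifetime; non-finite attributes
  are dropped on GEXF/GraphML export.
- Chlorophylls missing NB or ND are a hard parse error naming the
  pigment; a config switch (`on_missing_dipole: skip`) downgrades this
  to a logged skip recorded in the parse report. Coincident NB/ND
  (degenerate dipole) and coincident Mg pairs are always errors.
- Alternate conformers: the first conformer is taken, with a warning.
- Fewer than 3 chlorophylls cannot define a membrane frame; fewer than
  3 matched Cα cannot define a superposition; fewer than 2 matched
  subunits cannot define a ring rotation (all errors). A single radial
  group when two rings are requested is a flagged result, not an error.
- PDB output falls back to mmCIF (with a warning) when chain ids exceed
  one character or coordinates overflow the fixed-width fields.

## Problem sizes in the test and acceptance runs

The bundled suites run entirely on generated complexes: the full
18+25×17 trimer (731 antenna chlorophylls, ~2900 network edges), the
6+7 monomer for perturbation-recovery fixtures, 20 random clouds of up
to 200 chlorophylls for the network-vs-oracle property, and 10⁶
orientation triples for the isotropic ⟨κ²⟩ Monte-Carlo check. The whole
suite completes in well under a minute.

## Known limitations

- The point-dipole approximation fails at very short range (< ~1 nm),
  where transition densities overlap; rates for the closest pairs are
  indicative only, as in any κ²/R⁶ treatment.
- Sidedness counts on real deposits depend on the midplane convention
  (above); the gap-based split is deterministic but not guaranteed to
  match any particular deposition's annotation.
- No cryo-EM map handling, model building, multibody-refinement
  analysis, or spectroscopic modelling: quantities derived from
  particle stacks or measurements (ensemble displacement amplitudes,
  absorption spectra, oxidation kinetics) are out of scope by design.
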