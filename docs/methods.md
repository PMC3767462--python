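# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Descriptor model

The analysis treats a compound as a vector of named descriptor values. Two
provenance classes exist and are tracked per value:

* **computed** — descriptors with an explicit formula or geometric
  construction, computed here from element symbols, bonds and 3D coordinates;
* **imported** — descriptors produced by external QSPR models (aqueous
  solubility, cell permeabilities, logHERG, skin permeability, serum-albumin
  binding, metabolic-reaction counts, polarizability, CNS score, percent human
  oral absorption). These enter through descriptor tables; the package maps
  external column headers (including the QikProp export dialect) onto a
  canonical registry and never re-derives the underlying regressions.

A missing value is an **absent key**, never NaN or 0: the compliance engine
must distinguish "out of range" from "unknown", and means/denominators must
shrink rather than be polluted.

## Geometry descriptors

**SASA.** Solvent-accessible surface area uses per-atom sphere sampling in the
Shrake–Rupley style: each atom's van der Waals sphere (Bondi radii, editable)
is inflated by the probe radius (default 1.4 Å, water), sampled on a
deterministic golden-spiral lattice (default 960 points/atom), and a point
contributes if it lies inside no other inflated sphere. The lattice is
deterministic by construction; a seeded jitter can be enabled but is off by
default, so identical inputs give identical outputs on any platform. Accuracy
scales like 1/n in the point count: on a single sphere the sampler is exact,
and doubling the lattice changes molecular SASA by well under 0.5% on the
fixtures. Explicit hydrogens are included in the surface (whether external
predictors do the same for their surface descriptor is not documented
anywhere; we state our convention and keep it fixed).

**Hydrophobic SASA.** The "hydrophobic portion" has no universal definition;
the shipped set is carbon, Cl/Br/I, and hydrogens bonded to carbon, with
burial still tested against *all* atoms. The set is an editable argument.

**Volume.** The volume enclosed by the solvent-accessible surface is the
union of the inflated spheres, integrated on a uniform Cartesian grid
(default 0.2 Å spacing; error is bounded by the spacing — use 0.1 Å when 1%
accuracy matters on atom-sized objects). Closed-form two-sphere
(inclusion–exclusion with the lens volume) and single-sphere values are the
test oracles.

**Globularity.** Glob = 4πr²/S with r = (3V/4π)^{1/3}. Equal to 1 for a
sphere; the isoperimetric inequality bounds it above by 1 up to sampling
noise (tests allow 1.02). Two disjoint equal spheres give 2^{−1/3} ≈ 0.794.

**Cohesion index.** Ind_coh = HBA·HBD/S_mol, an exact ratio.

**H-bond counts.** HBA counts N and O heavy atoms; HBD uses the *heavy-atom
convention*: an N/O with at least one attached hydrogen counts once (water:
HBD = 1). Both element sets are editable pattern configuration, because the
counting rules used by proprietary predictors are undisclosed and ours must
therefore be explicit.

**Rotatable bonds.** Single, acyclic (ring perception via cycle basis),
non-terminal bonds between heavy atoms; amide C–N excluded (carbon bearing a
double-bonded oxygen). Ethane 0, n-butane 1, benzene 0.

**log P.** A pluggable backend interface: `zero` (testing stub),
`atom_contrib` (a deliberately simple per-element contribution table, shipped
and documented in the source) and `crippen` (Wildman–Crippen via RDKit, for
records carrying a SMILES). The default `atom_contrib` is crude; anyone with
a better estimator registers it in one line. Imported log P columns are
preferred when available.

## Compliance scoring (#stars)

A range panel maps descriptors to closed intervals ("range for 95% of known
drugs"); a value equal to a printed endpoint is **in range** (the printed
ranges read as inclusive). #stars counts star-panel descriptors whose value
falls outside. Missing descriptors are skipped and reported (policy `skip`)
or raise (policy `fail`); the per-compound `evaluated` count makes the
denominator explicit.

Panels are data (`data/panels.yaml`), not code. The shipped `drugs95` panel
carries every printed range; where the descriptor definitions and the
results discussion disagree (logK_HSA upper bound 1.2 vs 1.5; logBB upper
1.0 vs 1.2; #metab 0–15 vs 1–8), both variants ship (`drugs95` and
`drugs95_results`) and no attempt is made to guess the intent.

Two panel rows are approximations and are flagged as such:

* **Caco-2** guidance is printed as a qualitative scale (<5 low, >100 high)
  rather than a band; the shipped default treats ≥25 nm/s as compliant.
  MDCK uses the printed 25–500 nm/s band.
* The reference predictor determines #stars from 24 descriptors whose
  identities are unpublished. Our star panel has the 19 descriptors that
  appear in the library-summary table: the 14 with printed ranges plus MW,
  log P, HBA, HBD and NRB, the latter five with the predictor's standard
  recommended ranges (MW 130–725, logP −2…6.5, HBA 2–20, HBD 0–6,
  NRB 0–15). Star membership is configuration, so a user with the exact
  24-descriptor panel can drop it in.

Percentages are reported rounded to 2 decimals with the raw fraction
retained.

## Subset filters and Rule of Three

Clause sets with exact printed strictness (MW = 500 fails drug-like's strict
<; a value on the lead-like between-bounds passes). The printed bounds imply
lead-like ⊆ drug-like and fragment-like ⊆ drug-like; this is verified by
property test rather than assumed. Rule-of-Three compliance is the full
conjunction of the three strict inequalities; `criteria_met` exposes partial
compliance for users who prefer the "all or some" reading. The "number of
primary metabolites" criterion is mapped to the #metab descriptor — the only
metabolic count in the data model; this is an assumption.

## PK rules

* **Similarity-adjusted prediction** blends the nearest training-set
  analogue's experimental value with the model prediction,
  P_pred = S·P_exp + (1−S)·P_QP, only when S ≥ 0.9 (threshold configurable);
  at S = 1 the experimental value is returned exactly, below threshold the
  model value is kept unchanged. The similarity metric is pluggable; the
  default is Tanimoto on hashed Morgan fingerprints (radius 2, 2048 bits),
  since the similarity space of the reference implementation is undisclosed.
  No training set ships (the reference one is proprietary); users supply a
  CSV (id, smiles, experimental_value).
* **Transdermal rate** J_m = K_p·MW·S_wat with K_p = 10^logKp (cm/h) and
  S_wat = 10^logS_wat (mol/L). The published unit ("μ cm⁻² h⁻¹") is
  ambiguous; a `unit_scale` factor (default 1.0, identity) absorbs the
  conversion so the conventional J_m > 100 threshold behaves as in the
  reference outputs. The rule is exact arithmetic: non-negative, separable,
  strictly increasing in each factor.
* **CNS flag**: active iff the integer score on the −2…+2 scale exceeds 1,
  i.e. exactly +2.
* **Oral-absorption class** (1 = low, 2 = medium, 3 = high): the bin edges
  are not published; defaults <25% → 1, 25–80% → 2, >80% → 3, configurable.

## Synthetic libraries

The generator emulates a natural-product screening library at the descriptor
level. Default marginals are centred on the average values typical of plant
secondary metabolites (MW ≈ 427 Da, log P ≈ 4.2, HBA ≈ 5.9, HBD ≈ 2.4,
NRB ≈ 5.3, logS_wat ≈ −5.1, …) with spreads chosen once to be generous
(roughly a third of the mean for size-like descriptors, 1–2 log units for
log-scale ones). Normal and mean-parameterised lognormal marginals are
supported, with truncation and integer rounding for count descriptors.
Optional correlations go through a Gaussian copula.

**Planted structure is exact by construction**, not hoped-for: in/out
labels are assigned by quota first (round(f·n) compounds in range), then
values are sampled from the marginal conditioned inside or strictly outside
the panel range (truncated-normal sampling; the out-of-range side is chosen
in proportion to the marginal's tail masses). When a #stars = 0 fraction is
planted, the quota rows are sampled in-range for *every* star descriptor and
each remaining compound is guaranteed at least one violation, using a
descriptor without a planted fraction as the violation carrier when needed;
contradictory recipes (e.g. more required violations than non-compliant
rows) raise instead of being silently approximated. A side effect worth
knowing: under a planted #stars fraction, *all* star descriptors are
range-conditioned, so their marginals are compliance-shaped rather than
free.

What the generator does **not** emulate: chemical consistency across
descriptors (no structures are generated; MW and S_mol of a synthetic
compound are statistically, not physically, related), the heavy right tails
of real natural-product libraries, and real missing-data patterns (synthetic
profiles are complete). Passing planted-fraction tests therefore
demonstrates the correctness of the counting and reporting machinery, not
the realism of any particular compound.

Randomness uses numpy's seeded PCG64 generator exclusively; a config plus
seed reproduces a library byte-for-byte across platforms.

## Problem sizes

The shipped tests and the acceptance script use 960–1,920 lattice
points/atom, 0.1–0.2 Å volume grids, 200 randomised profiles for the
brute-force compliance oracle, 10,000 random profiles for the filter-logic
property, and 1,000-compound planted libraries — sizes at which every oracle
comparison is sharp and the whole suite runs in seconds.

## Known limitations

* Geometry descriptors trust the input coordinates; no minimisation,
  protonation or conformer handling (structure preparation is upstream).
* The SASA/volume sampler is O(n²) in atoms per molecule — fine for
  drug-sized molecules, slow for proteins.
* The star panel approximates an unpublished 24-descriptor set with 19
  documented members (see above).
* The default log P backend is intentionally simple; treat its absolute
  values as placeholders.
* Histogram bins are left-closed with lower-edge labels (widths: 1 for
  counts, 0.5 for log-scale descriptors by default); kernel-smoothed
  "distribution curve" rendering is out of scope.
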