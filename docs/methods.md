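# Methods

## The problem

When a ribosomal protein is made in excess of its assembly partners, a
nuclear quality-control pathway ubiquitinates and degrades it. The ligase
responsible (a HECT-family E3: Tom1 in budding yeast, Huwe1 in human
cells) shows a striking selectivity: it modifies lysines that are exposed
on the unassembled protein but concealed once the protein is built into
the ribosome. This package implements the two computational analyses that
support that picture:

1. a **large-probe geometric accessibility test** that asks, for each
   ubiquitination-site lysine, whether a sphere the size of the ligase's
   catalytic module could touch the lysine's ε-amino nitrogen (NZ) in a
   given assembly state — the free large subunit (60S) versus the complete
   ribosome (80S);
2. the **quantitative-proteomics aggregation** used to identify
   ligase-dependent ubiquitination sites (SILAC ratios of GlyGly-remnant
   peptides) and aggregating insoluble proteins (iBAQ differences), with
   Fisher-exact / Benjamini–Hochberg category enrichment.

Because the underlying raw mass-spectrometry data are not publicly
deposited, every statistical stage is validated against seeded synthetic
data with planted ground truth rather than against the original tables.

## Probe accessibility

### Model

A lysine site is *accessible* in a state if a rigid spherical probe of
radius R (default 25 Å, the approximate footprint of a HECT domain
carrying its donor ubiquitin) can be placed tangent to the NZ atom
without overlapping any other atom of the assembly. Concretely, for each
of `n_directions` unit vectors `u` from a deterministic Fibonacci-sphere
lattice, the probe centre is placed at

    c(u) = nz + (R + r_NZ) · u        (r_NZ = 1.55 Å)

and the direction is clear iff no obstacle atom `a` satisfies
`|c(u) − a| < R + r_vdw(a) − slack`. One clear direction suffices.

Assumptions and deliberate simplifications:

* **Tangent placement, not path search.** The probe only needs a clear
  final pose, not an unobstructed straight or curved approach channel.
  This is the weakest geometric reading of "can the ligase touch the
  lysine" — an upper bound on reachability — and it is deterministic and
  cheap enough to certify exactly. A strict-channel variant would only
  convert some accessible calls to inaccessible (never the reverse).
* **Rigid everything.** No side-chain flexibility, no induced fit.
* Waters and hydrogens are never obstacles; metal ions and modified
  residues are obstacles by default (they occupy space), with a switch to
  drop heteroatoms for sensitivity analysis.
* The lysine's own residue never blocks its probe (`self_exclusion =
  "residue"`), since the ligase engages that side chain itself.

Per-direction clash checks run against the subset of atoms within
`(R + r_NZ) + R + max(r_vdw)` of the NZ atom, extracted with a KD-tree,
so per-site cost is sublinear in assembly size (a ribosome-scale model
has ~2×10⁵ atoms; only thousands are ever candidates).

### Monotonicity laws

Two exact laws follow from the clash inequality and are enforced by
property tests: adding obstacle atoms can only shrink the clear set
(obstacle monotonicity — this is why assembling the 40S subunit onto the
60S can only conceal sites, never expose them), and shrinking the probe
can only enlarge it (radius monotonicity; the proof is that
`|c(R) − a| − R` is non-increasing in R because the centre moves along
`u` at unit rate).

### Certification and sampling resolution

The synthetic cage fixture places the NZ atom at the centre of a sphere
of pseudo-atoms (radius 6 Å, carbon-like 1.70 Å radii, ~0.5–1 Å spacing)
with a circular aperture of known half-angle α. Whether a tangent probe
fits has a closed form: the axis direction is clear iff the aperture rim,
at angular distance α, lies beyond the clash threshold, giving a critical
half-angle

    α* = arccos[ (d² + r_c² − (R + r_a)²) / (2 d r_c) ],  d = R + r_NZ

(≈ 84.96° for r_c = 6 Å, R = 25 Å). The suite asserts that the
implementation, this closed form, and an independent brute-force oracle
(10⁵ random directions, no spatial index, no shared code path) agree on
the full aperture sweep, and that the verdict flips exactly once, at α*.

Directional sampling has finite resolution: 1024 lattice points space
directions ~3.6° apart, so a clear cone narrower than that can be missed.
Fixtures are therefore evaluated ≥2° away from α*; within that margin no
finite sampling (including the 10⁵-direction oracle, ~0.6° resolution)
can decide the verdict, and the tests assert the flip *bracket* contains
α* instead. For the same reason the *count* of clear directions is not
exactly invariant under rigid rotation of the scene (the lattice is fixed
in space); the accessible *flag* is rotation-invariant away from the
critical margin, and translation invariance is exact. The generator
refuses cage configurations whose discretization gaps could themselves
admit the probe through a nominally closed wall (gap half-angle ≥ α*),
because such a fixture has ambiguous truth.

### Real structures

`erisq access` accepts any mmCIF/PDB model, a chain→protein map (a
curation template can be emitted from entity descriptions), a per-chain
author-numbering offset table, and a site list TSV. For the yeast
ribosome, supplying the 80S crystal structure (PDB 4V88) with a curated
site list of ubiquitination-site lysines reproduces the 60S-versus-80S
concealment comparison via two `--state` chain selections, with the
`clearance_slack ∈ {0, 0.5}` / heteroatom-in-or-out sensitivity sweep
bracketing the uncertain atomic-radius treatment. Unresolved sites (no NZ in the
density) are always reported as "unobserved", never dropped, so the
denominator of any count stays auditable.

## SILAC GlyGly aggregation

All ratio combination happens on the log2 scale — measurement error in
isotope-ratio data is multiplicative, and log2 treats a 2-fold decrease
and a 2-fold increase symmetrically.

* **Orientation.** A label-swap replicate reports WT/mutant instead of
  mutant/WT; `orient_ratio` reciprocates it. Re-orientation is an exact
  involution: inverting every ratio and toggling every swap flag leaves
  all summaries unchanged (property-tested).
* **Peptide collapse.** Several peptides can report one site within a
  replicate; they collapse to the median of log2 ratios, back-transformed
  (robust to a single aberrant peptide).
* **Per-site summary.** Mean of per-replicate log2 ratios; 95% CI from
  the t distribution with n−1 degrees of freedom (n is usually 3, so a
  normal interval would be badly anticonservative); linear fold change
  `2^mean`; a site is *decreased* when fold change ≤ 0.5. Sites observed
  in fewer than `min_reps = 2` replicates are filtered, not summarized.
  No per-site multiple-testing correction is applied — classification is
  by fold-change threshold; correction happens at the category-enrichment
  stage only.
* **Protein normalization.** Dividing a site ratio by the protein-level
  mutant/WT ratio converts it to an occupancy ratio, separating a change
  in modification stoichiometry from a change in protein abundance. Both
  normalized and raw outputs are available because published plots do not
  always state which is shown; with no protein table the raw ratio passes
  through flagged unnormalized.

Calibration on synthetic data (3 replicates, one swap, noise SD 0.3 log2
units): planted 4-fold decreases are detected with sensitivity ≥ 95% and
null sites with false-positive rate ≤ 5% (10 seeds × 1000 sites), and the
t-based CI covers the true log2 ratio in 95% ± 2% of 1000 null sites.

## Insoluble-fraction ranking

Per-replicate ΔiBAQ = iBAQ(mutant) − iBAQ(wild type) in the
detergent-insoluble fraction, averaged over replicates with SEM. Raw
differences (not log ratios) are used deliberately: iBAQ is an absolute
abundance proxy, and differences weight abundant proteins — the relevant
behaviour when the aggregating species are highly expressed ribosomal
proteins. A log-scale option exists for sensitivity analysis. Ranking is
by descending mean ΔiBAQ with lexicographic tie-break; the top decile is
`ceil(0.10 n)` proteins (1270 → 127), expanded when boundary ties
straddle the cut. Missing iBAQ cells are treated as 0 (absent from the
fraction) and flagged. Planted accumulators shifted by ≥5× the replicate
noise SD are recovered in the top decile at ≥90% (10 seeds).

## Enrichment

One-sided Fisher exact test (over-representation only — the question is
enrichment, not depletion): p = upper hypergeometric tail P[X ≥ a] for
the 2×2 table of (selected × in-category) counts, against the background
of all identified items. BH step-up adjusts across categories. The
implementation (scipy hypergeometric survival function; statsmodels BH)
is verified against a from-scratch enumeration oracle using exact
binomial coefficients for all tables with N ≤ 60 (agreement to 1e-12)
and against hand-applied step-up examples. For ranked inputs the default
"selected" set is the top 10% by ascending mean log2 ratio.

## Synthetic-data generators

All generators are pure functions of `SimConfig` (identical seed ⇒
identical output). Defaults encode the targeted study design: 3
biological replicates with one label swap; ~10% of quantified sites
ribosomal and ~15% of sites affected (matching the 101/972 and 141/972
proportions of the motivating screen); a planted 4-fold occupancy
decrease; noise SD 0.3 log2 units (a typical replicate spread for
SILAC ratio data); affected sites concentrated in the ribosomal category
with odds 8 (reproducing a >50% vs ~11% within-category decrease split);
1270 proteins in the iBAQ table with 10% planted accumulators at 5× noise
SD. Cage fixtures use a uniform 1.70 Å pseudo-atom radius so the critical
aperture has a closed form.

What the generators deliberately do **not** emulate: peptide-level
identification error and missing-value structure, between-run intensity
drift, protein inference ambiguity, correlated noise across sites of one
protein, and any spectral-level process. Passing the synthetic suite
therefore shows the *aggregation and classification machinery* is
correct and calibrated under the stated noise model; it does not certify
performance on real MaxQuant output with its censoring and contaminant
structure.

## Numerical choices and degenerate inputs

* Direction grids and cage lattices are Fibonacci-sphere constructions:
  deterministic, seed-free, quasi-uniform.
* Probe clash uses strict `<`, so an exactly tangent pose counts as
  clear; the boundary case is measure-zero and covered by the
  `clearance_slack` sensitivity knob.
* A single-replicate site (allowed only with `min_reps=1`) gets a
  ±∞ CI and a degenerate flag rather than a fabricated interval; a
  single-replicate ΔiBAQ gets SEM 0, flagged in the log.
* Zero decreased sites yield a zero-count fraction table, not a division
  error; an empty odds-ratio cell follows the convention ∞ when the
  numerator is positive, NaN for 0/0.
* Report JSON uses sorted keys and 6-decimal floats so re-runs are
  byte-identical and diffable.

## Problem sizes

The test and acceptance runs use scaled simulation sizes chosen to keep
Monte-Carlo error well inside the asserted margins: 1000 sites × 10 seeds
for sensitivity/FPR, 1000 null sites for CI coverage, 300–500 proteins ×
10 seeds for accumulator recovery (the printed 1270→127 decile arithmetic
is checked exactly at n = 1270), 8-point aperture sweeps certified at
10⁵ oracle directions.

## Known limitations

* The geometric criterion is a reachability upper bound; counts under a
  strict-channel reading could differ by a site or two near the margin.
* Whether ions and ligands were obstacles in the published structural
  counts is unknown; both settings are exposed, neither is privileged.
* Category annotations are user-supplied; no live GO retrieval, so
  annotation-database p-values are out of scope.
* No imputation: a site missing in a replicate simply does not count
  toward `min_reps`.
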