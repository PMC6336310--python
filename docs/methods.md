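# Methods

## Scope and data model

The package analyzes annotated immunoglobulin rearrangement records — one
record per sequenced transcript — for a 2×2×2 factorial experiment with
factors AOS (antiorthostatic suspension), TT (tetanus toxoid) and CpG
(adjuvant). A record carries gene-level V/D/J calls (alleles are collapsed
at parse time; every reported analysis is gene-level), an isotype from an
identifiable constant region, the junction amino-acid string (CDR3 plus the
conserved C and W/F anchors), the D alignment length in nucleotides, and
tri-state frame/stop evidence. Tri-states make the "unknown functionality"
class — short transcripts without enough sequence to decide — representable
without any nucleotide-level reasoning.

Heavy (IGH) and kappa (IGK) chains are analyzed separately throughout:
bulk RNA-seq has no chain pairing information. Lambda records are parsed
but dropped at analysis entry; they are a small (~5 %) fraction of light
chains and none of the reported analyses use them.

## Counting rules

* **Fractional abundance.** Call list of length 1 → weight 1.0; length 2 →
  0.5 to each gene; length ≥ 3 or 0 → the record is excluded from the axis,
  numerator *and* denominator. The percent denominator is the total
  assigned weight on that axis for that animal, which is what keeps every
  row summing to 100 exactly.
* **Undetermined category.** On the D and J axes (and in pairing), an
  unresolvable segment is counted as "U": D when unreported,
  multi-candidate, or aligned < 6 nt; J when unreported or multi-candidate.
  The < 6 nt rule is applied to D only by default — the concern it encodes
  (spurious short matches) is specific to the very short D segments — but
  `d_length_rule_on_j` extends it to J. The V axis has no "U": the V call
  anchors a record, so un-callable-V records are simply excluded.
* **Pairing eligibility.** A record contributes a V/(D)/J combination only
  when productive, motif-valid, and carrying exactly one V candidate.
* **Usage denominator population.** Usage runs on productive + unknown
  records by default (the two classes that make up "total assessed reads");
  `productive_only` restricts it.
* **High-frequency segments.** Strictly greater than 5 % group-mean usage
  in at least one named treatment cell; ties at exactly 5 % excluded
  (literal reading of "over five percent").
* **Low-frequency pair filter.** A V/J pair is dropped only when its mean
  percent is below 0.1 % in *both* compared factor levels.

## CDR3 sharing semantics

Identity is the full junction amino-acid string within a locus. A group's
set is the union over its animals, deduplicated after pooling, so a CDR3
seen in three animals of one cell counts once for that cell. The
shared-by-k table counts, over the union of all group sets, how many group
sets contain each sequence; percentages are of the union and rounded
half-up to 2 decimals (decimal arithmetic, so printed-table values like
0.155… → 0.16 reproduce exactly). Pairwise overlaps report the
intersection size and the percent of *each* side's repertoire separately.

## Statistics

* **Three-way ANOVA.** `y ~ AOS*TT*CpG` fitted by OLS per feature, type-I
  sums of squares. All designs produced here are balanced, where type-I =
  type-II = type-III and term p-values are invariant to factor order (this
  invariance is tested). Responses are raw percentages; no
  arcsine/logit transform is applied, a documented limitation for
  compositional data (a depressed gene inflates its competitors'
  percentages, so renormalization can propagate a strong single-gene effect
  to other features). Zero-variance responses are flagged degenerate with
  p = 1. Per-feature ANOVAs are reported without cross-feature
  multiple-testing correction, matching the per-segment reporting style
  they emulate.
* **Post-hoc contrasts.** Tukey HSD over treatment cells
  (`statsmodels.pairwise_tukeyhsd`).
* **Per-animal variance.** Per feature, (animal percent − across-animal
  mean percent)², summed over the axis's features for a whole-animal
  variation score; compared across the 8 cells by a cell-means linear
  model whose LS-means reduce to cell means on this balanced layout, with
  Tukey-adjusted pairwise contrasts and a global F test. Tukey adjustment
  is our explicit choice where the emulated SAS procedure's adjustment is
  unstated.
* **Marker screen.** Signed fold change `m₊/m₋` if `m₊ ≥ m₋` else
  `−(m₋/m₊)` (|FC| ≥ 1 by construction, sign = direction); p from a Welch
  t test on log₂(TPM+1) — a declared stand-in for the original pipeline's
  unspecified differential-expression engine. The flag is exactly
  |FC| > 2 ∧ p < 0.05; a 1.4-fold change never flags regardless of p.
* **Usage regression.** OLS of one group-mean usage vector on another;
  R² and slope p reported.
* **Trial/replicate labels** are carried in the design but not modeled by
  default (the emulated model has only the three factors).

## Simulator: the stated world

Each animal's records are i.i.d. draws. V/D/J genes come from power-law
baseline weights (`w ∝ 1/rank^a`, a = 1 for V: with 20 genes a handful
exceed 5 % of the repertoire, as real repertoires do) multiplied by the
effect multipliers of every '+' factor of the animal, renormalized.
Isotypes draw from an IgM-dominated base mix the same way. Junctions are
`C + core + anchor`, cores Poisson-length (mean 12 AA heavy, 9 AA kappa —
the average CDR3 lengths the emulated data shows) sampled from a finite
shared "public" pool with probability `p_public = 0.2`, else freshly
random. Defaults: 4 animals per cell across two trials (the sequenced
cohort), 10⁴ reads/animal as a desk-scale stand-in for the ~10⁵ assessed
reads per animal; ambiguity and functionality rates (two-V 10 %, ≥3-V 3 %,
D missing 25 %, D short 15 %, unknown functionality 45 %, unproductive
5 %) are set to make the undetermined-D category large and the
productive/unknown split roughly even, as observed. All rates are
configurable; none is asserted.

What the generator does **not** emulate: somatic hypermutation and clonal
lineages, sequencing error, paired heavy/light chains, biological
between-animal variation beyond multinomial sampling (each animal in a
cell shares the same expected composition), and any realistic public-clone
generative process — the finite-pool model is the minimal structure that
makes sharing curves and overlaps nontrivial, and only monotonicity in
`p_public` is claimed. A green recovery test therefore establishes that
the pipeline detects effects of the injected multiplicative form at
multinomial noise levels, not that it would have the same power against
biological dispersion.

Two consequences worth noting. First, with only sampling noise between
animals, the ANOVA's residual variance is the multinomial one, so the
power benchmark (multiplier 0.2 on one V gene detected in ≥ 80 % of seeds
at 10⁴ reads, n = 4/cell) is a simulation-defined bar, not an empirical
claim. Second, ambiguous-call injection slightly distorts realized usage
relative to the target weights (the second candidate gene is uniform, not
weight-proportional), so the weight-convergence check runs with ambiguity
rates zeroed.

For many-replicate calibration the simulator exposes a fast path
(`simulate_usage_counts`) that draws per-animal V-gene counts directly
from the effect-adjusted multinomial — distributionally identical to
counting unambiguous records, and tested against full record synthesis at
desk scale.

## Numerical and design choices

* Report-layer rounding is decimal half-up; internal tables are full
  precision.
* Rank ties in top-k pairing break lexicographically by (v, d, j) and are
  flagged, so heat maps are reproducible.
* "Class switching" covers all non-IgM/IgD heavy isotypes including IgE
  and the IgG subclasses; isotype report tables aggregate the subclasses
  to "IgG".
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawns per (locus, animal); identical
  (config, seed) runs produce byte-identical AIRR files and analysis
  bundles, which is tested at the bundle level.
* Determinism and calibration tests run at reduced read counts; scale
  affects runtime only, not the properties under test.

## Known limitations

* Compositional coupling of percentages (above) means single-gene effect
  attribution is approximate when effects are large.
* The Welch-on-log TPM screen is not numerically identical to the original
  CLC differential-expression tool; only the flag rule is faithful.
* Sharing analyses treat a CDR3 string as a clone; no nucleotide-level
  clonotyping or similarity networks.
* AIRR I/O covers the column dialect this pipeline consumes, not the full
  AIRR schema.
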