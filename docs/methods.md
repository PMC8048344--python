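# Methods

This note documents the models behind each stage, the synthetic data
the package is validated on, the numerical choices, and what passing
tests do and do not demonstrate about real data.

## The synthetic study conditions

The default benchmark plants five paralogous domain families of 40
members each on one generating tree, embedded in longer proteins:

* **Domain frame.** 78 alignment columns; no indels inside domains, so
  columns coincide with residue positions and planted truth is exact.
  Length variation comes from flanks (30–120 residues of i.i.d.
  background-composition sequence on each side) and from envelope
  trimming during search.
* **Conservation architecture.** All families share a planted core:
  hydrophobic columns 7/11/27/61 and three cross-helix pairs —
  30 (aromatic [FY]) with 69 (cationic), 19 (anionic) with 54
  (cationic), 62 (cationic) with 74 (anionic). Each family adds three
  family-specific conserved columns. Conserved columns evolve by
  resampling *within* their residue group, so group identity is
  preserved while the residue may change.
* **Outgroup.** One family is truncated after column 60, the four-helix
  regime: it loses the fifth helix and with it every pair position
  above 60, and its members' coverage against full-length domains drops
  below the 0.8 clustering gate — it isolates immediately, as a
  divergent sister fold would.
* **Subfamily.** One family is generated as two 20-member subclades
  separated by a calibrated stem (cross-subfamily identity ≈ 0.50
  against within-subfamily ≈ 0.78), so the incremental clustering trace
  has a planted split to find in the mid-60s percent range.
* **Identity calibration.** The substitution process is per-site
  categorical resampling along the tree (probability 1 − e^{−rt} per
  branch). Branch lengths are grouped into classes — within-clade (one
  per family), subfamily stem, backbone — and each class scale is set
  by bisection against its empirical target: each family's mean
  pairwise identity hits its specification (default 0.65), the
  subfamily stem hits the cross-subfamily level, and the backbone is
  calibrated on the *closest* family pair (0.22), so no family pair
  drifts toward within-family levels. The random draws are coupled
  across bisection trials (all uniforms and candidate residues are
  drawn per site regardless of the rate), making identity monotone in
  the scale and the search well behaved.
* **Decoys.** 500 background-composition proteins of 150–400 residues
  with the embedded Robinson–Robinson amino-acid frequencies; about 5 %
  of family proteins carry a tandem second domain copy.
* **Topology regimes.** Family clades are random join trees by default
  (realistic identity gradients, correlated drift). A `star` topology
  puts essentially all divergence on pendant edges, making members
  conditionally independent given the family root — the regime of a
  deep, dereplicated cluster. Conservation properties are validated on
  star families at mean identity ≈ 0.30: there, planted columns stay
  group-conserved (they resample within their group) while drifted
  columns cross the 75 % rule in ≤ 2 % of cases. On correlated-drift
  families at identity 0.65 a large share of *all* columns exceeds the
  group-conservation threshold — the regime of a highly conserved
  cluster, where the profile legitimately colors most of the surface —
  so the planted/unplanted discrimination is only a meaningful claim in
  the deep-family regime.

What the generator does **not** emulate: indel evolution inside
domains, site-rate heterogeneity, composition drift across clades,
database-scale redundancy, and homologous-but-unrelated folds. Passing
recovery tests therefore shows the pipeline's logic and statistics are
sound at realistic identity levels, not that real-database sensitivity
will match.

## Profile HMM

`build_profile` assigns columns with gap fraction < 0.5 to match
states. Emissions are Henikoff position-based weighted counts smoothed
with α = 0.5 background pseudocounts; transitions come from the
observed per-sequence state paths with Laplace pseudocounts (I→D is
not modelled, plan7-style). Scoring is local: log-odds in bits against
the background null, uniform entry and exit over the k match states
(−log₂k each), insert states emitting at background (zero log-odds), so
flanking residues are free apart from entry/exit. Viterbi is the scored
statistic; forward is available and is verified against a hand-
enumerated path sum on a toy model. Calibration fits a Gumbel law by
maximum likelihood to the Viterbi scores of 5000 i.i.d. background
decoys at the median database length and reports the KS fit statistic.
Search E-values are n_targets × Gumbel P-value; accepted envelopes are
masked and the flanks rescanned, so tandem domains are found. This is
deliberately simpler than HMMER (no dual-tail machinery, no glocal
mode, no acceleration filters); bit-for-bit parity with hmmsearch is
not a goal.

The benchmark seed alignment takes five members *spread evenly* across
each family — a curated superfamily seed whose known members span each
family's diversity, including both subfamilies of the split family.
With a first-five seed the unrepresented subfamily costs ~8 points of
sensitivity; a representative seed is what a curated starting set
provides in practice.

## Pairwise alignment statistics

Alignment itself is Biopython's PairwiseAligner under BLOSUM62 with the
BLAST gap convention (a gap of length L costs 11 + L), wrapped so that
scores, identities, coverage and the two denominare conventions
(aligned columns, shorter, longer sequence) are explicit. λ is the
analytic ungapped solution (bisection to 10⁻⁹, 0.3176 for BLOSUM62
under proteome-average background). Because raw scores are integers,
E-values live on discrete atoms spaced by a factor e^λ; the decoy
calibration therefore stores the empirical survival curve of background
scores for the bulk and switches to the λ-exponential tail beyond the
calibration range, with K matched at the median. Calibration quality is
asserted at the achievable atoms: the observed frequency of E ≤ t
matches N(1 − e^{−E*}) within 3√expected, where E* is the largest
achievable E ≤ t. For clustering, identity uses the longer-sequence
denominator with a 0.8 reciprocal-coverage gate (silix-like defaults);
both are configurable.

## Clustering and the split trace

Fixed-threshold clustering is single linkage on the thresholded
identity graph. The incremental trace raises the threshold in 1-point
steps (the granularity at which such thresholds are reported); a
tracked cluster splits when at least two components each reach the size
rule — 5 % of the full set at first isolation, 10 % of the parent
thereafter, and never below two members, since a cluster dissolving
into singletons produces outliers, not subclusters. Members falling
into sub-threshold fragments are shed silently, so each recorded node
is a cluster at its emergence threshold. Redundancy reduction is greedy
longest-first with identity over the shorter sequence (exact
alignments, no k-mer prefilter).

## Communities

Significant pairs (E ≤ 10⁻⁴) enter with weight −log₁₀E (floored at
10⁻¹⁸⁰): modularity needs positive weights and stronger similarity
should weigh more, so the magnitude transform is the working reading of
"log of the scores". Louvain runs with eight seed-derived restarts and
keeps the best modularity; on graphs of at most eight nodes the
partition space (Bell(8) = 4140) is enumerated instead, so tiny-graph
results are exact optima by construction rather than heuristic luck.

## Phylogeny and branch supports

Distances are p-distances with pairwise deletion, optionally Poisson
corrected (d = −ln(1−p)) and capped at d = 5 with a warning — outgroup
comparisons at ~10 % identity saturate and the cap keeps the matrix
finite. NJ is the canonical Q-criterion algorithm with Studier–Keppler
updates; ties break on the lexicographically smallest taxon pair
(internal nodes inherit their smallest leaf name) and negative branch
lengths clamp to zero with a warning, so results are order-invariant
and deterministic. TBE is computed exactly: for branch b with lighter
side p, δ(b,T) is the minimum over *all* branches of T of the Hamming
distance between indicator vectors up to complementation, and
TBE = 1 − mean δ/(p−1); FBP is exact bipartition presence. Cherries
(p = 2) use the same formula, where δ ∈ {0,1} forces TBE = FBP.
Trivial p = 1 branches are transferable at zero cost. ML inference is
out of scope; NJ keeps the pipeline self-contained, and since TBE is
tree-source-agnostic, trees from external ML tools can be imported as
Newick and passed to `tbe_support` unchanged. Rooting places the root
at the midpoint of the branch separating the outgroup clade, after an
explicit monophyly check that names the conflicting taxa.

## Conservation and variants

Filtering removes columns with > 90 % gaps first, then sequences gapped
on > 20 % of the remaining positions — the order matters and is fixed.
A column is grayed below 80 % representation; otherwise colored with
its dominant group's display class when that group exceeds 75 % of the
**non-gap** residues (the representation rule already penalises
gappiness; counting gapped sequences in the denominator is available as
an option). Groups [W] and [C] are not part of the classical color key
and display as hydrophobic and polar respectively; this is
presentational only. Pair 30–69 requires the aromatic group [FY] at 30
and either charge class at 69 ("aromatic to charged"); the two salt
bridges require their specific charge classes. Pairs with a missing
column — e.g. the truncated outgroup — report as not evaluable.
Per-cluster profiles extracted from a master alignment keep master
column numbers, so positions are comparable across clusters.

Variant mapping translates a protein position inside a hit envelope to
the domain-local index, validates the reference residue against the
stored domain sequence (a mismatch raises a provenance error — isoform
or sequence-version drift is the main real-world hazard), and follows
the member's column map to the master frame. Annotation is a pure
function of (column, profile, position sets) with a fixed three-note
vocabulary: conserved stabilizing-pair member → "may impair domain
stability"; groove-lining → "may affect partner binding"; otherwise
"effect unclear".

## Problem sizes and determinism

The test-suite and acceptance script run the full benchmark (5 × 40
members, 500 decoys, 5000 calibration decoys), 1000 alignment-oracle
pairs, 100 additive NJ matrices, and 200-replicate bootstraps on ~20
representative taxa; a full pipeline run uses 1000 bootstrap replicates
by default, and test runs scale that to tens. All randomness flows from
a single master seed through named substreams, so identical
configurations reproduce byte-identical outputs (asserted on stage
checksums).

## Known limitations

* Sensitivity estimates inherit the generator's simplifications; the
  truncated outgroup family loses 1–3 members at some seeds (short
  domain, weaker scores), which is the realistic failure mode.
* The Gumbel calibration assumes i.i.d. background targets; biased
  composition databases would need a composition-adjusted null.
* Single-linkage clustering merges families on any single above-
  threshold edge, so thresholds in the immediate vicinity of the
  between-family identity tail are unreliable by construction; the
  family-recovery claim holds for thresholds comfortably between the
  between- and within-family levels.
* NJ is a distance method; very short internal branches that ML would
  resolve may collapse or flip, which the TBE supports make visible
  rather than hide.
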