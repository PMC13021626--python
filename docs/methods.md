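# Methods

## The compendium model

A compendium is a set of datasets, each belonging to a study (PMID) and
annotated with a condition code, of kind *profiling* (detection lists) or
*differential* (fold change + p-value per observed site). Observations are
keyed by (site, dataset); at most one observation per key is allowed.
Duplicate peptide-level rows for one site in one dataset are either rejected
(default, with row-level diagnostics) or collapsed to the most extreme
|log fold change| (`on_duplicate="collapse"`), since multiple peptides
covering the same site are a data-entry artefact rather than independent
evidence. Site coordinates are 1-based on the canonical protein sequence;
isoform positions must be pre-mapped through the optional mapping table,
which is a frozen snapshot — the package never queries a live identifier
service.

### Regulation calling

UP iff fold change ≥ `up_fc` (default 1.3) and p < `alpha` (default 0.05);
DOWN iff fold change ≤ `down_fc` (default 0.76) and p < alpha; otherwise NS.
Fold-change boundaries are inclusive and the p-value cut-off strict, taking
the stated inequalities literally. A differential row with a beyond-threshold
fold change but no p-value is NS by default; `trust_prefiltered` treats such
rows as already significant, for sources that ship pre-filtered tables. The
conservative default means a compendium of p-value-free tables yields no
calls unless the user opts in explicitly.

### Predominance

A site is predominant when its differential-dataset fraction strictly
exceeds `predominance_fraction` (default 0.5, i.e. "more than half"). The
natural-language rule ("profiling and differential datasets") and the
ranking practice (differential frequency) pull in different directions, so
the denominator universe is a switch: `differential` (default — the number
of differential datasets in which any site of the protein was quantified),
`profiling`, or `both`. Neither choice is asserted as canonical; the default
reproduces differential-frequency ranking. Ties are broken by ascending
sequence position so output is deterministic.

## The co-regulation screen

Per (anchor, PsOP) pair, each dataset where both sites carry directional
calls contributes to exactly one of nUU/nUD/nDU/nDD; NS or missing
observations exclude the dataset. The 2×2 table [[nUU, nUD], [nDU, nDD]] is
tested one-sided (Fisher exact, hypergeometric null conditional on both
margins): the `greater` tail asks whether the PsOP's direction is enriched
for concordance with the anchor, the `less` tail for discordance. This table
is the only 2×2 constructible from the four direction categories without
external counts; it tests association of the two sites' directions across
datasets, not their marginal regulation rates.

The four high-confidence criteria are FET p < `hc_fet_alpha` (strict),
support ratio ≥ `hc_ratio` (inclusive), ≥ `hc_min_pmids` distinct studies
and ≥ `hc_min_codes` distinct condition codes among the supporting
(concordant for positive, discordant for negative) datasets. The ratio
denominator defaults to the number of datasets in which the anchor itself is
differential (`ratio_denominator="anchor"`), which keeps the criterion
attainable for PsOPs quantified in subsets of the compendium; the whole
differential compendium is available as an option. No multiple-testing
correction is applied — the screen filters on raw FET p plus the replication
criteria; a Benjamini–Hochberg column is available as a clearly separated
optional extension of the output table. A site can pass in at most one
direction, the one with strictly larger support; equal support both ways is
flagged ambiguous and passes neither. Results are ordered by descending
support, then p, then site label, and are invariant to input row order.

## Intra-protein co-occurrence

Pairs of sites on one protein reuse the same tally, with sites in canonical
ascending-position order (no anchor/other asymmetry within a protein). The
positive frequency is Σ(nUU+nDD)/Σ(nUD+nDU) and the negative its
reciprocal; a zero denominator is reported as `inf` with a flag rather than
clamped, so the reciprocity identity pos·neg = 1 holds on all finite nonzero
cells. The matrix view places positive frequencies in the upper triangle and
negative in the lower, NA where undefined.

## The synthetic generator

The generator emulates the screen's assumed statistical structure, not mass
spectrometry: D differential datasets partitioned into studies by contiguous
blocks with condition codes assigned round-robin; an anchor site that is
differential with probability `anchor_diff_fraction` per dataset (direction
a fair coin, NS otherwise); positively/negatively coupled sites that
follow/mirror the anchor's direction with probability `coupling_prob` when
detected (`detection_prob` per site per dataset), falling back to fair coins
where the anchor is NS; and independent background sites. Detected sites in
differential datasets always carry a direction. Fold-change magnitudes are
log-normal (location log 2, scale 0.35) truncated at the calling cut-offs,
and p-values are Uniform(0, alpha) for directional calls and
Uniform(alpha, 1) with a neutral fold change for NS, so every generated
observation re-classifies exactly to its intended call — the generator's
semantics are exact, not approximate. One `numpy.random.Generator` seeded
once drives everything; identical seeds give byte-identical output.

Default benchmark condition: D = 40, 8 studies, 10 condition codes,
anchor fraction 0.6, detection 0.8, coupling 0.95, and 30 + 30 + 270
positively coupled / negatively coupled / background sites. The 330-site
total and the positive-set size follow the recovery benchmark; the split of
the remaining 300 into a symmetric coupled complement plus background was
fixed once as the neutral choice. What the generator does **not** model:
peptide-level ambiguity, missingness correlated with abundance, study-level
batch effects, or correlation among background sites — so passing recovery
tests show the screen recovers its own assumed signal structure, not that
real compendia satisfy those assumptions.

A note on attainable precision under these conditions: a background site is
co-differential with the anchor in ≈ 19 datasets, where the one-sided FET at
α = 0.05 passes ≈ 2–3% of null sites per direction and the replication
criteria do not bind (≈ 8 studies, ≈ 10 codes, ratio ≈ 0.4). Over 270
background sites that is ≈ 5–7 false positives against ≤ 30 true positives,
so the expected precision of the positive-set recovery sits near 0.85 (the
type-I calibration test bounds the same quantity from the null side). Making
precision higher would require either fewer background sites or a more
stringent test than the screen defines; neither is adjusted here.

## Structure

PDB parsing, Shrake–Rupley ASA (probe 1.4 Å, 1000 surface points, ProtOr
united-atom radii) and secondary structure are delegated to biotite. For
secondary structure the geometric P-SEA assigner is used: the pipeline
consumes only the binary loop indicator, for which a full hydrogen-bond
8-state assignment adds nothing; the 8-state DSSP alphabet is still accepted
at the `loop_indicator` boundary ({H, G, I, E, B} → 0; {T, S, P, -} → 1,
with isolated β-bridges counted as sheet and polyproline as loop). RSA
divides ASA by the Sander–Rost residue maxima (the table matching DSSP-style
normalisation; Tien 2013 selectable) and clips to [0, 1] — an isolated
residue exceeds the folded-chain maximum and clips to exactly 1. pLDDT is
taken from the CA B-factor and divided by 100; an all-zero B-factor column
is treated as missing pLDDT, entering the PAI as 0 with a flag, never
silently imputed. The PAI weights (0.5, 0.3, 0.2) sum to 1, so PAI ∈ [0, 1],
is monotone in each input, and the loop term contributes exactly 0.2.
The test suite checks the ASA against an independent Shrake–Rupley
implementation (Bio.PDB) run with identical radii (agreement to 1%), and
the secondary-structure contract on ideal-geometry fixtures (a parametric
α-helix CA trace must be rigid, an extended trace loop).

## Conservation

Column entropy uses frequencies over observed residues, excluding gaps
(`gap_as_state` includes the gap as a 21st state); all-gap columns are
undefined (NaN, flagged). No pseudo-counts are added: with tens of
orthologues they would materially inflate H near zero. Class boundaries are
inclusive to the moderate class (H = 0.10 and H = 0.50 are moderate).
Query coordinates map to columns by counting non-gap query characters;
columns are 1-based. A species conserves a site when its row is non-gap and
identical to the query at the column; an optional ±w context window extends
the identity requirement to flanking columns (off by default — the exact
context rule used in the motivating analysis is unstated, so it is an
option, not an assertion). The origin clade is the LCA of the conserving
species in a user-supplied child→parent taxonomy (single root, acyclic,
validated at load); no live taxonomy service is queried.

## Annotation overlay

Annotation tables are matched by gene symbol, or by (symbol, position) for
site-specific tables under `level="site"`; gene-level is the default since
exported interactor lists are gene-level and site-level sources vary in
coordinate conventions. No fuzzy matching: a silent mismatch is worse than
a reported non-match. Duplicate entries merge their source labels.
Percentile-scored predictor exports are filtered by `min_percentile`
(e.g. 90 keeps the top decile). The join never alters the screen columns,
and anchor comparisons are plain set intersections/differences over passing
PsOPs in deterministic sorted order.

## Problem sizes and numerical conventions

The test suite and acceptance checks run at fixture scale chosen for the
package's own CI: screens over 40-dataset, ≈ 330-site compendia (20 seeds
for null calibration, 10 for recovery), an exhaustive Fisher-vs-enumeration
sweep over all 2×2 tables with margins ≤ 12, and toy structures built
programmatically. The Fisher p equals margin-conditional hypergeometric
enumeration to better than 1e-12 (integer arithmetic in the oracle).
Screens are byte-deterministic on fixed input.

## Known limitations

- Headline counts from the motivating TNIK study (e.g. 1349 positively
  co-regulated PsOPs for S640, co-occurrence frequencies 5.3/5.6/4) require
  its curated 182-dataset compendium, which is not redistributable here; the
  package reproduces the procedure, with the synthetic generator standing in
  at fixture scale.
- Printed RSA values from any particular study depend on its exact ASA
  backend and max-ASA table; agreement at 3 decimal places across backends
  is not guaranteed (RSA here: ProtOr radii + Sander–Rost maxima).
- P-SEA assigns secondary structure from CA geometry; on real structures it
  agrees with hydrogen-bond assignments for most residues but can differ at
  element boundaries — the loop indicator inherits that behaviour.
- The screen models directional calls only; fold-change magnitudes beyond
  the calling thresholds carry no weight.
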