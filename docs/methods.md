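# Methods

This note records the models, rules and numerical choices implemented in
`sig70arch`, and what the synthetic cohorts do and do not establish.

## Homolog identification from domain hits

Input is HMMER3 per-domain tabular output (`domtblout`).  The parser reads
the per-domain alignment coordinates (`ali from`/`ali to`, 1-based
inclusive), the per-domain bit score and the independent E-value
(`i-Evalue`); the conditional E-value is ignored because it depends on the
other domains of the same sequence.  The target-length column (`tlen`) is
kept as the protein length so the FASTA is optional.

**Thresholding.**  A hit survives if its domain bit score reaches the
profile's gathering (trusted) cutoff.  The comparator defaults to `>=`
because gathering cutoffs are curated as inclusive bounds; a strict `>` is
available as a configuration switch.  Thresholds are a per-profile pair
(sequence-level, domain-level); only the domain-level cutoff is enforced by
default — per-domain records do not carry the full-sequence score, and the
sequence-level value is retained for completeness.  Unknown profiles are an
error unless the table declares a default pair.

**Overlap resolution.**  When hits overlap (share ≥ 1 residue; a tolerated
overlap fraction of the shorter hit is configurable, default 0), the longest
hits with the best E-values win.  Concretely: sort by (alignment length
descending, E-value ascending, start ascending, profile name ascending) and
accept greedily, rejecting any hit that overlaps an accepted one.  The last
two sort keys are tie-breaks added to make the selection a total order, so
the output is independent of input order.  The result is a maximal
antichain under residue overlap.

**Seed requisite.**  A protein is a putative sigma70 homolog only if at
least one surviving hit comes from the seven seed profiles (r1_1, r1_2, r2,
r3, r4, r4_2, ECF).  The seed set is overridable — setting it to
`{DUF6596}` turns the same pipeline into the accessory-domain survey.

## Architectures and decomposition

An architecture is the N→C ordered token sequence of the resolved hits,
written with `*` separators.  Long profile names are shortened through an
editable alias table (`Sigma70_r2` → `r2`, …); unknown profiles pass through
unchanged, which is how accessory domains keep their Pfam names.

The essential vocabulary is closed — r1_2, r2, r3, r4, r4_2, ECF — with
canonical ranks r1_2 < r2 < r3 < r4 ≡ r4_2 and ECF ranked after r4.  r4 and
r4_2 deliberately share a rank: a pattern carrying both has no canonical
order and is therefore non-canonical.  Everything outside the vocabulary is
accessory, an open set, so classification stays total on novel genomes.

Decomposition restricts the architecture to essential tokens (the core
pattern) and labels each accessory token N, C, or internal relative to the
core span.  Internal accessory domains have not been observed in
cyanobacterial cohorts (accessory domains sit at the protein extremities);
they are accepted rather than rejected, flagged with a warning, and mapped
to the both-sides placement class for numbering, because a classifier that
errors on unseen layouts would not be usable on new genomes.

## Clan and family assignment

The shipped registry (`data/clans.yaml`) defines twelve primary clans A–L by
their essential-domain sets, each with a canonical core pattern, plus the
miscellaneous clan Z.  Family index = base + placement offset, with offsets
1/2/3/4 for no AD / N-terminal / C-terminal / both sides, base 0 for the
canonical core and base 4k for the clan's k-th registered non-canonical
core.  This makes 5–8 the block of the first non-canonical pattern and 9–12
the second, and so on; registration is append-only, so numbering never
shifts once assigned.  Clan A ships one registered non-canonical core
(r1_2\*r3\*r2\*r3\*r4, families A.5–A.8).

Z has no defined core, so every pattern routed to Z occupies non-canonical
blocks (Z.5+, Z.9+, …).  With `--auto-extend-clans`, an unseen
essential-domain set instead registers the next unused letter (skipping Z);
its canonical pattern is the set sorted by rank, name as tie-break.

One genuinely ambiguous point in the legacy cross-reference material: the
historical SigL/SigR labels are attached to r4_2 and r4_2\*NB-ARC\*TPR_MalT
architectures in a way that conflicts with their published unit names.  The
registry follows the architecture rules (r4_2 → K.1, r4_2 with C-terminal
ADs → K.3) and leaves the legacy labels out of the classification proper.

Unit suffixes within a (genome, family) group are assigned 1..n along a
deterministic ordering key (protein id by default; replicon/coordinate
columns can be supplied).  Historical numbering was arbitrary; determinism
was chosen so reruns are bit-identical.

Primary vs alternative factors within A.1 are *not* distinguished — domain
structure alone cannot separate them.

## Cohort statistics

Counts are assembled into a complete genome × family integer matrix
(zero rows included).  Heatmap export bins cells into {0, 1, 2, ≥3}.
Taxonomic orders with fewer than 10 genomes are merged into "Others" before
boxplot-style comparisons.

The group-comparison cascade: Shapiro–Wilk on each group at α = 0.05; if
both pass, a two-sided two-sample Student t-test (equal variances —
matching the classical test, not Welch); otherwise the two-sided
Wilcoxon–Mann–Whitney test, exact null distribution when both groups have
n ≤ 20 and no ties, normal approximation with tie correction otherwise.
Constant groups short-circuit: all-identical data give p = 1.  Stars are
\*/\*\*/\*\*\* at p < 0.05/0.01/0.001.  Stars are reported on raw p-values
(the convention for these cohort reports); a Benjamini–Hochberg column is
emitted alongside so readers can apply a correction if they prefer.

Heterocyst enrichment per family is a two-sided one-sample t-test of the
H-group per-genome counts against the mean of the pooled non-H genomes (the
reference is configurable); the direction of the difference decides whether
a family is enriched or depleted in heterocyst formers.  Genomes with an
unclassified morphotype should be mapped to U upstream, mirroring the usual
convention for ambiguous cyanobacterial strains.

The count vs genome-size relation is summarized by Spearman rank
correlation (monotone association, no linearity assumption), flagged when
fewer than 10 genomes are available.

The accessory survey reports, per clade: % genomes carrying the queried
domain, % of domain-carrying proteins that also carry an essential sigma70
domain, and the family breakdown of those proteins with `Ud` for
accessory-only proteins.  Clades below 15 genomes (configurable) merge into
a catch-all group so percentages are not computed on tiny denominators.

## Domain-edit scenarios

Core patterns evolve by typed unit-cost events: loss and gain of an
essential token at any position, substitution restricted to the r4↔r4_2
variant pair, ECF formation consuming an adjacent r2 + r4 (or r4_2) pair,
and gain/loss of a generic accessory token `AD` at the termini only
(accessory insertion is a late, terminal event).  ECF formation is a single
composite "modification" event of cost 1 and is irreversible — nothing
splits an ECF back into r2 + r4; an alternative decomposition is available
through the cost table.  ECF cannot be gained directly: it only arises
through formation.

`min_event_path` is a best-first (uniform-cost) search over the pattern
space, bounded at 8 tokens by default.  To keep distant pairs tractable the
search is guided by an admissible alignment lower bound (a weighted edit
distance in which deletion/insertion cost the loss/gain of the token,
r4↔r4_2 alignment costs the substitution, and a source r2+r4/r4_2 pair may
merge into a target ECF at the formation cost); the bound never exceeds the
true cost, so returned paths remain minimal.  Ties between minimal-cost
paths are broken by the lexicographically smallest event-sequence key,
making results deterministic.  An optimal path never needs an intermediate
longer than the longer endpoint, which the test oracles exploit.

The shipped diversification scenario roots at A.1 and reaches A.5, B.1,
C.1, D.1, E.1, F.1, F.3, H.1, H.3, J.1, K.1 and K.3, every edge a single
event; D.1 is kept reachable from both C.1 (substitution) and F.1 (r3
insertion) as genuine alternatives.  ECF-only L.1 origins are shipped as a
separate edge set (single events from E.1/F.1, two events from
B.1/C.1/D.1).  Scenario verification is edge-by-edge; no global
Steiner-tree optimization over hypothetical intermediates is attempted —
the scenario is asserted, and the package checks its per-edge parsimony.
Gene duplications (family expansions) are copy-number annotations, not
architecture events.

## Synthetic cohorts

`generate_cohort` fabricates, from a single mandatory seed: FASTA proteomes
(random residues — the pipeline consumes hits, not alignments), one
domtblout hit table (genome ids carried in the description field), a
threshold TSV, genome metadata and a truth table of planted family labels.

Default conditions (`default_paper_like_spec`): 200 genomes at a 90/44/66
U/F/H split; per-family Poisson counts with per-morphotype means chosen so
U/F genomes average ≈ 11.3 homologs and H genomes ≈ 13.8 (overall ≈ 12,
with ~90% of genomes between 5 and 17); A.1 and F.1 planted as
1 + Poisson(mean − 1) so both occur in every genome; L.1 mean 0 in H
genomes (ECF-only factors are absent from heterocyst formers); CDS counts
drawn per morphotype (H largest) with a positive per-homolog slope so the
count/size correlation is planted.  Domain lengths make a full
r1_2\*r2\*r3\*r4 protein ≈ 350 aa and an ECF-only protein the shortest.
True hit scores sit an exponential margin (scale 15 bits) above the 22-bit
cutoffs; decoys are either 1–5 bits below threshold or nested inside a true
hit (strictly shorter, worse E-value) so the overlap resolver must remove
them.

What passing on synthetic cohorts shows: the rules are implemented
correctly and the pipeline is exact on inputs that obey them.  What it does
not show: robustness to real-data pathologies — fragmented or chimeric gene
models, marginal bit scores at the cutoff, profile versions with shifted
gathering thresholds, or genuinely novel domain combinations beyond the
planted set.  Real cohorts should expect some Z-clan and warning-flagged
output.

## Problem sizes used in checks

The test suite runs the generator at up to 200 genomes, compares overlap
resolution against a residue-set oracle on 1,000 random instances of ≤ 10
hits, checks edit-path costs against exhaustive breadth-first enumeration
for all pattern pairs up to length 2 plus a 100-pair random sample up to
length 4, enumerates Wilcoxon permutation nulls exhaustively for
n₁ + n₂ ≤ 8, and calibrates the cascade's type-I error on 2,000 null
replicates.  These sizes were chosen to make the checks exhaustive where
the space is small and statistically tight where it is not.

## Known limitations

* No HMM scanning is performed by default; the package consumes existing
  per-domain results (an adapter can be wired to pyhmmer where profiles are
  available), and it never builds or calibrates profiles.
* Sequence-level trusted cutoffs are recorded but not enforced.
* The classifier is architecture-only by design: families with identical
  architecture but different function are indistinguishable.
* The evolution module treats patterns as strings of tokens; it knows
  nothing about sequence divergence, dating, or phylogenetic context.
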