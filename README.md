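# sig70arch

Modular domain-architecture analysis of bacterial sigma70 transcription
factors.

Bacterial RNA polymerase needs a sigma70 subunit to recognize promoters, and
cyanobacteria carry many of them — a primary factor for housekeeping
transcription plus a variable roster of alternative factors.  Historical
sigma naming (SigA…SigR) was built genome-by-genome and does not track the
actual *domain composition* of the proteins, so the same architecture ends
up under different names and vice versa.  `sig70arch` classifies sigma70
homologs purely from their modular architecture: the N→C ordered sequence of
Pfam-style domains found by profile-HMM search.

The package is aimed at comparative genomicists who already have per-domain
HMMER3 results (or want a synthetic cohort to test against) and need a
reproducible, automatic classification plus the cohort statistics that go
with it.

## The model

Domains split into six **essential** sigma70 domains — `r1_2`, `r2`, `r3`,
`r4`, `r4_2` (a variant of r4) and `ECF` — with a canonical N→C rank
(`r1_2 < r2 < r3 < r4 ≡ r4_2`, `ECF` standalone), and an open set of
**accessory** domains (`DUF6596`, `NB-ARC`, `TPR_MalT`, `WD40`, …).
Restricting an architecture to the essential vocabulary gives its **core
pattern**; a core is *canonical* when each of its essential domains occurs
exactly once, in rank order.

* a **clan** (letters A–L, plus miscellaneous Z) is the set of homologs
  sharing one essential-domain *set* — e.g. clan A = {r1_2, r2, r3, r4},
  clan F = {r2, r4_2}, clan L = {ECF};
* within a clan, a **family** is fixed by the core pattern and the accessory
  domain (AD) placement: canonical core → index 1 (no AD), 2 (N-terminal
  AD), 3 (C-terminal AD), 4 (both sides); the k-th registered non-canonical
  core owns the block 4k+1…4k+4 (5–8, then 9–12, …);
* every homolog gets the standardized unit name `Sig<clan>.<index>.<n>`
  with `n` numbered deterministically within each genome and family, e.g.
  `SigA.1.1`, `SigA.1.2`, `SigF.3.1`.

Upstream, homolog identification follows the domain-hit rules: per-domain
bit scores must reach the profile's gathering (trusted) cutoff, overlapping
hits are resolved by keeping the longest hits with the best E-values, and a
protein qualifies only if at least one of the seven seed profiles
(`Sigma70_r1_1`, `Sigma70_r1_2`, `Sigma70_r2`, `Sigma70_r3`, `Sigma70_r4`,
`Sigma70_r4_2`, `Sigma70_ECF`) survives.

Downstream, the package computes cohort statistics (genome × family count
matrices, morphotype comparisons through a Shapiro–Wilk-gated
t-test/Wilcoxon cascade, homolog count vs genome size, accessory-domain
surveys) and reconstructs minimal domain-edit scenarios between family core
patterns (losses, gains, r4↔r4_2 substitution, ECF formation from adjacent
r2+r4, terminal AD gain/loss) by uniform-cost search.

## Worked example

Generate a small synthetic cohort (9 genomes, planted architectures plus
decoy hits), run the pipeline, and verify the diversification scenario:

```sh
sig70arch simulate --out demo/sim --seed 11 --genomes-u 4 --genomes-f 2 --genomes-h 3
sig70arch run --hits demo/sim/hits.domtblout --thresholds demo/sim/thresholds.tsv \
              --genomes demo/sim/genomes.tsv --fasta demo/sim/proteins.faa --out demo/out
sig70arch evolve --out demo/evo
```

which prints

```
wrote 105 planted homologs in 9 genomes to demo/sim
classified 105 sigma70 units
13 edges, total cost 13, 13 single-event edges
```

The 105 planted homologs are all recovered, the decoys having been removed
by the threshold filter and the overlap resolver.  `demo/out/classification.tsv`
starts

```
genome_id  protein_id  clan  family_index  family  core_pattern   ad_placement  architecture_string  unit_suffix  name
G0001      G0001_P001  A     1             A.1     r1_2*r2*r3*r4  none          r1_2*r2*r3*r4        1            SigA.1.1
G0001      G0001_P002  A     1             A.1     r1_2*r2*r3*r4  none          r1_2*r2*r3*r4        2            SigA.1.2
G0001      G0001_P003  A     1             A.1     r1_2*r2*r3*r4  none          r1_2*r2*r3*r4        3            SigA.1.3
G0001      G0001_P004  B     1             B.1     r1_2*r2*r4     none          r1_2*r2*r4           1            SigB.1.1
```

— three homologs with the full four-domain architecture are clan A, family
A.1 (canonical core, no accessory domain), numbered `SigA.1.1…3` within
genome G0001.  The scenario report (`demo/evo/scenario.tsv`) confirms each
edge of the A.1 diversification model is a single event under unit costs:

```
source  target  cost  single_event  events
A.1     A.5     1.0   True          gain@1:r3
A.1     B.1     1.0   True          loss@2:r3
A.1     C.1     1.0   True          loss@0:r1_2
C.1     D.1     1.0   True          substitution@2:r4_2
```

`sig70arch distribute` adds the count matrix, the per-family morphotype
tests and the homolog-count vs genome-size correlation;
`sig70arch survey` runs the per-clade accessory-domain (DUF6596) prevalence
report.  Everything is equally callable as a library
(`import sig70arch`).

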