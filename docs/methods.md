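# Methods

This note records the models behind each `skit` module, the parameters
that matter, the numerical conventions, and what the simulation-based
validation does and does not demonstrate.

## Coordinate conventions

All coordinates are 0-based half-open throughout the library. PAF output
follows the PAF convention (both intervals on the forward strand of
their sequence, minus-strand alignments marked in the strand column);
geno-TSV, GFF3 and VCF positions are 1-based on disk and converted on
read/write.

## Synthetic chromosomes and rearrangement histories (`simgenome`)

A derived haplotype carries a **coordinate map**: for every base, the
ancestral position it descends from, its orientation relative to the
ancestor, and whether a point substitution has hit it. Structural events
rewrite sequence and map together:

* **inversion** — tract reverse-complemented, map orientation flipped;
* **duplication** — a copy (optionally reverse-complemented) of the
  source tract inserted at an insertion point outside the source;
* **deletion** — tract removed;
* **translocation** — tract excised and re-inserted at an insertion
  point given in pre-event coordinates;
* **point_mutation_burst** — a set number of substitutions at distinct
  positions, each to a uniformly chosen different base (a Jukes–Cantor-
  like process with no indels, so coordinate maps stay exact; multiple
  hits can occur across branches, not within one burst).

Histories are replayed along a labelled tree: each branch carries an
ordered event list and a per-base substitution probability (binomial
draw per branch). Tips sharing a branch share its events, which is how
the duplication-then-differential-loss scenario is expressed (one stem
duplication, different deletions on the two descendant branches).

**Ground-truth alignments** are emitted by matching per-base provenance
between two haplotypes: maximal runs in which consecutive query bases
pair with consecutive reference bases of the same ancestral origin and
consistent relative orientation become alignment records. The `dv` tag
is the realized per-base mismatch fraction of the run, so divergence
filters downstream see honest values. Duplications naturally produce two
records over one reference tract; novel bases align nowhere.

`random_history` draws 1–5 events whose source tracts and insertion
anchors are disjoint on the ancestral coordinate system, then translates
them to the evolving haplotype. This keeps every event individually
recoverable; overlapping events whose signals cancel (an inversion
re-inverted, a duplicate deleted) are deliberately never drawn, because
recovery of such composites is not well defined.

### Panel genotypes

The painting inputs are diploid reference panels with specified
within-panel diversity π and between-panel divergence d_XY. No
generative model is prescribed for them, so the simulator uses a
site-independent biallelic star model chosen to be *exactly* solvable
for the two target quantities: each site has an ancestral and one
alternative base; panel *p*'s consensus carries the alternative with
probability *m_p* and each allele is further flipped with probability
*a_p*. With u = 1 − 2a and v = 1 − 2m,

    π_p = (1 − u_p²)/2        d_XY(p,q) = (1 − v_p v_q u_p u_q)/2,

inverted in closed form (least-squares star decomposition of log v for
3+ panels). The haploid target is one extra allele drawn from its panel
of origin and is never missing; missingness knocks out whole diploid
calls at the specified rate. This is not a coalescent: sites are
unlinked, there is no shared polymorphism beyond the star structure, no
linkage disequilibrium and no mutation-rate heterogeneity — so painting
recovery on these panels demonstrates the correctness of the estimators
and the assignment rule, not robustness to real LD structure.

### Depth tables

Per-site exonic depth is Poisson with mean (per-copy coverage × true
copy number), or negative binomial (variance μ + μ²/k) when an
overdispersion parameter k is given — real short-read depth is
overdispersed, and no particular noise model is canonical, so Poisson is
the default and k is exposed.

## Synteny blocks (`synteny`)

Three steps per iteration: **split** (the reference axis is segmented at
every alignment boundary; each segment × covering alignment is one
sub-block, with the query interval obtained by strand-aware proportional
interpolation within the parent — approximate at indel-rich alignments,
since CIGARs are not consumed), **filter** (sub-blocks under the
iteration's minimum reference span are dropped; the minimum applies to
the reference side), and **merge** (chaining, below). Later iterations
re-split the previous blocks with the next minimum size. Defaults:
minima 200 bp / 2 kb / 20 kb, maximum reference gap 100 kb at every
iteration.

Chaining scans sub-blocks in reference order. A sub-block may join an
open chain when strand and query name match, the reference gap is in
[0, max_distance], and the query coordinate advances with the strand
(forward chains march up the query, reverse chains march down) by at
most a query-gap bound. Among candidate chains the one with the smallest
query gap (then reference gap, then age) wins, which keeps the two
copies of a duplicated tract extending their own chains. Sub-blocks that
overlap on the reference never share a chain.

Two asymmetric gap tolerances, and why: a reference-side gap means
material *deleted* from the query (the published 100 kb tolerance); a
query-side gap means material *inserted* into it. The query bound
defaults to the schedule's final minimum block size (20 kb) — an
insertion large enough to matter at the calling resolution should start
its own block. With an unbounded (or 100 kb) query gap, an
inverted duplicate or translocated copy landing near a genuine inversion
in query space fuses with it during iteration 1, and the later
re-splitting interpolates the junction away; this measurably degrades
inversion breakpoint recovery. `max_query_gap=None` restores the
literal reference-gap-only rule; `require_same_query=False` additionally
chains across query sequences on reference distance alone.

The published description discards alignments "less than 2 kb and with
divergence … less than 0.2" when comparing variant assemblies; keeping
only *low*-divergence alignments is the evident intent of a paralog
filter, so the filter retains records with dv ≤ threshold and a
`keep_low_dv` flag restores the literal wording. Records lacking a dv
tag are dropped (with a warning) while the filter is active.

### Rearrangement calls

On the final blocks (after re-segmenting any block whose members jump
more than 20 kb on the query axis — such a jump means unrelated material
was chained across):

* **inversion** — maximal run of minus-strand blocks that is
  query-collinear (query falls as the reference advances) with ref- and
  query-side run gaps ≤ 20 kb; a jump back up in query, or a larger gap,
  starts a new call (it indicates an unrelated inverted tract, e.g. an
  inverted duplicate).
* **duplication** — reference region where ≥ 2 blocks overlap with
  distinct query tracts (reciprocal overlap of the query tracts,
  restricted to the shared reference interval, < 50%). Overlapping
  pair regions are merged into single calls.
* **translocation** — among the remaining blocks, the minimal set
  breaking query-order collinearity (complement of the longest strictly
  increasing subsequence of query ranks), so one moved block yields one
  call instead of a cascade of rank shifts.

Block and call boundaries are only as precise as the final iteration's
minimum block size; the validation scores inversion breakpoints at a
20 kb tolerance accordingly.

## Windowed statistics and painting (`winstats`)

π is the mean over genotyped sites of the average pairwise difference
among the 2n alleles of the panel (within-individual pairs included;
sites with fewer than two non-missing alleles skipped). d_XY is the mean
over sites of the mean difference across all between-group allele pairs
(the haploid target contributes one allele; sites lacking a valid
between-group pair are skipped; pair counts renormalize per site under
missing data). Heterozygous calls contribute both alleles — no IUPAC
collapsing in statistics. d_a is d_XY − π against a panel, or
d_XY − (π_A + π_B)/2 between panels.

Windows contain a fixed count of genotyped sites (default 25,000),
anchored by default on sites genotyped in the haploid target — the
assembly being painted — with `anchor="any"` as the alternative; the
trailing short window per chromosome is flagged partial and excluded
from painting. Painting masks a window if any panel fails to reach the
minimum genotyped-site count (default 10,000) in at least one of its
individuals (the literal published rule), assigns the lowest-d_a panel
when the runner-up is at least the margin (default 0.01, inclusive)
behind, and otherwise reports UNASSIGNED.

Degenerate self-comparison: for a polymorphic group compared with
itself the standard estimators give d_XY = π(n−1)/n (self-pairs are
excluded within but included between groups), so d_a is slightly
negative (−π/n) rather than exactly zero; it is zero for monomorphic
groups.

## Copy number (`cnv`)

Masking keeps exonic sites where every individual across all species has
depth ≥ 1 (guarding against poor cross-species mappability); per-gene
medians need ≥ 100 surviving sites. Normalization is per individual —
each individual's gene medians divided by that individual's median
across all chromosome genes — which removes per-library coverage
differences; the published text does not fix the level, and per-sample
normalization is the choice made here. The normalizer assumes most genes
are single-copy; on a chromosome dominated by a high-copy cluster the
estimates would be systematically low. Rounding is half-away-from-zero
(1.5 → 2). Species-level values are medians over the species'
individuals, rounded the same way. At least 3 genes are required for a
normalizer.

## Molecular dating (`moldate`)

A third codon position is fourfold degenerate iff the four codons
sharing its first two bases translate identically under the standard
code; degeneracy is classified from the reference (outgroup) codon
context, and the multi-sequence variant demotes sites whose codon
context disagrees across sequences. d_a restricted to fourfold sites is
converted to time as `age = T_cal × d_a(focal) / d_a(cal)`; the function
is homogeneous of degree 1 in the focal and −1 in the calibration
divergence. The 95% CI comes from a percentile block bootstrap over
genes (default 1,000 replicates) — sites within a gene are linked, genes
are treated as exchangeable — and is propagated through the calibration
by pure scaling, holding the calibration point fixed as a constant.

**Known bias**: raw p-distances saturate with multiple hits, and the
ratio of two saturating distances at different depths is biased upward
(the deeper calibration is compressed more). At the regime the method is
used in (calibration divergence ≈ 14%) the strict-clock validation shows
a ~3–4% upward bias in the recovered age, within the 5% tolerance the
validation uses but not negligible; no multiple-hit correction is
applied, matching the published procedure.

## Gene alignments and trees (`genealign`)

Processing order is fixed: (1) genotypes failing the quality rule become
missing — the rule is GQ < 20 **or** DP < 5 by default (failing either
masks the call; the published sentence reads "and", but the AND reading
would keep low-GQ high-depth calls, contrary to evident intent; a
`combine="and"` flag restores it); (2) sites missing in any sample are
removed; (3) heterozygotes collapse to IUPAC codes; (4) CDS splicing by
exon coordinates, reverse-complemented for minus-strand genes, with
positions absent from the call set filled with N — so the N filters
measure how much of each gene survived. A gene is discarded when any
sample has more than 500 Ns or an N fraction of at least 75% (both
thresholds as published; the fraction rule is inclusive).

Concatenation joins genes in a stated order and records a partition
table. The distance tree is neighbour joining (scikit-bio, negative
branch estimates clamped to zero) on p-distances in which ambiguity
codes contribute their expected mismatch over compatible-base sets
(R vs A = 0.5) and N is excluded pairwise — a deliberate plumbing tree
for topology checks on synthetic data, not a substitute for
likelihood-based inference.

## Validation experiments (`skit.validation`) and problem sizes

* **Rearrangement recovery** — 100 histories on 1 Mb chromosomes, 1–5
  disjoint events of 50–200 kb, 5% divergence, truth alignments at
  ≥ 200 bp; inversions scored at 20 kb breakpoint tolerance,
  duplications by source-tract overlap.
* **Painting** — three panels (π 0.01; pairwise d_XY 0.05/0.055/0.06),
  150,000 sites → six full 25,000-site windows; plus a high-missingness
  run confirming the 10,000-site masking rule.
* **Copy number** — 1,000 genes × 120 exonic sites, 20× Poisson
  coverage, 60% single-copy and the rest uniform on 2–8, three
  individuals in two species; scored as exact integer recovery per
  gene × individual.
* **Dating** — three taxa, strict clock at 0.0057 substitutions per base
  per Ma with splits at 7.45 and 12.7 Ma, ≈ 150,000 fourfold sites
  (calibration divergence ≈ 14%, mirroring the regime of interest).

These sizes keep the full suite and the acceptance script in the
minutes range on a single core while leaving each recovery criterion
statistically meaningful. What passing shows: the estimators implement
their definitions exactly (they match brute-force oracles to floating
point), and the pipelines recover known truth under the simulator's
assumptions. What it does not show: robustness to alignment error,
repeat-induced mis-mapping, LD, indel-rich alignments, or annotation
error — none of which the simulator emulates.
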