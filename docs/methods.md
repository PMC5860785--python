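# Methods

This note documents the models, conventions and numerical choices behind
gcrscope, in the spirit of a methods supplement: what is simulated, how
each analysis stage works, which knobs matter, and what the synthetic
benchmarks do and do not demonstrate about real data.

## The assay geometry being emulated

The simulator reproduces the geometry of a chromosome-arm GCR selection
assay in budding yeast. The assay chromosome carries, telomere to
centromere: a left telomere, a telomeric hygromycin-resistance marker
(*hph*), a counter-selectable *CAN1/URA3* cassette, a *breakpoint region*
of unique sequence between the cassette and the most telomeric essential
gene, the essential gene itself, a *ura3-52*-style marker homology,
members of three repeat families (delta ~330 bp, PAU ~900 bp, a scaled
Ty-like element of 1.5 kb) in both orientations, a 2-kb diverged
segmental duplication, and the centromere. A second chromosome carries
forward-orientation partners of every repeat family, the segdup partner,
and a full-length Ty copy deliberately omitted from the feature table,
flanked by a 5-bp target-site duplication, so that anchor-based junction
sequencing can be shown to walk into unannotated repeats. A third, plain
chromosome serves as translocation target and disomy subject.

Default scale is desk-size: three chromosomes of 30 + 30 + 20 kb. Sizes,
feature layout, repeat copy numbers and divergences are configurable;
the defaults are what the test-suite conditions use throughout. Repeat
copies diverge pairwise by 5% by default (the segdup divergence is a free
parameter; nothing in the emulated assay pins it, so 5% was chosen once
as typical of diverged duplications and kept). The *ura3-52* homology
tract is 450 bp — long enough to recombine, deliberately shorter than
the insert size so that marker-HR junctions still produce
junction-defining discordant pairs.

Telomeres are irregular TG(1–3) repeats emitted by a seeded grammar
(blocks `T G{1..3}` on the G-rich strand), and telomere detection is
grammar-driven rather than motif matching, so the repeat pattern is a
configuration, not a constant.

## Implanted events and their truth records

Each of the five junction-forming GCR classes (plus whole-chromosome
disomy) is implanted by rewriting the assay chromosome:

* **telomere addition** — truncate at the break and append a grammar
  telomeric seed (default 250 nt; the seed's junction-adjacent base is
  kept distinct from the reference flank so the truth breakpoint is
  unambiguous);
* **interstitial deletion** and **micro-/non-homology translocation** —
  fuse two flanks through an *engineered* microhomology of exactly *h* bp
  (or an untemplated insertion): a site search finds flank pairs whose
  maximal fusion-point overlap is exactly *h*, with mismatches planted
  immediately outside the block;
* **homology translocation** — a seamless crossover inside a shared
  repeat/segdup copy pair; the realized microhomology is the natural
  identical tract between divergent sites;
* **hairpin-mediated inverted duplication** — resection to the pivot
  `p`, annealing at a planted inverted repeat (stem `s`, loop `l`),
  copy-back and replication give the dicentric intermediate
  `revcomp(chrom[p:L]) + chrom[p+2s+l:L]` (exposed on the truth record
  and verifiably dicentric), then one secondary rearrangement — repeat-HR
  through a family copy, marker-HR through the URA3 homology, or a
  microhomology fusion — resolves it to a monocentric product;
* **disomy** — an extra whole copy of the target chromosome.

Breakend coordinates are reported under a fixed convention: because a
microhomology block is attributable to either flank, the block is
assigned to the canonical first end (chromosome order in the reference,
then position). The detector applies the identical convention, which is
what makes breakend-exactness a meaningful round-trip check.

Hairpin annealing sites are planted "clean": the stem cannot be extended
outward or into the loop by chance base pairing, so the (stem, loop)
assignment under the tie-break *maximal stem, then smallest loop* is the
unique maximal interpretation. Real genomes do not guarantee this;
ambiguous sites would be reported under the same tie-break.

## Read and culture simulation

Fragments are drawn uniformly ∝ molecule length; insert sizes are
N(600, 60) truncated at twice the read length (gel-selected ~600-bp
fragments; reads 100 bp; default coverage 50×); ends are read inward
(FR); substitution errors at 1% per base; 2% verbatim PCR duplicates.
No indels, quality models or chimeras — so mapping behaviour near real
indel-rich loci is untested by construction.

Cultures grow from one cell by binary expansion to N cells; a mutation
at division *j* (of ~N, in temporal order) founds a clone of final size
N/j; counts are Poisson mutation numbers pushed through deterministic
clonal expansion, optionally binomially thinned by a plating fraction.
This reproduces the heavy-tailed jackpot distribution the median
estimator is designed for, and nothing else (no death, no fitness
effects, no phenotypic lag).

## Analysis conventions

**Mapping.** Exact 31-mer seeds (three per read), ungapped extension, at
most 5 mismatches; unique requires the runner-up to carry ≥2 more
mismatches; ties are always `multi`, never broken arbitrarily, so
repeats cannot manufacture unique depth. Junction-spanning reads fail
both flanks and remain unmapped — they are the junction-sequencing reads.
SAM import labels MAPQ ≥ 20 unique. On genomes of this size the mapper
is exactly equivalent to brute-force Hamming search (tested).

**Insert model.** Concordance bounds are the 0.1/99.9 percentiles of
inward same-chromosome inserts, after restricting to the bulk below
3× the median — junction-spanning pairs otherwise inflate the upper
percentile and hide deletions.

**Depth.** Only both-unique, deduplicated pairs count. Read depth is
scaled by the median concordant read depth over uniquely-mappable
territory (exact k-mer uniqueness at k = read length); the median is
taken on a 101-bp-smoothed profile because per-base integer depths
quantize the median to whole units (>2% granularity below ~50×).
Requiring both ends to map uniquely depresses pair coverage within an
insert length of multi-mapping islands; segmentation and disomy calls
inherit that sag, which is why disomy statistics trim 1 kb at molecule
ends and why a duplicated interval is asserted to segment at state 2
over most, not all, of its length.

**Junction calling.** Discordant pairs cluster by orientation signature
within one insert length; same-chromosome inward clusters whose implied
span is below the insert bound are discarded as insert-size outliers
(deletions below insert resolution are undetectable by this signal
anyway). A cluster is kept when it has ≥3 defining pairs and a one-sided
binomial test (α = 0.01) rejects the genome-wide stray-discordant rate
given local span depth.

**Junction sequencing.** The consensus grows from a reference anchor
flank by greedy overlap layout (20-nt exact seeds, ≤2 mismatches per
overlap, extension requires ≥2-read support), with the consensus
re-voted after every placement round so individual sequencing errors
cannot poison later placements; a lone or double dissent at a column is
treated as error, three or more agreeing dissenters above 20% of the
column raise an ambiguity error naming the reads. Where a junction runs
through homology whose partner locus is still intact (repeat families,
the URA3 marker), mates of concordant pairs are excluded from the
collection — they would vote the reference allele — and the anchor falls
back to the single-copy side, mirrored if necessary. Breakends are then
refined to exact coordinates from the flank alignments; junctions inside
homology tracts are only placeable to within the tract, and remain so.

**Telomere additions.** One-sided events are seeded by a terminal
zero-copy segment, the boundary refined from read starts, and only
junction-crossing reads (≥25 nt of unique flank) feed the consensus —
wholly-telomeric reads are self-similar and chain at shifted registers.
A call requires ≥15 nt of grammar match beyond the refined breakpoint.
The recovered seed length is a lower bound (about one read length);
derivative-length predictions for telomere additions are short by the
unrecovered remainder.

**Hairpin inference.** A foldback is a kept same-chromosome,
same-strand-signature junction within 10 kb whose centromeric side steps
to ≥1.5n. The stem/loop scan exploits an invariant: anchoring the two
consensus flanks to the chromosome pins `p + fold0` exactly even when
the fold-adjacent columns are corrupted (the junction neighbourhood is
quasi-palindromic, so read orientation is locally ambiguous and loop
columns may be miscalled). Candidate pivots are scanned under that
constraint; exact-match stems are preferred before the ≤1-mismatch
allowance (otherwise the maximal-stem tie-break over-grows into the
loop); each candidate must fall between the measured forward/reverse
walk limits (with a core-sized allowance for read-derived consensus)
and match the consensus image outside its loop. Recovery is exact for
stems 4–50 and loops 0–200 on clean sites; a foldback with no usable
stem is reported with arm alignments only (`stem_len = None`).

**Classification.** The walk starts at the assay centromere and proceeds
telomere-ward consuming junctions; precedence is: de novo telomere →
hairpin (any inverted self-segment) → homology translocation (same
repeat-family/segdup context on both breakends, or microhomology ≥50 bp)
→ micro-/non-homology translocation → interstitial deletion. Group 1
requires the predicted length to exceed the parent by >2% (a declared
convention standing in for PFGE resolution); otherwise group 2/3 by hph
loss/retention. Classification without a resolved junction sequence is
flagged low-confidence but not withheld.

## Fluctuation statistics

The point estimate solves the Lea–Coulson median relation
`r/m − ln m = 1.24` (bracketed Brent root-finding, tolerance 1e-10) for
the plating-corrected median count; the rate is `m / median(N)`. Each
culture's count also yields a per-culture estimate, and the 95% CI is
the binomial(n, ½) order-statistic interval on those estimates — a
nonparametric rank CI around the median, reproducing the customary
asymmetric intervals. An all-zero median yields a flagged upper bound
(the rate that would put the median at one mutant). Calibration at a
true rate of 1e-7 with N = 1e8 and 16 cultures gives ~13% median
relative error and 94–96% CI coverage over 1000 replicates.

Type-partitioned rates multiply the rate and CI by each class fraction
(observed: the genotype's own spectrum; expected: the reference
spectrum). Observed/expected samples are compared by a two-sided
Mann–Whitney U — exact for groups ≤20 without ties (verified against
full enumeration), normal approximation with tie correction otherwise —
starred `*` below 0.05 and `**` below 0.0005. Which samples feed the
test is a declared choice (per-culture scaled rates); the estimator
family deliberately excludes maximum-likelihood fluctuation estimators.

## Problem sizes and what the benchmarks show

The shipped benchmarks run 50 simulated isolates (10 per class) at 50×
coverage and 1% error on the 80-kb genome, 1000 estimator replicates,
and a 10,000-replicate Mann–Whitney null; everything completes in a few
minutes on one CPU. Passing them shows the pipeline is internally
consistent and exact where exactness is attainable — it does not show
robustness to GC bias, indels, chimeric library artifacts, subclonal
mixtures, nested multi-round secondary rearrangements, or repeat
families at real-genome copy numbers, none of which the generator
emulates. Copy-number states are integer-only; secondary-rearrangement
chains beyond one resolving event are reported but not mechanistically
re-inferred.
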