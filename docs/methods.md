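# Methods

## Scope and data flow

`sealdiet` implements the computational core of a scat DNA metabarcoding
diet analysis: reads → sample assignment → sequence clusters → prey taxa →
per-sample fractions → population summaries, with three companion
analyses (dual-marker integration, life-stage apportionment, bias
correction) and an in-silico evaluation of the diet indices themselves.
Wet-lab steps (collection, extraction, PCR, library prep) are upstream
data; the package starts at reads or count tables.

## Read processing rules

**Tag codes.** Samples are identified by 10 bp primer tags designed so
that every pair of tags is at Levenshtein distance ≥ 5. The constructor is
a greedy randomized code search over {A,C,G,T}^L (exhaustive shuffled
enumeration for L ≤ 8), rejecting homopolymer runs > 3; the returned set
is re-verified by exhaustive all-pairs edit distance. The search is
bounded and fails loudly, naming the achieved size, when the parameters
are infeasible (e.g. L = 2, d = 3).

**Demultiplexing.** Reads are 5'-anchored (tag, then primer, then
insert), so tag and primer matching uses positionally anchored Hamming
distance with IUPAC-aware base comparison (degenerate primer bases match
any base in their set); Levenshtein is reserved for code design. A read is
assigned iff the primer matches with ≤ 2 mismatches AND exactly one tag
matches with ≤ 2 mismatches; the mismatch budgets are separate. Reads
matching two or more tags within tolerance are discarded as ambiguous and
tallied — with a distance-5 code this cannot happen, but the demultiplexer
does not assume its tag set came from the designer.

**Clustering.** Greedy abundance-sorted centroid clustering: unique
sequences in descending count (ties broken lexicographically), joining the
first cluster whose representative they match at identity ≥ 0.99, else
founding a new one; clusters with total count < 3 are discarded.
Clustering is performed on the pooled inserts of all samples rather than
per sample: per-sample clustering would silently delete any
(sample, taxon) combination observed only once or twice even when the
sequence is abundant across the dataset, breaking count conservation
through the pipeline. Identity is 1 − edits/max(length): a Hamming fast
path for equal lengths, global edit distance (edlib) otherwise.

**Assignment.** A cluster representative is assigned to the species of
its best-identity reference hit when identity ≥ 0.9 and the query is at
least 100 bp. The length floor is a deliberately simple stand-in for a
BLAST e-value screen: for ~260 bp amplicons at ≥ 90% identity the e-value
criterion is dominated by the identity and length conditions, and
reimplementing Karlin–Altschul statistics would add machinery without
changing any assignment this package makes. Best-hit species are mapped
through the indistinguishability groups; a tie at the best identity
spanning more than one group is left unassigned.

**Sample filter.** After removing predator (harbour seal) and contaminant
reads, samples with fewer than 10 identified prey reads are excluded; the
exclusion is logged and reported.

## Reference database and "OR" taxa

Reference FASTA headers follow `>Species|Common_name|marker` with a
permissive fallback (whole header = species). Pairwise distances are
p-distances from a global alignment; IUPAC codes count as matches when
their base sets intersect (conservative identity). Species grouping is the
transitive closure of "any pair of their sequences is at distance 0" —
one shared haplotype suffices even when other haplotypes differ, because a
read matching the shared haplotype genuinely cannot be attributed to
either species alone. Merged identifiers join group members
alphabetically with `_OR_`; alphabetical order is a convention chosen for
determinism. Finer nonzero distances are implementation-defined and
nothing downstream depends on them; only distance == 0 carries meaning.

## Diet indices

The four indices are computed exactly as defined in the README. Numerical
conventions: occurrence is read count > 0 (the sample-level 10-read filter
happens upstream, so no per-cell threshold is applied); samples with zero
detected items are excluded from S for wPOO and RRA (0/0 otherwise) and
logged; POO/wPOO sum to 1 within 1e-9 and RRA to 100 within 1e-6 by
construction; merged OR taxa are single taxa. RRA is invariant under
per-sample rescaling of counts, which the tests assert.

## Dual-marker integration

The 16S salmonid fraction of a sample is the summed fraction of taxa
resolving wholly within Salmonidae (including OR groups of salmonids). It
is distributed over salmon species proportionally to the sample's COI
read fractions; non-salmonid fractions pass through, and the output sums
to 1 exactly. When salmonid 16S signal exists but the sample has fewer
than 10 COI reads, the fraction is reported unsplit at family level
("Salmonidae") — conservation is preserved without inventing a species
split. COI detections with zero 16S salmonid signal are logged, not added
to the diet.

## Life-stage apportionment

A sample's salmonid DNA percent is split juvenile/adult by the first
available of: (1) the sample's own classified-bone ratio, (2) the ratio of
bones pooled for the collection month — per site-month by default (diet
varies considerably between haulout sites), falling back to the all-site
month pool — (3) a seasonal rule. The season mapping defaults to months
3–6 → juvenile (out-migration) and 7–12, 1–2 → adult (return runs), and
is a configurable parameter because regional salmon phenology, not
arithmetic, determines it. Unclassified salmon bones never enter a ratio.
The ratio is sample-level and applied uniformly to every salmonid
species' percent in the sample; juvenile + adult equals the input percent
to 1e-9 (exactly, in exact arithmetic).

## Correction factors

RCFs are read ratios test/control observed in 50/50 biomass mixtures;
replicates aggregate by geometric mean because ratios are multiplicative.
TCFs are observed/known fraction ratios from a mixture of known
composition. DCFs are accepted as externally supplied multipliers only —
the lipid-based regression that predicts them is not reimplemented here,
as no coefficients are available to validate against. Correction divides
counts by the factor and renormalises per sample; this is algebraically
identical to dividing fractions and renormalising, so whether factors are
defined in count space or fraction space is immaterial (tested). A
consequence worth noting: corrected outputs are invariant to a global
rescaling of all factors, so only factor *ratios* matter.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes:
Dirichlet-distributed true biomass proportions per scat; multinomial 16S
read counts with probabilities ∝ proportion × per-species amplification
bias factor, plus one predator-read category (blocking-oligo leakage,
default fraction 0.1 — a configurable convention, as no leakage rate is
established); an independent COI multinomial over salmonid taxa only
(separate PCR); reads as tag + primer + reference insert with independent
per-base substitution errors (indels excluded to keep the clustering
oracle exact); hard-part detection per consumed taxon with a Bernoulli
probability and month-dependent juvenile/adult bone labels. Reads per
sample are fixed (default 2,000 for 16S, 1,000 for COI) — the simplest
testable contract; an empirical depth distribution is not modelled. All
randomness derives from a single seed via per-stage independent streams,
so identical configs give byte-identical outputs.

What the generator does **not** emulate: chimeras, quality-score
structure, indel errors, PCR cycle kinetics, pooling/normalization
artefacts, secondary prey, or collection bias. Passing tests therefore
demonstrate the correctness of the computational rules under the stated
statistical model, not robustness to every artefact of real sequencing
data.

## Index evaluation

The evaluation simulates diet datasets over a factorial grid of sample
sizes and bias magnitudes (default 25/100 samples; 1×, 5×, 20× bias; 50
replicates for the headline run; 500 reads/sample), computes RRA, POO and
wPOO, and scores each against the true population diet (the mean of
per-sample true diets, matching RRA's unweighted mean structure) with
Bray–Curtis dissimilarity BC = 1 − Σ min(p, q). Bias magnitude B means
per-taxon factors geometrically spaced over a B-fold range, randomly
assigned to taxa each replicate. The true diet is uneven (geometric
Dirichlet concentrations, default decay 0.55 over 8 taxa), as predator
diets typically are; with an even diet occurrence indices would
trivially excel, and the comparison would be uninformative. Occurrence
detection is ≥ 1 read. The directional result — RRA more accurate than
POO in every cell even at 20× bias — is asserted as a property, not a
numeric target.

## Problem sizes

Default test problem sizes were chosen to make each check statistically
decisive at desk scale: 1,000 random tables for metric/oracle parity;
200 samples × 1e5 reads for parameter recovery under 20× bias
(Bray–Curtis < 0.02); 50 replicates per cell for the index comparison;
8-sample simulations for the read-level round trip (exactness is binary,
so depth adds nothing).

## Known limitations

- The juvenile/adult scheme is binary; real consumption spans a size
  continuum.
- The family-level "Salmonidae" fallback deliberately under-resolves
  rather than guessing a species split.
- Whether monthly bone pools should be per-site or global is exposed as
  configuration; both are defensible and the default (per-site with
  fallback) reflects between-site diet variability.
- The distance matrix beyond distance-0 detection is a plain p-distance,
  not a model-corrected phylogenetic distance.
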