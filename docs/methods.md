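# Methods

This note documents the models and procedures behind virmatch, the defaults
that matter, the design choices that were genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Taxonomy and LCA

Strain lineages come from a TSV (strain_id, phylum … species); identical
prefixes share nodes, so the store is a rooted tree and the lowest common
ancestor of a strain set is plain path intersection.  Blank ranks are
collapsed: a strain with no species entry attaches directly to its genus, and
an LCA is always reported at the nearest *named* rank — host calls therefore
land at whatever rank the evidence supports (strain, genus, family, class…).
Names are matched case-sensitively after whitespace trimming.  When a query
spans the whole table the LCA is the synthetic root; predictions carry an
`unresolved` flag in that case rather than a fabricated rank.

## Synthetic community generator

The generator is first-class, tested code: it defines the conditions under
which every detector is validated.

**Composition model.**  Each genus is an order-3 Markov chain over ACGT: a
64 × 4 transition table with rows drawn from a Dirichlet with concentration
1.0 per context.  Host strains and host-linked viruses of a genus are
independent emissions from the same table, which is exactly the signal the
4-mer method consumes.  The concentration default was calibrated once so
that two independently drawn genera differ by a canonical 4-mer MAE well
above the 0.001 assignment threshold (the suite checks ≥ 95/100 trials on
100-kb emissions), while two 30–100-kb emissions from one table differ by
roughly 4·10⁻⁴ — comfortably below it.  In the large-concentration limit all
contexts approach uniform(0.25) and the signal vanishes.

**Defaults** (the standing study conditions): ten host strains of 60 kb in
four genera across three phyla; strain-level substitutions at rate 0.005;
viruses of 10–30 kb; full prophages inserted verbatim; partial prophages as
6-kb windows substitution-mutated to exactly 0.75 / 0.85 / 0.95 Hamming
identity; two deliberate negatives (4.5 kb at 0.95, and 6 kb at 0.65) that
sit outside the ≥ 4.9-kb / ≥ 70 % detection rule; CRISPR arrays of 4 and 3
copies of a 28/30-bp repeat whose spacers copy viral windows at exactly 0, 1
and 2 mismatches (the array insertion point is resampled until the bases
flanking the repeat copies are non-unanimous, so the planted repeat is
guaranteed maximal and its locus well-defined); 1,000 error-free read pairs
per virus (read length 100,
insert 500 ± 50, truncated below at the read length) — about 7× coverage of
a 30-kb genome, enough that a circular template yields junction-spanning
pairs with near-certainty.  Insertion sites are uniform but excluded from
the outer 1 kb of a contig so planted loci stay clear of edge effects.

Mutations are substitution-only throughout, so "identity" of a planted
region is well-defined as Hamming identity; prophage identity is hit exactly
by mutating round((1 − identity)·length) distinct positions.

**Circular contigs.**  A circular genome is linearised the way assemblers
emit it: with its first 45 bases duplicated at the end (a direct terminal
repeat).  Reads are simulated from the *circular* template, so fragments may
wrap the origin; the truth table flags pairs whose fragment wraps while both
reads stay intact in linear coordinates — exactly the pairs a
junction-spanning counter can recover.

**Determinism.**  All generation is a pure function of (config, seed).  The
global seed expands to per-component child generators through
`SeedSequence([seed, crc32(label)])`, where the label names the component
("host:Pseudomonas_P1", "reads:v_bg_a", …); regenerating one component never
perturbs another, and rerunning the pipeline with the same config and seed
reproduces every output byte-for-byte.

## Circularity calls

The three criteria are applied literally: length strictly greater than
2,000 bp; a same-orientation terminal repeat of ≥ 35 bp (34 bp fails); and
≥ 2 junction-spanning pairs with each mate within 500 bp of its end
(501 bp fails).  The repeat test is exact string equality between prefix
and suffix — at these lengths a chance ≥ 35-bp repeat has probability around
L²·4⁻³⁵ ≈ 10⁻¹⁴ for a 3-kb contig, so exact matching is strictly
conservative with respect to any end-homology significance test.  Inverted
repeats do not count: circularity requires direct terminal redundancy.

Reads are placed by exact full-length substring match on either strand
(the generator's reads are error-free by default; a substitution rate is
configurable but unplaced reads simply contribute nothing).  A read occurring
more than once excludes its pair as ambiguous.  A counted pair must be
oriented toward the junction: plus-strand mate near the right end,
minus-strand mate near the left end.  Coordinate-sorted SAM alignments are
accepted as an alternative evidence source feeding the same windows.
Coordinates are 0-based half-open everywhere.

## Composition method (4-mer)

Counting is canonical: each ACGT window contributes one count under the
lexicographic minimum of the 4-mer and its reverse complement, giving
(256 − 16)/2 + 16 = 136 canonical 4-mers; windows containing other letters
are skipped, and counting never crosses a contig boundary.  Multi-contig
genomes pool counts per strain *before* normalising — length-weighting is
the unbiased estimator; averaging per-contig frequencies is not.  The
distance d is 1/136 of an L1 distance, hence a metric bounded by 2/136.

The threshold d < 0.001 is strict, applied before ranking; the top five
candidates by lowest d are collapsed by LCA, with ties at the fifth place
included (order-independence).  MAE sampling noise scales as 1/√length, so
contigs under 4 kb are still profiled but flagged low-confidence in the
output.

## Shared-region method (blast / blast99)

An in-house ungapped seed-and-extend engine: exact 11-mer seeds on both
strands, X-drop extension along the diagonal (match +2, mismatch −3,
X = 60), overlapping extents on a diagonal merged with their statistics
recomputed over the union.  Two refinements keep desk-scale all-vs-all scans
fast without touching the detection contract:

* **two-hit initiation** — a seed is extended only when a second seed lies on
  the same diagonal within 150 bp.  Genuine shared regions at ≥ 70 %
  identity carry an exact 11-mer roughly every 50 bp, so nothing detectable
  is lost; isolated chance seeds (which cannot reach a reportable score) are
  dropped unextended.
* regions under 50 bits are not reported; with X = 60 a mismatch run of 21
  would be needed to sever a region, an event of probability ~10⁻⁸ per 5 kb
  even at 70 % identity.

Scores use the ungapped Karlin–Altschul formulation, bit = (λS − ln K)/ln 2
with λ = 0.625, K = 0.41, and E = m·n·2^(−bit) with m the virus length and
n the summed host genome length.  The filters are dominated by the
length/identity rules in any case.  Gapped alignment is deliberately out of
scope: planted variation is substitution-only, so ungapped identity is exact
— a documented limitation for real data, where an indel would split one
region into two (coverage union handles this for containment).

Genus-level calls require a region ≥ 4,900 bp at ≥ 0.70 identity with
bit ≥ 50 and E ≤ 10⁻³; each strain is collapsed to its best region before
top-5 ranking (a strain with many regions is still one hit), ties included.
Strain-level containment ("blast99") requires > 0.99 of the virus covered by
the union of regions of > 0.99 identity whose E-value is below 10⁻¹⁸⁰ — the
printed "E = 0" of alignment tools is a floating-point underflow, so a
literal zero test would be an artifact.  Several strains may each contain
the virus; each yields its own strain-rank call.  Precomputed 12-column
tabular alignments can replace the built-in scan; they feed the same
filters.

## CRISPR method

Array detection is CRT-style: an exact 8-bp seed recurring ≥ 3 times with
start-to-start spacings inside [repeat_min + spacer_min, repeat_max +
spacer_max] nominates a candidate; the repeat is extended while all copies
agree column-by-column; candidates violating the geometry (repeat 19–38 bp,
every spacer 19–48 bp) are discarded, and overlapping candidates resolve to
the one with more repeats.  The copy-divergence tolerance defaults to 0:
with a handful of identical copies, any majority-vote tolerance occasionally
over-extends a repeat past its true boundary by chance agreement of flanking
bases, which would corrupt the extracted spacers; a CRT-like tolerance is
available via `max_copy_divergence` for degenerate real-world repeats.

Spacer matching is an exhaustive full-length Hamming scan of every spacer
against every virus, both strands, keeping ≤ 1 mismatch.  For full-length
matches at this threshold an exhaustive scan is equivalent to or stricter
than a short-word alignment search, and gap penalties are moot — a gapped
match cannot satisfy a full-length ≤ 1-mismatch filter.  Identical spacers
within one array are counted once (tandem duplications would double-count
evidence).  Back-validation requires the spacer to occur exactly (zero
mismatches) in its host of origin; exact occurrences in *other* hosts are
logged but never promoted to predictions, since the array provenance is what
carries the evidence.

## Annotation curation

domtblout parsing takes the full-sequence E-value and score columns; hits
pass at bit ≥ 30 and E ≤ 10⁻³ (both inclusive).  Categories are
case-insensitive substring rules over target name and description, ordered
by priority with resistance classes first — so "streptomycin
adenylyltransferase" is antibiotic resistance, not generic metabolism — and
anything unmatched falls through to `not_categorized`.  The shipped table is
a starting set covering the classes most relevant to contaminated aquifers
(copper and other metals, beta-lactamases, AcrB/AcrD/AcrF efflux,
aminoglycoside enzymes, toxin–antitoxin, phage hallmarks, metabolism); it is
a plain TSV and meant to be extended per study.

## Consensus and clusters

Agreement is judged at genus rank: every calling method's taxon is lifted to
genus when deeper, and the calls agree when they form a chain (a strain call
agrees with its genus; calls in different families disagree).  Methods that
legitimately emit several strain calls for one virus (containment, CRISPR)
collapse to the strains' LCA for the consensus cell.  The best-rank call is
the deepest-rank prediction, ties broken by the accuracy ordering
crispr > blast99 > blast > 4mer.  Per-method no-calls remain explicit rows
in the per-method tables, distinguishing "ran, no prediction" from "not
run".  Cluster consistency reports, per virus cluster, the LCA of member
best-rank calls and its rank; single-member clusters are trivially
consistent and flagged by their predicted-member count.  Disagreements are
reported, never adjudicated.

## What the benchmark shows — and does not

Passing on the synthetic community demonstrates that each detector recovers
exactly the signal class it was designed for, at the stated thresholds, with
no false pairs under the generator's assumptions: substitution-only
variation, error-free reads, composition stationarity within a genome, no
repeats or mobile elements beyond the planted ones, and hosts that are
either clearly related to a virus or clearly not.  Real metagenomes violate
all of these in degree: indels shift alignment identities, low-complexity
and repetitive DNA inflates chance similarity, within-genome composition
varies (and recently acquired prophages carry donor composition), and
reference collections are sparse, so real-data accuracy is bounded by
ascertainment, not by these tests.  Problem sizes (60-kb hosts, 10–30-kb
viruses, 100-virus recovery experiments) were chosen as the smallest at
which the 4-mer statistics are well-resolved against the 0.001 threshold;
the thresholds themselves never depend on the sizes.

Known limitations: ungapped alignment only; no Cas-gene or array-orientation
analysis; no assembly-graph circularity evidence; the curation keyword table
is deliberately minimal; and the E-value model uses fixed ungapped constants
rather than composition-adjusted statistics.
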