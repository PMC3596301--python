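# Methods

`snoevo` infers the evolutionary history of polycistronic box C/D snoRNA gene
clusters from comparative genomic data: it detects snoRNAs and their host
introns, compares cluster architectures across a species tree, classifies
intron/exon loss-and-gain events by mechanism, and tests the stepwise 5'→3'
splicing hypothesis for complex introns. Because public genome/EST analyses of
this kind cannot be reproduced at desk scale, the package validates itself
against a bundled genome-evolution simulator with a complete ground-truth
event log.

## The biological model

A polycistronic cluster is a non-coding host gene whose spliceosomal introns
each carry one box C/D snoRNA (box C `TGATGA` near the 5' end, box D
`CTGA`/`ATGA` near the 3' end, and an antisense guide element — the reverse
complement of an rRNA segment — abutting box D). Cluster architectures change
through six mechanisms:

- **de-intronization** — splice signals degenerate; the snoRNA survives in the
  unspliced transcript (cell state `exonic`);
- **genomic deletion loss** — most of the intron plus its snoRNA is deleted,
  leaving a residual terminal stub at the exon–exon junction;
- **excision-and-insertion** — the intron unit is excised at the DNA level and
  re-inserted into a staggered double-strand break elsewhere, leaving a
  target-site duplication (short direct repeats) at the new junction;
- **recombination** — two snoRNA introns fuse into one chimeric intron whose
  snoRNA joins the 5' parent (through its guide) to the 3' parent (from its
  guide through box D);
- **internal exon loss** — an exon between two introns is deleted, leaving
  introns in juxtaposition (a complex intron);
- **intron gain** — a new snoRNA-free intron inserts into an exon (or into a
  snoRNA between guide and box D), accompanied by a short inverted repeat:
  one arm ending the upstream exon, its reverse complement near the intron's
  opposite end (8–12 bp).

## Simulator design

`simulate_evolution` builds an intron-rich ancestor (default: seven families,
named for cluster I, snR78…snR72; snoRNAs 70–100 nt; introns 60–200 nt; exons
5–80 nt; 2 kb neutral flanks) and evolves it by pre-order traversal of a
12-leaf species tree, applying each operator to each eligible element with a
per-branch probability, then i.i.d. point substitutions.

Choices that keep the ground truth unambiguous (and hence make truth-recovery
tests meaningful):

- Cluster-internal random filler avoids exact donor words (`GTAAGT`) and any
  7-mer within 2 mismatches of the branch consensus (`TACTAAC`), so planted
  splice signals are the unique exact-consensus signals.
- Every planted intron ends `branch + pyrimidine tract + AG`: the first AG
  downstream of the branch point is the true acceptor (AG scanning, as in
  splicing chemistry).
- Functional motifs (boxes, guide, donor, branch, pyrimidine tract, acceptor)
  are mutation-protected by default, reflecting their conservation in real
  data; `protect_motifs=False` removes this.
- At most one event per element per branch, resolved by a fixed priority
  (deletion > recombination > excision–insertion > de-intronization > gain >
  exon loss). Chimeric introns and relocated copies are exempt from further
  structural events: a fusion that is itself re-fused or excised leaves a
  history that leaf genomes cannot determine even in principle.
- Exon loss applies only to internal exons flanked by two spliced introns —
  the configuration that creates a complex intron and the only one the
  comparative method can observe.
- Recombination partners are the nearest snoRNA-bearing intron downstream with
  no other snoRNA in between; the fusion consumes the spanned exon(s).
- De-intronization mutates the donor GT and scrambles the branch word to ≥3
  mismatches from consensus, then freezes those positions so later
  substitutions cannot resurrect a signal.
- Residual stubs are retained from the intron's 5' end (length 5–25 nt);
  target-site duplications are 3–8 nt; inverted-repeat arms 8–12 nt.
- Event probabilities are not biologically estimated anywhere; the benchmark
  default (0.05 per eligible element per branch for each operator, 2%
  substitution per site per branch) yields ~25 events spanning all six
  mechanisms on the default tree at seed 42.

The per-branch RNG is derived from `(seed, branch index)`, so identical
configurations give byte-identical FASTA/GFF3/JSON outputs.

The transcript generator emits spliced products of a cluster precursor. In
stepwise mode every product's removed-intron set is a 5'-contiguous prefix of
the intron order (weights configurable); violation mode guarantees at least
one non-prefix product. An error rate adds per-base substitutions (EST-quality
noise).

## Detection pipeline

**Scan** (`snorna_scan`): box C/D pairs are found by tolerant motif matching
(box C ≤1 mismatch, box D exact, start-to-start separation 50–150 nt);
candidate boundaries are anchored by infix alignment of the best-matching
reference family (edlib); guide elements are scored as the longest
reverse-complement match to the rRNA (≥10 nt, ≤1 mismatch); families are
assigned by affine-gap global alignment identity (≥0.6). A candidate whose
refined interval stops short of its box pair, or whose best identity is below
0.8, is tested for chimerism by an exhaustive breakpoint scan (segments ≥20 nt
at ≥0.7 identity against reference prefixes/suffixes, with segments longer
than their parent rejected). Candidates lacking a guide or a family are
discarded; overlaps resolve toward the better guide, then length, then
position.

**Annotate** (`intron_annotate`): for each snoRNA the host intron is the
best-scoring (donor, branch point, acceptor) triple flanking it — donor scored
against `GTAAGT` (GT required), branch against `TACTAAC` (≤2 mismatches),
acceptor `AG` — with ties to the shortest intron, then leftmost donor; the
search never crosses another snoRNA (one snoRNA per intron). The default
acceptance threshold is the maximum score 15: in the validated regime
functional signals are exact, and lower-scoring triples are chance assemblies
(e.g. a residual-stub donor plus a near-branch word) that would re-call
de-intronized snoRNAs as intronic; lower the threshold for permissive scanning
of real genomes. Without a qualifying triple the snoRNA is classified exonic.
snoRNA-free (gained) introns are found by an exact-signal scan (exact donor
and branch, first AG 5–40 nt after the branch preceded by ≥4 pyrimidines)
over the cluster region ±300 nt. Architectures tile the cluster span into
exons and introns; complex introns are maximal runs of ≥2 adjacent introns.

**Compare** (`compare_events`): snoRNAs are grouped into clusters by spacing
(≤400 nt); the main cluster is the largest group, preferring a group that
contains an exonic snoRNA (de-intronized snoRNAs never relocate), then the
leftmost. The presence/absence matrix holds one row per family (states:
intronic / exonic / absent / relocated / chimeric) plus one row per
orthology-group of gained introns (grouped across species at ≥0.7 identity,
keyed by a hash of the representative sequence). Events are placed by Fitch
small parsimony with the full Swofford–Maddison up-pass and two refinements:
the intron-rich root prior acts as a virtual observation at the root, and the
final assignment prefers the parent's state wherever most-parsimonious, so
genuinely ambiguous changes fall on pendant edges where per-species evidence
lives. Event kinds follow the evidence hierarchy relocated copy > residual
stub > state change alone; relocated copies are grouped by insertion-site
flank identity and stubs by anchored terminal-window length (descendants of
one deletion share the stub length; independent deletions differ), so merged
losses in sister clades are split when the evidence is inconsistent.
Recombinations are placed at the MRCA of carriers of each sequence-grouped
chimera, and losses of the parent families on that branch are attributed to
the fusion. Exon rows are keyed by the flanking family pair and tested the
same way (prior: present).

**Repeats** (`repeat_junction`): direct repeats anchor one arm at the junction
(flank suffix/prefix) with the partner within `max_len` of an insert end or at
the opposite flank; inverted repeats pair the last 20 nt of the exon with the
last 20 nt of the intron. Both report all maximal (non-extendable) pairs;
mismatch budgets default to 0 for inverted arms and 1 for direct arms ≥6 nt.
Enrichment never changes an event's kind.

**Splice** (`splice_infer`): each transcript is compared against all 2^k
removed-subset hypotheses (k ≤ 12) by edit distance; the best hypothesis wins
if its mismatch rate is ≤3%. The product set is stepwise-consistent iff every
removed set is a 5' prefix of the intron order — exactly the condition under
which the single-donor/alternative-acceptor model predicts the same classes,
so both compatibilities are reported and never adjudicated.

## Numerical and tie-break conventions

Coordinates are 0-based half-open internally, GFF3 1-based inclusive only at
the file boundary; all features are forward-strand. `N` is accepted in real
input, treated as a mismatch by every scanner, and never emitted by the
simulator. Guide ties break toward fewer mismatches, then leftmost offsets.
Product-hypothesis ties break toward fewer removed introns, then the
lexicographically smallest set. Detected snoRNA ids reuse the family name,
with `_2`, `_3`… for additional copies in genome order, which makes truth and
detection output byte-comparable.

## What passing tests do and do not show

The simulator emulates presence/absence polymorphism, residual stubs,
relocated intron units with target-site duplications, chimeric snoRNAs,
complex introns and junction inverted repeats — with uniform base composition,
no indels outside the six operators, no strand inversion, no assembly gaps,
and conserved (mutation-protected) functional motifs. Validation on it
therefore shows that the inference logic is correct when its assumptions
hold; it does not show robustness to degenerate splice signals, GC/repeat
structure, or draft-assembly artifacts in real genomes. On the benchmark
(12 leaves, seed 42, 2% divergence, ~25 events over all six mechanisms) event
recovery is precision 1.00 / recall 0.96; across other seeds of the same
conditions recovery typically ranges 0.6–1.0, with errors concentrated in
dense cascade realizations — e.g. independent fusions of the same family pair
(sequence-indistinguishable) or losses whose observability later events
erase — where leaf genomes genuinely underdetermine the history.

## Known limitations

- Single-copy families only; paralogous clusters are out of scope.
- Reverse-strand clusters are not modeled (forward strand throughout).
- The 1-nt boundary shared by adjacent introns seen in some real clusters is
  supported only behind `allow_shared_nt` and is never simulated.
- Gains into snoRNAs (between guide and box D) are simulated and structurally
  tested, but a nested intron stretches the box C–box D separation beyond the
  scanner's window, so such snoRNAs are undetectable by the box scan — the
  benchmark therefore targets exons only (`p_gain_into_snorna = 0`).
- `search_relocated` consumes the whole query unit in an infix alignment, so
  its coverage parameter is honored trivially; identity carries the decision.
- Partial-length (truncated) transcripts are flagged but not deeply exercised
  by the simulator, which emits full-length products.
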