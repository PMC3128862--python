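# Methods

This note documents the models, numerical conventions and design choices
behind viroshot, and what the synthetic-data generators do and do not
emulate.

## Read model and trimming

A read is a plain A/C/G/T/N string whose id, when it follows the clone-id
grammar `<lib>_P<plate>_<rowletter><colnumber>.<F|R>`, carries its library,
plate, well and sequencing direction. Trimming truncates at the 3′ end to
`max_len` (default 500 bp) and discards reads shorter than `min_len`
(default 100 bp, boundary inclusive-keep). Truncating 3′-ward reflects
where Sanger chromatogram quality degrades; quality-value trimming is out
of scope because the data model carries no quality information. Trimming
is idempotent and order-preserving.

## Greedy overlap assembly

Commercial Sanger assemblers do not publish their internals, so the
assembler here is a fully specified substitute whose parameters carry the
conventional thresholds for this kind of library: minimum overlap 21 bp,
minimum identity 98%.

Contract: repeatedly merge the pair of reads/contigs with the longest
ungapped overlap ≥ `min_overlap` at identity ≥ `min_identity` (matches /
overlap length, no gaps), considering both strands and allowing
containments, until no qualifying merge remains. Determinism comes from a
total order on candidate merges: longer overlap first, then
lexicographically smallest member read id of each side, then orientation,
then placement offset. Consensus is per-column majority with ties resolved
to the base contributed by the earliest-created member covering the
column.

Implementation: a seed-word index (word length `min(min_overlap, 21)`)
proposes candidate placements and a heap orders them; items are versioned
so stale candidates are skipped after merges. The seed filter is lossless
for the default thresholds: an overlap of length L at ≥ 98% identity has
at most ⌊0.02 L⌋ mismatches, and by pigeonhole its longest exact run is at
least ⌊(L − m)/(m + 1)⌋ ≥ 21 for every L ≥ 21. The test suite verifies
exact agreement with an exhaustive all-placements oracle on small
instances.

Ungapped identity is the simplest testable reading of a bare
"98% identity" requirement; an indel-tolerant variant would need an
alignment model the contract does not specify. This is the one place the
package is deliberately narrower than a production assembler.

## Contig classification

`same_clone`: all members share library, plate and well — the
forward/reverse reads of one clone. `adjacent_well_suspect`: members share
library and plate and every pair of distinct wells is at Manhattan
distance 1 with row letters mapped to integers; diagonal wells are *not*
adjacent (the narrowest reading of "adjacent wells", chosen because the
classification flags likely pipetting cross-contamination). Everything
else is `independent`; unparseable ids give `unknown` with a logged
warning. The inter-clone read fraction reports reads in non-`same_clone`
contigs as a percentage of all reads, at one decimal.

## Hit annotation

Hit tables are TSV with columns query_id, subject_id, percent_identity,
evalue, bit_score, database, subject_description, source_category. The
source category is a closed vocabulary (bacteriophage, eukaryotic_virus,
mobile_element, bacteria, archaea, eukaryote, microbial_metagenome,
viral_metagenome, unknown) carried as data: faithful automated taxonomy
assignment would require live database access and manual curation, so it
is an input, produced by the generator or by the user.

Significance is inclusive (E ≤ threshold, default 10⁻³). Top hits minimize
E-value with ties broken by maximal bit score then lexicographic subject
id. Keyword flagging is deliberately permissive plain substring matching
("cocktail" matches "tail"), so flags mark *candidates*; confirmed virus
status comes from the category column, mirroring a manual-verification
workflow. Any-hit summaries count a query if *any* significant hit is
viral; known-virus counts exclude queries whose only viral evidence is a
viral-metagenome match, and each known-virus query is attributed to phage
or eukaryotic virus by its best known-virus hit. Queries hit in several
databases are deduplicated per query. Reported percentages round half-up
at the printed precision (integers for the virus split).

## Threshold analysis

Sweeps evaluate the composition of significant top hits at each threshold
among collapsed groups (default: virus = bacteriophage + eukaryotic
virus; prokaryote = bacteria + archaea; eukaryote; mobile elements kept
separate; the collapse map is configurable). Categories without a
taxonomic group (metagenome-derived, unknown) are excluded from the
composition so that group proportions sum to 1; they still count in the
cumulative significant fraction. Decade bins are half-open
[10ᵏ, 10ᵏ⁺¹), lower-inclusive, consistent with the inclusive significance
boundary; a floating-point guard snaps values within 10⁻⁹ relative of a
decade edge onto it.

The break point is operationalized as the adjacent pair of decade labels
(thresholds for sweeps, bin lower edges for bins) with the maximal
decrease in the summed virus + prokaryote proportion, ties to the most
stringent pair, none-found when the series never decreases. "Sharp
decline" has no standard quantification; max-drop is the simplest
deterministic choice and reports should treat the result as an empirical
indicator, not a tested change point.

## Library comparison

A "hit" is always a distinct query sequence with at least one match at
E ≤ threshold (default 10⁻⁵ for inter-library comparisons, stricter than
the annotation default), never a raw HSP row — circle-area style summaries
of "proportion of a library's sequences with a hit" are per-sequence
quantities. The three parameters and the reciprocal distance are defined
in the README; both directions of a pair are always reported separately
because cross-search is asymmetric. Zero hits give an explicit infinite
distance sentinel that ranks last and is never silently dropped. With
length normalization enabled and equal mean read lengths the results equal
the unnormalized ones exactly.

The bundled cross-search is a desk-scale stand-in: two reads match if they
share an exact word of ≥ `word_size` (default 20) nucleotides on either
strand, with pseudo E-value 10⁻⁵ · 4^(word_size − L) for longest shared
word L — monotone in L and exactly at the comparison threshold for the
minimum word. It exists so the comparison pipeline can be exercised and
tested end to end; real translated-search output in the same TSV dialect
should be used for scientific conclusions.

## Particle accounting

Densities are mass/volume per fraction; totals are Σ concentration ×
volume over an explicit fraction selection (the caller chooses which
fractions were pooled). DNA per particle is reported in attograms
(nearest integer); the implied genome size assumes double-stranded DNA at
660 Da per base pair (650 is also in use; the constant is configurable and
shifts the kb figure by ~2%). Recovery divides recovered particles by
volume filtered times a historical abundance range — the high abundance
bounds recovery from below — and is labelled an estimate. Expected gene
copies is total library bases over mean genome size: the ceiling on how
often a single-copy viral gene could be seen if every genome carried it.

## Synthetic data

The generators emulate the *structure* of a direct-cloned virome study,
not its biology:

- Genomes are i.i.d. uniform nucleotides at a GC fraction (default 0.45,
  mid-range for marine phage isolates) with lengths drawn from four size
  classes (30–45 kb, 60–80 kb, 125 kb, 146–200 kb). Class weights default
  to equal because no abundance distribution is specified for the size
  classes; the open-ended largest class is capped at 200 kb. There is no
  repeat structure, codon structure or shared gene content — sufficient
  for exercising overlap assembly, where what matters is exact/near-exact
  sequence identity, but nothing downstream should be read as a statement
  about real viral communities.
- Clones draw uniform-random inserts of 1.4–4 kb (the size-selected band),
  emit a forward read from the 5′ end and, for paired clones, a reverse
  read as the reverse complement of the 3′ end; read lengths are Gaussian
  (default mean 600, sd 120, floored at 100) so that trimming at 500 bp
  has work to do. A configurable fraction of clones re-emits an earlier
  insert under a new well id, planting legitimate inter-clone contigs with
  known identities; generators return this bookkeeping so tests can score
  recovery. No sequencing-error or chimera model is included: planted
  overlaps are exact, so assembly tests verify the algorithm, not its
  robustness to base-calling noise.
- Hit tables give each query a hit with probability `hit_rate`; the
  query's primary category is multinomial over the composition (a `none`
  entry means no rows for that query), extra hits draw from the
  composition renormalized over hit categories, and E-values are
  log₁₀-uniform within each category's decade range — enough to exercise
  threshold sweeps across decades without modelling score statistics.
  Virus-category descriptions always contain the standard keywords so the
  keyword flag closes the loop. The default composition plants roughly
  8% virus, 15% bacteria and 74% no-hit against a curated database, the
  regime where most library sequences are novel.
- Gradient profiles place twelve 0.3 ml fractions on a monotone density
  ramp (default 1.44–1.55 g/ml) with particle concentrations peaking in
  the top four fractions at a level that totals ~1.9 × 10¹¹ particles;
  mass is density × volume plus Gaussian noise (σ = 0.5 mg by default,
  zero reproduces the planted densities exactly).
- Library pairs share a stated fraction of their genome pools (smaller
  10 × 8 kb genomes by default so that desk-scale cross-search has
  signal) and come with cross-hit tables in both directions.

One global seed expands to fixed per-stream sub-seeds, so each generator
is reproducible independently of which others ran. Same seed and
parameters give byte-identical output everywhere.

## Problem sizes in the test suite

The suite runs the worked examples at their natural sizes (907-read
benchmark assembly) and the property suites at sizes chosen to keep the
whole run around a dozen seconds on one core: oracle-equivalence on ≤ 20
reads × 50 seeds, composition recovery at n = 5000, break-point detection
at n = 400 × 50 runs, comparison monotonicity at 150 reads per library ×
5 shared fractions × 5 seeds, and an end-to-end smoke run on 1,000 reads.
Statistical assertions use 99% binomial bounds or a χ² goodness-of-fit at
α = 0.01 under fixed seeds.

## Known limitations

- The assembler is ungapped and greedy; it will not recover overlaps with
  indels and does not optimize multi-read contig layouts beyond greedy
  order.
- Source categories are inputs; nothing resolves taxonomy from subject
  descriptions beyond the permissive keyword flag.
- The naive cross-search scores only exact shared words; its pseudo
  E-values are calibrated to the comparison threshold, not to any search
  statistic.
- Synthetic genomes are memoryless; assembly and comparison results on
  them bound algorithmic correctness, not performance on repeat-rich real
  viral DNA.
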