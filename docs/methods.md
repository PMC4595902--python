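# Methods

## Model and assumptions

`mirmod` treats a small RNA read as a (possibly modified) copy of a mature
miRNA transcribed from a hairpin precursor. A base in the read is evidence
of modification exactly when it cannot have derived from the precursor at
the read's alignment position: it either mismatches the hairpin inside the
aligned core, or lies outside the core (beyond the hairpin, or in a
terminal mismatch run). Bases beyond the annotated mature end that *match*
the hairpin are templated length variants (isomiRs) and generate no
modification event.

The model is substitution-and-terminal-addition only: no gapped alignment,
because the modification classes of interest (tails, terminal variants,
edits, SNPs) do not involve indels. Antisense placements are never
considered; consequently A-to-I editing is read as A→G and the antisense
T→C signature is deliberately not counted.

Base-calling error is not modelled. Errors are rare, approximately uniform
across substitutions, and pseudo-random across positions, so they
contribute a thin background across all profile cells rather than the
position- and pattern-coherent signals the caller aggregates; quality
strings are parsed and carried but unused.

## Coordinate frame

All positions are reported on the canonical placement of the mature on its
hairpin: index 0 at the mature 5′ end, *L*−1 at the 3′-terminal base,
negative upstream, +*k* downstream. 3′-side tables are rendered as offsets
about the 3′ end (+1 = first base after the terminal base); 5′-side tables
as offsets about the 5′ end; internal events and the global profile use
absolute indices. Different-length matures are aggregated by relative
offset in the terminal profiles and by absolute index in the global one.

## Classification windows and rules

| parameter | default | meaning |
|---|---|---|
| 3′ window | −5 … +6 | offsets about the 3′-terminal base classed as 3′-modification |
| 5′ window | −8 … +5 | offsets about the 5′ end classed as 5′-modification |
| SNP threshold | 0.70 (inclusive) | modified/total depth ratio at which an internal substitution is a SNP |
| max core mismatches | 2 | mismatches tolerated inside the aligned core |
| min core | 15 nt | shortest acceptable aligned core |
| size window | 16–35 nt | read lengths retained after trimming |
| multimap policy | first_hit | or `fractional`: equal weights across tied paralogues |
| fold-change pseudo-count | 1.0 | added to group means before log₂ |

The terminal windows intentionally overlap the mature body so that
substitutions near an end are absorbed into the terminal class instead of
being mistaken for internal variation of a shorter/longer isomiR. A
contiguous run of non-templated bases within one class forms a single
multi-base pattern ("TT"), indexed at its first base; a templated base or a
class boundary splits runs. Internal events are one event per substituted
base. In the (degenerate, short-mature) case where a position falls in both
terminal windows it is assigned to the nearer end, ties to the 3′ side.

Internal ratios pool depth across samples — a SNP is a property of the
source genome, not of one library; per-sample classification can be had by
running samples separately. The ratio denominator counts every read base
spanning the position (overhangs included), derived from the same
placements as the events, so an event can never see zero coverage. The
0.70 boundary is inclusive by decision: a ratio of exactly 0.70 calls SNP.

Attribution of a placement to a mature requires the aligned core to overlap
the canonical locus by ≥ 50% of the mature length; reads placing on a
hairpin but attributable to no mature are logged and excluded from counts
and events.

## Alignment

References are short (hairpins of ~50–150 nt), so the aligner scans every
ungapped offset of every hairpin rather than building a seed index. At each
offset it selects the *optimal* local core — the read interval bounded by
matching columns, containing at most 2 mismatches, of length ≥ 15,
maximizing matching columns — by enumerating the maximal windows between
consecutive mismatch positions. This exact trim choice (rather than greedy
trimming of terminal mismatch runs, which it subsumes) is what the
brute-force equivalence test pins down: over random read/hairpin pairs the
best core-match count equals exhaustive enumeration of every (offset,
left-trim, right-trim) combination. Ties across hairpins/offsets keep every
best-scoring placement, ordered by (fewest core mismatches, shortest
overhang, hairpin id, offset), making "first optimal hit" deterministic. N
bases mismatch everything.

## Adapter inference

The most frequent 10-mer across the 3′ halves of a read sample (each read
votes once per k-mer; lexicographically smallest on ties) seeds the call;
it is then extended one base at a time, leftward first and then rightward,
while the extended string remains present in ≥ 50% of the seed-supporting
reads. Leftward extension stops at the insert/adapter junction because
upstream bases are random insert sequence, so the call converges onto the
adapter's true 5′ start; rightward extension stops where read ends truncate
the adapter. No 10-mer reaching 20% support means "no adapter detected",
which callers must distinguish from a low-support call. Trimming cuts at
the leftmost junction whose read-suffix/adapter-prefix overlap is ≥ 6 nt
with ≤ 12.5% mismatches; adapter dimers therefore trim to length 0 and are
removed by size selection. Trimming is idempotent.

## Normalization

Size factors follow the median-of-ratios estimator: the factor of sample
*j* is the median over miRNAs with all-positive counts of
counts(*m*, *j*) / geometric-mean over samples of counts(*m*, ·).
Factors are reported rescaled to geometric mean 1; this leaves every
between-sample ratio unchanged and makes normalization idempotent
(re-estimating on a normalized matrix returns factors of exactly 1 within
float tolerance). When no miRNA is positive in all samples the estimator
refuses and advises the pseudo-count fallback rather than guessing.
Dispersion estimation and hypothesis testing are out of scope; fold-change
tables are descriptive.

## Simulator: what it emulates and what it does not

The generator draws random hairpins (60–90 nt) with one embedded mature
(20–24 nt) per hairpin, flanked by ≥ 12 nt on both sides, rejection-sampled
so each mature sequence occurs exactly once in the whole reference; a
paralogue mode copies one mature into extra hairpins to exercise fractional
counting. Reads carry, per configured rates: a non-templated 3′ tail
(defaults U 0.30, A 0.15, length 1), a templated 3′ extension (0.10;
mutually exclusive with tailing so injected tails sit exactly at +1), a
non-templated 5′ base (0.05), an internal A→G edit (0.10) at a position
outside both terminal windows, substitutions at fixed SNP loci (one locus,
allele fraction 0.80), an appended 3′ adapter (probability 1.0) and uniform
per-base sequencing error (0.001). One seed fixes every output byte.

A tail base that coincides with the templated hairpin base downstream of
the mature is biologically indistinguishable from templated extension; the
truth table flags each tail's distinguishability, and recovery checks
compare against distinguishable truth (or measure pattern shares on matures
whose downstream base collides with neither tail type). What passing tests
show is therefore that the pipeline recovers everything that is in
principle recoverable from sequence alone — not that template-coincident
tails can be seen, which no hairpin-anchored method can do.

The simulator does not emulate: realistic (heavy-tailed) expression unless
the log-normal toggle is set, position-dependent error profiles, 5′
adapters/barcodes, multi-class tail mixtures on one read, or real miRBase
sequence composition. Conclusions about real libraries should rest on the
method's contracts (windows, thresholds, conservation), which the tests pin
exactly, not on the simulator's error model.

## Numerical and determinism choices

Counts are exact floats (integers under `first_hit`; sums of 1/n weights
under `fractional`). All tables are written with sorted rows and
shortest-round-trip float formatting, so identical runs are byte-identical;
the run log contains no timestamps for the same reason. Mature iteration,
placement ties and event grouping all break ties lexicographically.
Problem sizes in the test suite (20 000 reads for parameter recovery,
10 000 trials for the alignment oracle, ~10–20 hairpin references) were
chosen as the smallest sizes at which binomial tolerances are informative.

## Known limitations

* Low-frequency modifications are not distinguished from sequencing error
  (no quality-aware error model).
* Mature-to-hairpin linkage relies on the miRBase naming convention with an
  exact-substring fallback; exotic naming schemes land in the rejects
  report.
* Internal classification below the SNP threshold labels only A→G as
  editing; other low-ratio substitutions stay `other_internal` rather than
  being attributed to specific enzymes.
* The aligner is exhaustive-scan by design and sized for hairpin-scale
  references; it is not a genome aligner.
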