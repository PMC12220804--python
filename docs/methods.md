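# Methods

This note documents the models and procedures implemented in `plvscan`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open intervals on named contigs.
GFF3 is written 1-based inclusive with the version pragma, BED stays
0-based half-open; conversion happens only in `seq_io` writers/readers, and
round-trip tests pin both conventions. FASTA input is uppercased and any
character outside `{A,C,G,T,N}` is masked to `N` (the detection algorithms
treat `N` as a universal mismatch; IUPAC ambiguity codes carry too little
signal at these scales to warrant special handling). Strand `"."` marks
strand-agnostic features (TIRs, elements, TSDs).

## Inverted-repeat detection (`tir_finder`)

An inverted-repeat pair is two disjoint arms on one contig, arm5 before
arm3, such that arm5 aligns locally to the reverse complement of arm3 with
score ≥ 50 under einverted-convention scoring: match +3, mismatch −4,
linear gap penalty 12 per gapped column, outer span (arm5 start to arm3
end) ≤ 80 kb. These constants are the EMBOSS einverted defaults; all are
exposed in `IRScoring`.

Two search paths share those semantics:

* **Exact path** (contigs ≤ 2 kb): a full local-alignment dynamic program
  over S × revcomp(S). Writing the DP cell (a, b) for a prefix of S against
  a prefix of revcomp(S), the restriction a + b ≤ n keeps the two arms
  disjoint. All cells above threshold are visited in (score, position)
  order; each is traced back (move preference diagonal > up > left) and
  accepted unless either arm overlaps a same-role arm of an already
  accepted pair (best-score-wins for competing pairs sharing an arm locus —
  einverted's behaviour here is not documented, so the convention is
  declared and flagged). The vectorized row sweep resolves the within-row
  linear-gap recursion with a prefix-scan (`max` accumulate of
  `H + b·gap`), which is exact for linear gap costs. Tests compare this
  path cell-for-cell against an independent plain-loop oracle.
* **Seeded path** (longer contigs): positions i, j with
  S[i:i+13] == revcomp(S[j:j+13]) are found by integer k-mer coding; an
  indel-free inverted repeat keeps i + j constant, so seeds are grouped by
  anti-diagonal band (width 64) and clustered along i (gap ≤ 1.5 kb).
  Clusters with ≥ 3 seeds spanning ≥ 25 bp define candidate arm windows
  (±200 bp pad) that are locally realigned with `Bio.Align.PairwiseAligner`
  under the same scoring. k = 13 keeps the chance seed rate on a 2 Mb
  contig to tens of thousands while arms ≥ 100 bp at ≥ 90% identity almost
  surely contain an exact 13-mer.

Reported scores are reproducible by globally aligning the extracted arms
(`recompute_pair`): the local optimum restricted to its own substrings is
end-to-end, so the two values coincide. `tir_identity` re-aligns arms
globally with an affine-gap scheme (match 1, mismatch −1, open −5,
extend −2) and reports matches over alignment columns × 100; the scheme's
heavy gap costs keep substitution-only arm pairs gapless, so an arm pair
constructed with 3 substitutions in 100 bp scores exactly 97.0.

Candidate filters keep pairs with insert length 6–80 kb and both arms
100 bp–8 kb, bounds inclusive. Nested pairs (one insert inside another)
are deliberately retained — nested mobile elements are real.

## GC scanning (`gc_scan`)

GC is computed over non-N bases in non-overlapping 500 bp windows (the last
window of a contig may be short); all-N windows carry NaN and neither break
nor extend segment runs. Segments are maximal runs of windows deviating
from a host baseline by ≥ 10 percentage points with a consistent sign,
tolerating one intervening non-deviant window (nested insertions and short
host-like stretches inside an element would otherwise split it), reported
when spanning 5–80 kb. The 10-point default sits below the smallest
element-vs-host contrast this class of element typically shows (~14
points) while staying far above window noise (sd ≈ 2.2 points for a 500 bp
window at GC 0.5); it is a declared convention, configurable, not a
literature value. Per-element GC deltas compare the element against up to
10 kb of flank on each side, truncated at contig ends and at neighbouring
annotated elements; an element covering its whole contig falls back to an
assembly-wide baseline with a warning.

## TSD calling (`tsd_caller`)

`call_tsd` is an exhaustive sliding/padding search over 50 bp flanks: for
every length L in [4, 25] and per-side offsets (o_l, o_r) in [0, 3]², the
left copy is the last L bases of the left flank before an o_l pad, the
right copy the first L bases of the right flank after an o_r pad. A
candidate is valid when its Hamming mismatch count is ≤ 2 and ≤ ⌊L/5⌋ (the
proportional cap encodes that one mismatch in a 7-mer is credible while
degenerate short matches are not). The best candidate maximizes
matches − mismatches, ties broken toward longer L, then smaller total
offset, then fewer mismatches; the consensus takes the left-copy base at
mismatched positions. The max length 25 covers the long (7–23 bp)
recombinase-associated class with margin; the min of 4 covers canonical
~4–6 bp integrase duplications. Because the search space is generous, a
chance candidate exists in roughly 18% of unrelated 50 bp flank pairs —
the low-complexity flag and the conservation summary exist precisely to
keep such background out of headline numbers. A motif is flagged
low-complexity when it has ≤ 2 distinct bases or one base at ≥ 80%
frequency — the weakest rule that flags `GAGGG` while passing `GTTAT` and
`TGAATAA`. Offsets on both sides simultaneously are permitted (whether the
original analyses allowed this is unknowable; both offsets are reported).
The per-genome conservation summary reports two numerators — calls with
mismatches within the cap, and strictly exact calls — since "conserved"
is ambiguous between the two.

### Junction ambiguity and boundary rescue

The local inverted-repeat alignment extends one column whenever the base
just outside one TIR complements the base outside the other. Across a
reverse-complement-palindromic TSD this happens at *every* column, so the
reported element boundary systematically swallows such duplications and
can then drift further on chance matches. `call_tsd_near_boundary`
therefore re-runs the caller at symmetric inward boundary shifts
e = 0..20 and keeps the best-scoring reading, ties to the smaller shift,
under rules derived from the structure of the spurious-candidate classes:

* shifted copies must abut the shifted boundary exactly (offsets 0) and
  match perfectly — register-preserving pseudo-extensions of a true
  duplication require unequal offsets or mismatch budget, so they can
  never win;
* beyond 5 bp the candidate must be ≥ 6 bp and must not equal its own
  reverse complement at register shift −1/0/+1 — a spurious candidate
  drawn from within a TIR arm pairs a stretch against its own mirror image
  and is structurally forced into such a near-palindrome, whereas shifts
  ≤ 5 bp cannot move a boundary materially even when wrong;
* off-by-one asymmetric shifts (a gapped over-extension can leave the two
  sides one column apart) are considered only when they beat the best
  symmetric reading by ≥ 2, which exactly excludes single-column
  annexations;
* at the unshifted stage, candidates pay 2 points per bp of offset
  asymmetry (`asym_penalty`), again because only unequal-offset registers
  can annex chance columns.

The winning shift is fed back into the element call: the element and arm
intervals shrink by e per side (the dropped columns are matches by
construction, so the score drops by 3 per column and the identity is
re-measured). Some readings remain genuinely ambiguous — a quasi-
palindromic TSD whose junction reads equally well as TIR or duplication,
and 4 bp duplications swallowed under > 5 bp of drift — and are
knowingly left uncorrected; on simulations these amount to roughly 3–6%
of elements (see Limitations).

The truth tables of the synthetic generator record the *maximal symmetric
exact duplication present in the emitted sequence*, not merely the sampled
core: when the i.i.d. junction bases happen to extend the planted
duplication on both sides, the longer repeat is simply what is in the
sequence, and any caller should report it.

## Element calling and statistics (`element_caller`)

Marker hits are consumed from tabular HMM-scan output (the pipeline's own
TSV, or HMMER domtblout plus a gene-coordinate table); hits are dropped at
e-value ≥ 1e-3, capsid-class (MCP) hits additionally below 70% model or
query coverage — two regimes mirroring how capsid assignments warrant
stricter evidence than auxiliary markers; non-MCP coverage thresholds
default to 0. Per protein and marker class the best hit is kept, and every
filter logs its drop count so the candidate funnel is auditable.

Each size-filtered TIR pair defines a candidate element spanning TIR outer
edge to TIR outer edge (TSDs lie outside). With `require_marker` (default:
on — real elements carry hallmark genes) a candidate needs ≥ 1 marker hit
inside; TIR-only candidates go to a separate candidate track rather than
being silently dropped. GC delta is corroborating evidence, not a gate
(`min_gc_delta` defaults to 0), because population-level GC contrast does
not bind every element. Classification is total and deterministic: PLV-type
MCP only → PLV, virophage-type only → virophage, both → hybrid, hallmarks
without an MCP → unassigned. Nested retroelement insertions are GC-
divergent sub-segments (≥ 5 points against the element's own mean — the
baseline is diluted by the insertion itself, hence the lower threshold;
3–12 kb) containing a non-hallmark (`other`-class, e.g. reverse
transcriptase) hit. Genome statistics follow directly (density = n /
(assembly length / 1e6); percent of genome; mean length; mean TIR identity;
TSD conservation); density is reported at one decimal, full precision kept
internally.

## Gene-sharing network (`gene_network`)

Genomes and ortholog clusters form a bipartite graph: protein→ortholog and
protein→genome tables define edges weighted by the number of member
proteins a genome contributes; ortholog clusters with fewer than 10
proteins are excluded before edges are built. Community detection
optimizes Barber's bipartite modularity (the natural bipartite analogue of
Newman modularity, with the null model confined to genome–ortholog pairs).
The optimizer alternates full local-move sweeps over genome nodes then
ortholog nodes (sequential mode, letting the two classes settle
independently), allows a node to retreat to a fresh singleton community
when every existing community is a strict loss, and interleaves community
merges (zero-gain merges are taken when the communities are connected,
favouring fewer communities — this is also how a single-edge graph
resolves to one community). Ties in gain break toward the lower community
id. Eight restarts, the first from singletons and the rest from random
coarse partitions, all derive from the caller's seed, so results are
deterministic given the seed; randomized starts let the search cross
barriers that the greedy all-singletons basin cannot (verified against
exhaustive partition enumeration on graphs of ≤ 12 nodes). The resolution
parameter scales the null term and defaults to 1.

Dereplication is greedy longest-first clustering: a sequence joins the
first representative it matches at ≥ 90% identity (matches over local-
alignment columns) covering ≥ 90% of the shorter sequence, forward strand
only. It stands in for CD-HIT's semantics at small scale and makes no
claim of equivalence. Cluster summaries report, per genome community, the
member count and the fraction of members carrying each marker class.

## Synthetic genomes (`synthetic_data`)

The generator emulates the detection signals, not genome realism: host
background and element interiors are i.i.d. per base (host GC 0.42,
element GC 0.60 — an 18-point contrast inside the 10–30-point range
observed for real endogenous elements), which makes analytic expectations
(window variance, chance seed rates, null TSD rates) available to tests.
Defaults: 10 contigs × 2 Mb, 100 elements of 6–40 kb (mean ≈ 23 kb,
matching the reported mean element length), TIR arms 100 bp–3 kb (the
typical observed scale; the full 100 bp–8 kb range is configurable) at 95%
arm identity via substitutions, exact 4–6 bp TSDs at offset 0, 10 elements
carrying a nested 4–9.5 kb GC-rich (0.70) retroelement flanked by 300 bp
direct repeats ("a few hundred bp" made concrete) with a synthetic
reverse-transcriptase hit. Marker cassettes (MCP_PLV, pATPase, protease)
are represented in the emitted hit table rather than as translatable ORFs —
the pipeline consumes hit tables; HMM scanning itself is out of scope. The
fraction of elements with nested insertions is a knob with no claimed
real-world default. Packing that cannot fit raises a hard error naming the
first conflicting element. Fixed seed fixes every output byte.

What passing tests show: the geometry, composition and junction logic of
the pipeline are correct against an exact truth table. What they do not
show: behaviour on real repeat-rich genomes (segmental duplications and
transposon families create seed clusters and spurious inverted repeats far
beyond the i.i.d. background), on degraded ancient elements, or with real
HMM scan noise.

`toy_worked_examples` builds two fixed constructs whose flanks carry the
two literature-style TSD motifs (a 7 bp duplication with one mismatch,
TGAATAA/TCAATAA, and an exact 5 bp GTTAT), sized well inside the 6–80 kb
element filter; these are the acceptance worked examples.

## Problem sizes used in the test suite

Unit tests run on 250–300 kb two-contig simulations (8 elements); the
recovery acceptance test runs the full default (20 Mb, 100 elements,
seed-fixed, ~1 min); oracle-equivalence suites use 1000 random contigs
≤ 300 bp (inverted repeats), 1000 random flank pairs (TSDs) and ~40
graphs of ≤ 12 nodes (modularity). These sizes were chosen so the whole
suite completes in a few minutes while still exercising every code path at
meaningful scale.

## Known limitations

* Boundary accuracy is limited by genuine junction ambiguity: a reverse-
  complement-palindromic TSD makes the element boundary mathematically
  underdetermined, and chance drift can extend it further. On default
  simulations ~3–6% of planted elements end up with boundaries > 5 bp off
  or an unrecoverable TSD; no local decision rule can do better without
  corrupting more elements than it rescues (measured, not assumed).
* The seeded TIR path can miss arms shorter than ~25 bp or below ~85%
  identity on long contigs (no exact 13-mer seed); the exact path has no
  such limit but is quadratic.
* The modularity optimizer is a local search with randomized restarts;
  global optimality is verified only at oracle scale (≤ 12 nodes).
* Dereplication is O(n²) in the number of sequences and forward-strand
  only.
* The generator plants substitution-only TIR divergence (no indels), so
  gapped-arm handling is exercised only through the scoring machinery, not
  through planted truth.
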