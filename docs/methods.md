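# Methods

## The annotation model

`nlrkit` treats NLR annotation as a rule system over two evidence streams for
each protein: *signature hits* (intervals from InterProScan member databases:
Pfam, Gene3D, SUPERFAMILY, PROSITE profiles, SMART, CDD, PRINTS) and *motif
hits* (FIMO-style PWM matches for the NB-ARC-diagnostic RNBS-D, MHD and linker
motifs — motif indices 2, 7 and 8 of the classical 20-motif NLR set). The
classifier never looks at the raw sequence; all signal is carried by the
evidence tables. This is what makes the whole pipeline testable with synthetic
fixtures: the generator plants evidence for a target architecture and the
pipeline must reconstruct it.

Coordinates are 1-based inclusive throughout — the convention shared by
InterProScan TSV, FIMO TSV and GFF3 — so no conversion ever happens
internally.

### Domain vocabulary

Each category is a fixed accession set (see
`nlrkit.classify.DomainVocabulary`): R1 (PF12061), Rx-type CC (PF18052,
cd14798, G3DSA:1.20.5.4130), RPW8-type CC (PF05659, PS51153), TIR (6 IDs),
NB-ARC (PF00931, G3DSA:1.10.8.430), LRR (21 IDs), the wider NB-ARC-extraction
set (6 P-loop/winged-helix/helical fold IDs), the P-loop NTPase pair
(SSF52540, G3DSA:3.40.50.300), the MLKL HeLo domain (PF06760) and a few
integrated-domain signatures (ALOG, zf-BED). Anything else is category
"other" (letter `O`). No score cutoffs are applied to signature hits; the
cutoffs live entirely on the motif side.

### Motif filter

Hits are kept at score ≥ 60.0 and q ≤ 0.01 (both boundaries inclusive). The
MHD and linker motifs carry a stricter score ≥ 85.0 requirement *for NB-ARC
extraction evidence only*: sub-threshold hits survive in the annotation
output but are flagged `extraction_ok=False` and ignored by NB-ARC detection
and the degeneracy rule. Keeping rather than deleting them preserves the
annotation record while still enforcing the stricter evidentiary bar. All
thresholds are plain function parameters.

### NB-ARC detection and the NLR rule

NB-ARC-extraction signatures are chained by strict interval overlap (no gap
tolerance: split hits of one NB-ARC always overlap, while tandem NB-ARC
domains are separated by linkers). A chain is an NB-ARC region iff it
overlaps an NB-ARC accession hit, or an extraction-eligible diagnostic motif;
the region boundary is the union of the chained signatures, extended over any
supporting motif. Regions are numbered 1..k by start; extraction emits
`id_k` records when k > 1, the parent ID otherwise. NB-ARC presence — either
clause — defines category `NLR`, and the clause that fired is reported
(`nbarc-signature` / `nbarc-motif`). NB-ARC alone suffices for the category
(no second domain required); the architecture column lets users filter
single-domain NLRs if they prefer the stricter dataset definition.

### Degeneracy, precedence and the remaining categories

`NLR-degenerate` fires on either arm: (a) a sensor-type domain (CC, R1,
RPW8, TIR) plus a *stand-alone* P-loop NTPase hit — one whose interval
overlaps no non-P-loop signature from any database; or (b) a sensor-type
domain or LRR plus an extraction-eligible diagnostic motif. The
"stand-alone" condition is what excludes kinases, AAA ATPases and ABC
transporters whose P-loop co-annotates with their own domain — the classical
false-positive mode of P-loop-based NLR extractors. Then `MLKL` (HeLo
domain), `TX` (TIR-only), `CCX` (CC- or R1-only), `RPW8`, `non-NLR`, in that
order. The precedence (NLR > degenerate > MLKL > TX > CCX > RPW8) is a design
choice — the category definitions do not order themselves — chosen so
stronger evidence always wins and the partition is deterministic; the
within-tier order TX > CCX > RPW8 follows the listing order and only matters
for proteins carrying two sensor domain types and nothing else.

### Architecture strings

One letter per merged call in start order (`1CRTNLJO`), overlapping calls of
different categories both kept (ordered by start, then longer first), and
adjacent identical letters compressed (`TNLLL` → `TNL`). Same-category
signature hits merge across gaps up to 20 aa — split Gene3D/SUPERFAMILY hits
are common — a tolerance exposed as a parameter. For benchmarking
comparisons the string is further *canonicalized*: letters outside
`{T,C,R,N,L}` are dropped and repeats re-compressed, so `CONL` compares equal
to `CNL` (integrated domains and R1/C-JID are not scored).

## The PWM scanner

Scores are sums of per-position log2 odds, `log2((p + 1e-4)/b)`, with a
uniform 1/20 background by default (overridable; the background used by any
particular published FIMO run is generally unstated, so absolute scores from
this scanner may differ from a meme-suite run — which is why the thresholds
are parameters and real FIMO TSV is accepted as a drop-in). Letters outside
the alphabet (X etc.) contribute 0, i.e. score as background.

P-values are exact under the background model: per-position scores are
quantized to integers at 1/1000 bit, the distribution of the window sum is
built by convolution, and the survival function is read off. Reported window
scores sit on the same grid, so score and p-value are always consistent; the
quantization error against unquantized scores is below L/2000 bits for an
L-position motif (≈ 0.01 bits for the ~20-position NLR motifs — irrelevant at
thresholds of 60/85). For small motifs the DP is verified against full word
enumeration in the tests. Q-values are Benjamini–Hochberg (via statsmodels)
over *all* windows of a scan — one testing family per scan, mirroring
FIMO's behavior.

## Redundancy reduction

Identity follows the CD-HIT convention: identical aligned residue pairs
divided by the shorter sequence length, from a global Needleman–Wunsch
alignment (match +1, mismatch 0, linear gap −1, end gaps penalized). Because
alignments of equal score can differ in match count, the DP optimizes
(score, matches) lexicographically — both components are additive, so this is
exact — making the identity value well defined and order-independent.
Clustering is greedy incremental over length-sorted input (ties by ID):
each sequence joins the first cluster whose representative it matches at ≥
the threshold (default 0.90), else seeds a new cluster; the representative is
therefore the longest member. This is exact where CD-HIT's word filter is
heuristic, so boundary cases within a fraction of a percent of the threshold
can cluster differently than a CD-HIT run. Per-genus reduction keeps the
cluster representative for its own genus and the longest member (ties by ID)
for every other genus present — the selection rule for non-representative
genera is our declared convention. Complexity is O(n·m) per comparison and
O(k) comparisons per sequence against k representatives; intended scale is a
few thousand sequences.

## Alignment trimming and statistics

A column is kept iff its site coverage (non-gap fraction; `X` counts as
coverage, `-` and `.` as gaps) is ≥ the threshold — a column at exactly 95%
is kept, making the "less than 95% removed" rule's boundary explicit.
Trimming is idempotent and never removes a gap-free column. Length statistics
use the sample (n−1) standard deviation — printed means/stdevs of real
datasets are integers, so either convention matches after rounding, but the
choice is documented for reproducibility — and flag outliers strictly beyond
mean ± 2·stdev. PHYLIP I/O is relaxed-format (full IDs) via Biopython.

## Synthetic data generator

`nlrkit.fixtures` emulates the evidence structure of an annotated proteome:
for a target architecture string it concatenates uniform-random residue
segments (domain-typical lengths, e.g. NB-ARC 280–330 aa, CC 120–160 aa) with
5–30 aa linkers, emits one signature hit per segment from that letter's
vocabulary, plants diagnostic motifs inside the NB-ARC segment (default
score 90, q 1e-4 — clearing both thresholds; boundary fixtures at
59.9/60.0/84.9/85.0 and q 0.01/0.011 exercise the filter edges), and can
append stand-alone P-loop or HeLo segments for the degenerate and MLKL
categories. The intended category and architecture are derived directly from
the plan by the category definitions, independently of the classifier, and
emitted as a truth table. Files are byte-identical for a fixed seed.

What the generator does **not** emulate: real signature score distributions,
partially overlapping or missing member-database hits, domain boundary noise,
compositional bias, or sequence-level homology between fixture "domains".
Passing the synthetic suite therefore shows the rule system, parsers and
coordinate handling are correct — not that any particular HMM library would
produce this evidence for a real proteome. Family generation for clustering
tests is substitution-only (no indels) at an exact mutation count, so
realized identity equals the target up to rounding.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design: 200
fixtures for the end-to-end suite, 80–150 aa sequences for clustering
oracles, motifs of length ≤ 3 over 3–5 letter alphabets for exhaustive
p-value enumeration. Degenerate inputs are defined: empty FASTA → empty list
with a warning; sequence shorter than a motif → no windows; an alignment
trimmed to zero columns → empty alignment with a warning; empty reference in
the metrics → error. Rounding of printed percentages is one-decimal
round-half-up, matching the house style of the published tables.

## Known limitations

- Absolute scanner scores are not guaranteed to match meme-suite FIMO's
  internal scaling; use real FIMO output when exact score parity matters.
- Greedy clustering can differ from CD-HIT near the identity threshold
  (exact alignment vs. word-filter heuristic).
- C-JID calls are read from a precomputed HMMER domtblout; no HMM is bundled.
- LRR repeat-level annotation, subclade assignment by phylogeny and tree
  inference are out of scope; the package prepares their inputs.
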