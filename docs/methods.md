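# Methods

This note records the models, parameter choices and numerical conventions
behind igr-scout, and what the synthetic benchmark does and does not show.

## The selection model

The pipeline's premise is statistical: in genomes of low overall %GC,
intergenic regions that act as transcription templates for structured
ncRNAs are on average longer and GC-richer than other IGRs, so they occupy
the upper-right quadrant of a (%GC, length) scatter. We formalize the
"region drawn around the known RNAs" as an axis-aligned quadrant
`{%GC ≥ g, length ≥ L}` rather than a free-form polygon: a quadrant has a
two-parameter corner, is trivially monotone, and makes the fit exactly
reproducible.

The corner is searched over the grid of observed known-point coordinates
plus (0, 0). A corner is *feasible* when it retains at least `coverage`
(default **0.90**) of the known-RNA IGRs; among feasible corners the fit
minimizes `|n_unknown_inside − n_known_inside|`, breaking ties toward the
larger %GC cut, then the larger length cut. The balance term encodes the
practice of drawing the region "large enough to admit roughly as many
unknown IGRs as known ones"; `balance_tol` is reported but never enforced,
because on real genomes the achievable balance depends on the genome, not
the method. Genomes with no annotated RNAs at all fall back to absolute
config thresholds (`fallback_gc_min` 50%, `fallback_len_min` 120 nt).

%GC counts G+C among unambiguous bases only; a sequence of ambiguity codes
has undefined %GC (NaN), and an empty sequence is a domain error.

## Coordinates and formats

Everything internal is 0-based half-open with strands `+`/`-`; GenBank and
GFF3 are converted at the boundary. Only CDS features bound IGRs: an
annotated RNA feature does not split an IGR, it marks any overlapping IGR
as `known_rna` — those IGRs anchor the selection fit and are then removed
from analysis, mirroring how known ncRNA representatives are censused but
not re-investigated. "other" features never break an IGR. On circular
replicons the gap between the last and first CDS wraps the origin and is
stored with `end > len(sequence)`.

Motif alignments are exchanged as Stockholm 1.0 with `#=GC SS_cons`,
per-column consensus lines (`#=GC cons`, `#=GC conss` with conservation
digits 3/2/1/0), and `#=GS ... DE` tags carrying genome id and strand; a
freshly read file rewrites byte-identically. The writer is purpose-built
because the extra `#=GC`/`#=GS` vocabulary is not covered by generic
alignment writers.

## Coding filter

The protein screen is deliberately database-free: all maximal ORFs in six
frames under the bacterial code (starts ATG/GTG/TTG, stops TAA/TAG/TGA;
codons containing N are neither), flagging IGRs whose longest complete ORF
reaches `min_codons` (default **50**). The ORF interval includes the stop
codon and `n_codons` counts it. A homology search is strictly better
evidence, so an adapter (`ExternalProteinSearch`, FASTA in → TSV of hits at
e ≤ 1e-5) overrides the heuristic when supplied.

## Homolog grouping and alignment

Cross-species homologs are found with strand-aware k-mer containment
(`|A∩B| / min(|A|,|B|)`, max over strands) at **k = 6** and single-linkage
threshold **0.35** — chosen so substitution-only homologs at ≤ 25%
divergence link (at least through the family ancestor) while unrelated
high-GC sequence stays below ~0.1. Groups are deterministic: ids and
ordering follow the lexicographically smallest member.

Each group is aligned center-star around the member with the highest total
similarity: every member is globally aligned to the seed (match +2,
mismatch −1, gap open −4, extend −1; a gap of length ℓ costs 4 + (ℓ−1)) and
the pairwise gap patterns are merged by taking the maximum insertion length
between consecutive seed positions. This is a desk-scale substitute for
iterative covariance-model search; `ExternalHomologySearch` marks where
such an engine plugs in.

**Orientation.** A motif's sense strand is decided in two steps. Members
are first flipped toward the seed; the group as a whole is flipped when that
places ≥ 75% of members immediately upstream (≤ 100 nt, same strand) of a
gene — the 5′-UTR convention. For motifs without such a gene anchor, the
consensus is folded in both readings and the one whose structure carries
more covarying pairs (then the higher fold score) wins. The second step
matters because covariation is not mirror-symmetric: a compensatory G·U
swap reads as the non-pairing C·A antisense, so the sense reading of a
structured RNA is measurably better supported.

## Conservation, covariation and folding

Per column (non-gap rows, T→U): conservation levels n97/n90/n75 at
dominant-nucleotide frequencies 97/90/75%, `present` at ≥ 50%, else
`variable`; columns gapped in > 50% of rows are `variable` outright.

A column pair is graded over rows non-gap at both positions, against the
canonical set {AU, UA, GC, CG, GU, UG}: *covarying* requires ≥ 2 distinct
canonical pair types and ≥ 97% canonical rows; *compatible* requires ≥ 75%
canonical; fewer than 3 usable rows is always *unsupported*. The 0.97/0.75
thresholds and the ≥ 2-type requirement follow the conventions of
consensus-diagram tools; all are configurable.

The consensus structure maximizes pair score by a Nussinov-style DP over
columns: covarying pairs score **3**, compatible **1**, unsupported pairs
are forbidden, every pair spans > `min_loop` (**3**) columns, and columns
gapped in > 50% of rows never pair (three inserted rows are not evidence
for a consensus helix). Traceback is deterministic (pair the interval ends
on ties, then leave the right end unpaired, then the smallest split point).
No pseudoknots are folded; when two hairpin loops are reverse-complementary
over ≥ 4 nt a `pseudoknot_note` flag is raised, nothing more.

Helices are parsed bulge-tolerantly: consecutive pairs separated by ≤ 2
unpaired nucleotides (summed over both strands) belong to one stem, the
usual reading in which a 1-nt bulge does not split a helix. `n_stems`
counts helices of ≥ 3 pairs.

## Feature detectors

*Intrinsic terminator*: the 3′-most hairpin of the fold must have ≥ 6
stacked pairs (bulge-tolerant), a loop of 3–10 nt, and a run of ≥ 5 U among
the 8 positions after the stem's 3′ end, of which the first two must be U.
The 8-nt window with a mandatory UU start is standard intrinsic-terminator
practice around the bare "five or more U" rule. A sequence-only scan mode
anchors at qualifying U-tails and grows a complementary stem behind them —
used when no alignment fold is available.

*Shine-Dalgarno*: the longest contiguous substring of AGGAGG (≥ 4 nt)
within 4–15 nt upstream of the downstream gene's start codon,
strand-aware; `overlaps_structure` is set when any SD position projects
onto a paired column, the signature of an expression platform that
sequesters the ribosome-binding site.

*Upstream ORF*: the earliest alignment column at which ≥ 80% of rows read
AUG at their ungapped position and ≥ 80% of those rows reach an in-frame
stop before the row end. Alignments of fewer than 3 rows return nothing —
a conservation claim needs the same evidential floor as covariation.

## Classification

The rule engine is a fixed precedence list (selfish elements before
cis-regulatory, uORF before riboswitch — the order that reproduces the
known reclassification of uORF motifs originally mistaken for
riboswitches): MRSC (median ≥ 3 copies/genome, or mixed orientation with
transposase-like context), uORFC (conserved uORF, ≥ 75% 5′-UTR-positioned),
sORF (conserved start/stop, not UTR-positioned), TSC (exactly one stem +
terminator + ≥ 1 covarying pair), RLC/PBC/RTC (UTR-positioned with
ribosomal-protein / nucleic-acid-binding / temperature context), SRC
(UTR-positioned metabolic/transporter context, ≥ 3 stems, ≥ 3 covarying
pairs, ≥ 75% context agreement, and a terminator or sequestered SD), WRC
(a weaker version: ≥ 2 stems, ≥ 1 covarying pair), sRNA (< 50%
UTR-positioned, ≤ 1 stem), then ranks by representation: LRC (< 5 unique),
MRC (< 20), HRC (≥ 20 unique with ≥ 3 covarying pairs and ≥ 10 columns at
≥ 90% conservation), else Unnamed. The SRC/WRC boundary is inherently a
judgement call; these thresholds are one consistent operationalization and
every one is configurable. "5′-UTR-positioned" uses a 100-nt maximum gap
between motif and gene start, a number the surveys leave implicit
("immediately upstream").

The census table mirrors the published row order; its "Other" row exists
only for manual override labels — no rule produces it. "Known ORFs" counts
both annotation overlaps and coding-filter removals.

## The synthetic benchmark ("table1-bench")

Defaults: 20 species; background %GC 35; 120 genes/genome of 300–2400 nt;
background IGR lengths log-normal (μ = 4.0, σ = 0.5, clipped 20–400 nt);
8 annotated known-RNA anchor IGRs/genome (100–180 nt at 44–54 %GC); per
genome 15 coding-IGR decoys (61-codon unannotated ORFs at ~50 %GC) and 15
high-GC unstructured decoys (130–250 nt at 50–58 %GC); and five planted
motif families, one per category flavour: a 3-stem riboswitch-like family
with an SD sequestered in its last stem (SRC), a conserved-uORF family
(uORFC), a single-hairpin + U6-tail family (TSC), a 4-copies-per-genome
mobile element (MRSC) and a 2-stem protein-binding leader (PBC). Families
default to 55 %GC, conserved fraction 0.55 of unpaired columns,
substitution rate 0.08 per unconserved column per homolog, and pair
covariation rate 0.3 per pair per homolog (compensatory swaps drawn
uniformly from the 5 other canonical pairs).

Three generator choices deserve their rationale. Planted motifs occupy
their **entire IGR** (plus a ≤ 12 nt gap to the host gene for 5′-UTR
placements) — real structured-RNA IGRs are often fully occupied by the
motif, and it means homologs are homologous end to end, so the fixed-cost
center-star alignment stays in register. Ancestor stems draw uniformly
from the four Watson-Crick pairs rather than being GC-skewed: quasi-two-
letter stem arms make shifted self-alignments nearly as good as the true
register under the +2/−1/−4/−1 scoring, and at the 0.97 covariation
threshold a single misregistered row in twenty destroys the evidence for
every pair in a stem. The terminator family keeps its unpaired columns
pyrimidine (C/U): flanks with no purines cannot base-pair with the U-tail
or with each other, so the family's fold has exactly the one planted stem —
the property its category definition requires.

What the benchmark does *not* emulate: indels between homologs (the
substitution-only model is what makes exact truth-mapping of columns
possible), phylogenetic correlation between species (homologs are i.i.d.
draws from the ancestor), promoter/terminator annotation noise, plasmids,
and any realistic database-scale homology search. Passing the benchmark
therefore shows the pipeline's machinery is correct and internally
consistent under its stated model — not that its defaults are tuned for any
particular real clade.

## Problem sizes

The shipped benchmark (20 genomes ≈ 3.5 Mb total, ~2 300 IGRs, ~760
candidates, ~270 motifs) runs the full pipeline in a few seconds on one
CPU; the oracle-equivalence checks (corner enumeration, exhaustive folding
at widths ≤ 18, Gotoh alignment on pairs ≤ 60 nt, stem+tail enumeration on
1 000 random 80-mers, codon-pair enumeration on 500 random 200-mers) were
sized to exercise every code path while keeping the whole suite under a
minute.

## Known limitations

Base-pair maximization with two score levels is not an energy model: it
recovers covariation-supported stems but over-pairs conserved complementary
columns, which is why category rules lean on covariation counts rather
than raw structure. Single-linkage k-mer clustering cannot separate
families that share low-complexity composition. The SD detector assumes the
AGGAGG consensus and misses non-canonical ribosome-binding sites. The
classification of real motifs will often require the manual curation steps
this package intentionally automates away at desk scale.
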