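# Methods

This note records the models, rules and numerical conventions the package
implements, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the design choices made where the design was
genuinely open.

## Full-length classification

A transcript is classified against four criteria, tested in a fixed order
so that every failure is attributed to exactly one gate: significant
translated-search hit → conserved start codon → complete ORF with stop →
poly(A) tail. The first failing gate names the status; a transcript that
passes all four but has a 3′UTR shorter than `min_utr3` (default 10 nt)
with no canonical PAS hexamer in the upstream scan window is downgraded to
`internal_polyA_suspect` — the signature of oligo-dT priming at an internal
A-rich stretch rather than the true 3′ end. The 10-nt cutoff is a package
default (configurable); the phenomenon it captures is a minimal 3′UTR
before the tail.

**Best hit.** Among hits sharing the query, the minimum E-value strictly
below `e_cut` (default 1e-5) wins; ties break by higher percent identity,
then lexicographic subject id, making the pipeline deterministic.

**Conserved start.** Within the best hit's reading frame the accepted ATG
may lie (a) upstream of the alignment start, provided no in-frame stop
codon intervenes (a stop there would preclude that ATG initiating the
aligned protein — the rule is biologically forced though rarely stated),
(b) at the alignment start when the alignment begins at the reference's
first residue, or (c) at an aligned codon mapping to reference residue
≤ 10 (inclusive). When several positions qualify, the 5′-most wins,
maximizing the ORF. For records ≤ 200 nt an exhaustive scan over every
in-frame codon position reproduces the search exactly (oracle test).

**Minus-strand hits** (qstart > qend in the tabular input) are skipped with
a warning rather than reverse-complemented: directional, 5′→3′ oriented
cDNA clones are assumed.

## ORF and UTR conventions

The ORF runs from the accepted ATG through the first in-frame stop codon,
*stop included*, so `orf_len` is a multiple of 3; `utr5_len + orf_len +
utr3_len` tiles the poly(A)-trimmed length exactly. The 3′UTR is measured
to the tail start — excluding the homopolymer is the only definition stable
under tail-length variation. Histograms use left-closed bins `[k·w,
(k+1)·w)` with default widths 300 bp (ORF) and 100 bp (3′UTR); reported
means are rounded to the nearest bp.

Coordinates are 1-based inclusive in every file and report and 0-based
half-open internally; the conversion lives entirely in `seq_io`. Sequences
are stored as DNA; PAS hexamers and the Kozak consensus are converted T→U
only at presentation time.

## Poly(A) tails and polyadenylation signals

The tail detector accepts the longest 3′-terminal segment of length
≥ `min_tail` (10) whose A-fraction is ≥ 1 − `max_mismatch_frac` (0.9) and
which *begins and ends with A* — mismatched bases are interior, so the
reported boundary never sits on a non-A base. This boundary convention is
what makes a sequence like `ACGT` + 20×A yield a 20-nt tail rather than a
22-nt one that would swallow `GT` on a fractional technicality.

PAS calling screens the ≤ 35-nt window ending immediately before the tail:
AAUAAA anywhere in the window takes precedence over AUUAAA, and the 3′-most
occurrence is reported because the signal's function is position-dependent.
`offset` counts the bases strictly between hexamer end and tail start.
Transcripts with neither canonical signal feed hexamer discovery: with
pattern length fixed at 6, no wildcards and per-transcript presence
counting, pattern discovery degenerates to exact k-mer counting, proved
equivalent to a sliding-window dictionary in the tests. Hexamers supported
by ≥ `min_support` transcripts (default 30) are reported, sorted by count
then lexicographically. Discovery runs on the same 35-nt windows as the
canonical screen (a `scope` switch to whole 3′UTRs would be a two-line
change; the window is the default because the signal is positional).

## Kozak profile

The 8-mer spanning −4..+4 around the initiator ATG is extracted for every
annotated transcript with ≥ 4 nt of 5′UTR; shorter UTRs and contexts
containing N are excluded and counted, so `n_contexts + excluded` equals
the number of annotated transcripts. Information content per position is
`R_i = 2 − H_i` bits with no small-sample correction — only the consensus
string is a decision surface, and the correction (≈ 3/(2·ln2·n)) is
negligible at the cohort sizes profiled. Consensus ties break in fixed
A>C>G>T order and are flagged.

## UTR motif engine

Descriptors specify IUPAC core segments, optional (min, max) spacers
between segments, and flanking stem arms that must be reverse-complementary
within a mismatch budget; `stem_len = 0` with a single core reduces exactly
to degenerate string matching (regex oracle test). The shipped IRE, SECIS
and ADH_DRE descriptors are deliberately simplified, synthetic stand-ins
capturing approximate published geometry (IRE: bulged 5′ C, 5-bp stem,
CAGUGH loop; SECIS: AUGA…AAR…GA cores with 15–40/10–30 spacers, 7-bp stem,
≤ 2 mismatches; ADH_DRE: plain degenerate consensus). The engine — not the
descriptor library — is the tested artifact; no thermodynamic folding is
attempted.

## Cross-species comparison

Species pairs share a gene identity when their best hits name the same
subject; the lowest-E-value transcript represents each species. Percent
identity uses Needleman–Wunsch with match +1, mismatch −1, linear gap −2
and free terminal gaps; identity is matches over alignment columns
excluding columns lying in a terminal gap of either sequence, rounded
half-up to an integer (97.5 → 98). The scoring scheme is a package default
echoed in the report header, not a claim about how any particular study
computed similarity; with conserved termini and no indels the optimal
alignment is gapless and identity equals Hamming identity exactly (tested
against generator truth).

## Distances, trees, and the paralog rule

Alignment columns containing any gap are removed (complete deletion) before
distances; p-distance is the differing-site proportion and the Poisson
multiple-hit correction is `d = −ln(1 − p)`, defined for p < 1 (p ≥ 1
raises a saturation error; in verdicts it yields `ambiguous`). Amino-acid
input is the natural home of the Poisson correction but the computation is
alphabet-agnostic and the simulator exercises it on nucleotides.

Neighbor joining follows the canonical agglomerative algorithm: join the
pair minimizing `Q_ij = (n−2)·d_ij − r_i − r_j`, with the standard branch
length and distance-reduction formulas. Exact Q ties break by the
lexicographic order of the joined pair's smallest leaf names. One numerical
subtlety: Q computed by vectorized subtraction can differ between (i,j) and
(j,i) by one ulp, so Q is symmetrized with `min(Q, Qᵀ)` and the argmin
restricted to the upper triangle — otherwise the tie set can be empty on
exactly-additive input. Negative NJ branch lengths are retained and
flagged. On additive matrices the generating tree is recovered exactly
(tree metric reproduced to < 1e-9 over random 6-taxon instances).

Bootstrap support resamples alignment columns with replacement (default
1,000 replicates) and reports, per internal edge, the percentage of
replicate trees containing its bipartition. For paralog/allele triples a
3-leaf unrooted tree has a unique topology, so bipartition support is
undefined; support is instead computed on the operative statistic — the
percentage of replicates in which the distance inequality holds. Because
the Poisson correction is monotone, the inequality is evaluated on p
directly, which also makes replicates immune to saturation. The verdict is
`paralogs` iff `min(d(X1,Y), d(X2,Y)) < d(X1,X2)` with support ≥ 70%
(default), `allelic_variants` for the reverse inequality with support, and
`ambiguous` otherwise. Unequal-length triples are aligned first, anchored
on X1 (insertions relative to X1 dropped; complete deletion then removes
gapped columns).

## Synthetic data: what it emulates, and what it does not

Transcripts are assembled as 5′UTR + ORF + 3′UTR + tail with lognormal
length models: ORF mean ≈ 689 bp clipped to [114, 1416] and rounded to
codons, 3′UTR mean ≈ 243 bp (floor 45 nt so a PAS window always fits),
5′UTR mean ≈ 30 nt with a 5% fraction shorter than 4 nt (Kozak context
unavailable), tails uniform on 12–45 nt. PAS classes default to 0.55
AAUAAA / 0.26 AUUAAA with the remainder drawn from ten common variant
hexamers weighted by their observed prevalence. The Kozak
position-frequency model has modal string AAAC·ATG·G with a purine-biased
−3. Ortholog copies diverge at 0.015 (ORF) and 0.05 (UTR) substitutions
per site; 416 gene identities are shared between species by default.
Triples default to 100 allelic (0.002 within / 0.02 cross) and 100
paralogous (0.08 within / 0.02 cross) at 600 nt.

Construction guarantees make the truth table *exact*, not merely likely:
ORF interiors use sense codons only; 5′UTRs are scrubbed of in-frame ATGs;
the 47 nt upstream of the tail are scrubbed of unintended canonical
hexamers (codon-safely inside ORFs); the planted hexamer is separated from
the tail by ≥ 8 non-A bases so tail detection cannot absorb it; mutation of
ortholog copies protects the start, stop, and planted signal and never
creates an in-frame stop (a codon that would become a stop reverts).
Defect decoys — missing tail, missing stop (reading frame open through a
sense-codon 3′UTR into the tail), internal poly(A) (3′UTR < 10 nt of
non-A bases, no PAS), missing conserved start (hit starting at reference
residue 15), and no significant hit — are planted among species-specific
transcripts only, keeping ortholog-pair truth clean.

The generator does **not** emulate realistic codon usage or GC content,
expression levels, sequencing error, alternative polyadenylation,
heterogeneous divergence along a sequence, or indel-rich orthologs.
Passing closed-loop tests therefore demonstrates the pipeline's rules are
implemented exactly as specified and are mutually consistent — not that
the defaults match any real transcriptome's messiness; on real data the
boundary cases (A-rich UTR ends, weak PAS, truncated 5′ ends) will land on
the configurable thresholds above. With the default single-rate ORF
divergence the ortholog identity distribution is more concentrated
(~90–96% of pairs at 98–99%) than a real two-species cohort, where a
mixture of divergence histories spreads the tail.

## Problem sizes

The test suite and `scripts/acceptance.py` run the generator at 1,000
transcripts per species (2,000 total), 416 shared identities, 500 discovery
windows, 1,000 Kozak contexts, 100 random additive 6-taxon matrices, and
200 triples at 1,000 bootstrap replicates — sizes chosen to match the
cohort scale the method is meant for while keeping a full run of suite plus
script under a minute on one CPU.
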