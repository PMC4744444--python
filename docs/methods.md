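# Methods

## Scope and model

tirmap resolves the junction between a transposon construct and its genomic
insertion site in a single composite query sequence, reporting the terminal
genomic nucleotide (TGN) as the insertion coordinate. It assumes
Sanger-grade junction reads (hundreds of nucleotides, low error rate, but
possibly carrying SNPs/small indels near the junction), references small
enough to hold in memory (bacterial to invertebrate genomes, or individual
chromosomes), and constructs bounded by terminal inverted repeats (TIRs)
whose termini are reference coordinates 1 and *L*. It is not an NGS
split-read caller: no read pairing, no TSD-consensus building, no depth
model.

All coordinates are 1-based and inclusive on the forward strand of each
reference. Reverse-strand matches are found by scanning the
reverse-complemented query, and converted back to forward-query coordinates
when partial alignments are emitted, so the index stores one strand only.

## Pipeline

1. **Encoding and indexing.** Bases pack 2 bits each (A=0, C=1, G=2, T=3).
   Every reference is indexed by its overlapping decamers (k=10, step 1):
   a table from the 20-bit decamer key to ascending start positions. No
   frequency cutoff is applied to decamer buckets — filtering frequent
   k-mers is precisely what makes hash-based mappers miss insertions in
   low-complexity flanks, so it defaults off (a ceiling is configurable).
   Ambiguous bases have no slot in the 2-bit code: they are carried in a
   validity mask, decamers touching them are skipped at both index and scan
   time, and in the dynamic-programming stages they can only mismatch.

2. **Seeding.** Query decamers are looked up across all references and both
   strands; hits sharing (reference, strand, diagonal) whose query ranges
   overlap or abut merge into gap-free association intervals. "Adjacent"
   deliberately means same-diagonal only; joining across diagonals (i.e.
   across indels) is deferred to the MEI/SW2 stages so that association
   intervals stay literal exact matches (an invariant the tests assert by
   string comparison).

3. **SW1 extension.** Both margins extend outward one position at a time.
   The score of a gliding window — the up-to-4 most recently entered
   positions, match +2 / mismatch −1 — must stay at or above the window
   threshold (default 0); when it drops the margin stops and trailing
   mismatch columns are retracted, so an extended interval always ends on
   a match and never shrinks below its seed. At these defaults a window
   tolerates up to two mismatches among four entering positions, which
   carries the extension across isolated SNPs while halting within a few
   steps in unrelated sequence. The rule is the simplest one consistent
   with the published description of the expansion step (the original
   scoring formula is in an unavailable supplement); raising the threshold
   provably never lengthens an interval, which the property tests check.
   Extension is gap-free by design.

4. **MEI merging.** Extended intervals on one (reference, strand) merge
   when their query ranges overlap or abut and their diagonals differ by at
   most `max_diagonal_drift` (default 15 nt — generous for the ≤3-nt indels
   the robustness grid models, small enough not to fuse unrelated hits).

5. **SW2.** Each MEI's query fragment is aligned to its reference window
   (padded by the drift on both sides) with an affine-gap local
   Smith–Waterman: match +2, mismatch −1, gap of length k costs
   `gap_open + k·gap_extend` = 3 + k. The kernel is a numba-jitted Gotoh
   dynamic program with deterministic tie-breaking: at equal cell score,
   stop (shorter local alignment) beats diagonal beats gap-in-reference
   beats gap-in-query, and the earliest best cell in row-major order ends
   the traceback. The tests verify score equality against an independent
   cubic-time oracle that enumerates every gap length. The resulting
   partial alignment (PA) is genomic (GPA) or transposon (TPA) by the
   namespace of its reference. Its *nucleus* runs from the first column of
   the leftmost run of ≥10 consecutive match columns to the last column of
   the rightmost such run; PAs without such a run have no nucleus and are
   treated as all-tail in joining disputes.

6. **Chaining and joining.** Ranked PAs (at most `max_candidates`, default
   30, scoring at least the preset's floor) are chained left-to-right;
   neighbours may overlap (if resolvable) or leave at most
   `max_unaligned_gap` (default 20) query nt unaligned. Overlap resolution:
   a tail may not invade the partner's nucleus; residual tail–tail overlap
   splits at the query position maximising the summed kept-column scores
   (ties leftmost); nucleus–nucleus overlap is allowed up to 40 % of either
   nucleus and the shared columns go to the TPA (same-kind disputes: to the
   higher score); beyond 40 % the pair refuses to join. Only segments of at
   least `min_chain_segment` (default 20) query nt may sit inside a
   multi-segment chain: without that floor, ~10-nt chance matches get
   spliced in purely to manufacture extra bonus-carrying borders.
   Single-segment results are always kept regardless of length.

7. **Gap assignment and SW3.** Unaligned query columns between two chained
   segments are assigned to the side whose border is *not* pinned at a TIR
   terminus (at a transposon–genome border with the TPA at a terminus, the
   gap goes entirely to the genomic side; if neither or both sides are
   pinned, it splits at the midpoint). Each trimmed/expanded fragment is
   then realigned against its reference window elongated by the next 10
   reference nucleotides on each side, clamped at the reference ends
   (SW3). This is the accuracy mechanism of the whole tool: a TGN sitting
   beyond a junction-proximal SNP re-enters as a terminal match (prefix
   match−mismatch scores +1 > 0), and a TGN beyond a deletion at TSD
   position ≥4 re-enters behind an affine gap (e.g. 4 matches − gap =
   +4 > 0). Mutations at TSD positions 2–3 leave too little terminal anchor
   to pay for the gap, which is exactly the sensitivity gradient the
   simulation grid measures.

8. **Scoring, bonus, ranking.** A final alignment scores the sum of its
   segments' SW scores; when enabled, a cumulative bonus of +500 is added
   per transposon–genome border (a two-border iPCR-style read gets +1000),
   never to transposon–transposon or genomic–genomic borders. Chains are
   ranked by total score, then coverage, then a deterministic signature.
   The mapper warns when enabling the bonus changed the top-ranked chain —
   the standing advice for suspected self-insertions is to rank without it,
   since constructs carrying genome-derived markers (the simulator's world
   includes one on purpose) otherwise surface a false genomic insertion in
   the marker's source locus, outscoring the true self-insertion by
   exactly the bonus.

9. **Calling.** At the first transposon–genome border whose transposon
   side ends at construct coordinate 1 or *L*, the TGN is the reference
   coordinate of the first genomic column after the border; shared
   (overlapped) columns were already assigned to the transposon, so when a
   k-nt motif is shared between TIR terminus and genomic flank
   (restriction-site overlaps) the reported TGN is always the coordinate
   *after* the motif. Borders whose transposon side is not at a terminus
   produce a low-confidence call (reported, never suppressed). A border
   between two transposon references with one side at a terminus is a
   self-insertion, reported with the transposon-internal coordinate.
   Orientation: type I when the transposon and genomic segments align on
   the same strand sense, type II otherwise; the sequenced end follows the
   terminus identity (1 → 5′, *L* → 3′). Both are invariant under
   reverse-complementing the query.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `match` / `mismatch_penalty` | 2 / 1 | per-column scores, all stages |
| `gap_open` / `gap_extend` | 3 / 1 | affine gap: length k costs 3 + k |
| `window_threshold` | 0 | SW1 4-nt gliding-window cutoff |
| `max_diagonal_drift` | 15 nt | EI→MEI diagonal tolerance and SW2 window pad |
| `nucleus_min_run` | 10 | consecutive matches defining a nucleus |
| `nucleus_max_overlap_frac` | 0.40 | joinable nucleus–nucleus overlap limit |
| `bonus` / `bonus_enabled` | 500 / off | per transposon–genome border |
| `preset` | `short` | minimum reportable PA score: short 20, long 40 |
| `max_candidates` | 30 | PAs entering chain enumeration |
| `max_unaligned_gap` | 20 nt | query gap allowed between chained segments |
| `min_chain_segment` | 20 nt | shortest PA admissible inside a chain |

The `short` preset keeps the short genomic fragments that iPCR yields when
the restriction site falls close to the TIR; `long` raises the floor for
cleaner reports on long well-behaved reads. Every value is configurable via
`AlignmentParams`, YAML config or CLI flags; nothing is hard-coded.

## Synthetic data

`make_world(seed)` emulates the study conditions: a uniform-random 100-kb
genome, a 10-kb construct whose first and last 31 nt are reverse-complement
TIRs, an 8-nt TSD (the P-element value), and a 1.5-kb marker copied
verbatim from the genome into the construct interior to exercise the
self-insertion/bonus caveat. Junction reads default to a 160-nt genomic
fragment plus a 120-nt transposon fragment (Sanger-scale); layouts cover
TIR+genome, genome+TIR, two-border TIR+genome+TIR (the second construct
fragment entering at an internal restriction-site cut, as in iPCR
amplicons), both orientations, and construct-into-own-marker self-insertion
reads whose target fragment deliberately crosses the marker edge. The
mutation grid plants transversion SNPs (A↔T, C↔G — the fixed choice, since
the published grid does not state whether transversions were randomised),
deletions and insertions at TSD positions 2–6 (singles, the 3–4 double, the
3–4–5 triple); position 1 — the TGN itself — is never mutated. Insertion
mutations use random bases by default, with a `use_n` switch for literal
Ns, so robustness to indels is measured separately from ambiguity handling.
All randomness flows from explicit seeds; batches of 25 reads per condition
keep the full grid (16 conditions × 25 reads) around a minute on one CPU.

What the simulator does **not** model: chromatogram noise profiles, quality
trimming, natural repeat families, polymorphism between strains, GC bias.
Passing the synthetic benchmarks therefore demonstrates the joining/SW3
mechanics and coordinate bookkeeping, not performance on any particular
real genome; real-genome behaviour additionally depends on repeat content
and annotation quality.

## Numerical and degenerate-input choices

Determinism is end-to-end: fixed tie-breaks in the DP, stable sorts
everywhere, chain deduplication by segment signature, all RNG through
seeded `numpy` generators. Queries shorter than 10 nt, or sharing no
decamer with any reference, are reported unmappable (an output, not an
error). Chain enumeration is capped (4000 expansions, ≤6 segments) —
far beyond what junction reads produce, but a hard bound nonetheless.
N-containing decamers never seed; N columns always mismatch. Persisted
indexes are a versioned JSON container (packed payload, ambiguous
positions, decamer table, annotations) written atomically; bit-layout
compatibility with any external index format is a non-goal.

## Known limitations

Natural-transposon multi-copy hits are reported per matching copy and
cannot be disambiguated without orthogonal data (splinkerette PCR). The
mapping convention reports the TGN of the sequenced junction, so 5′ and 3′
reads of one TSD-duplicating insertion legitimately differ by TSD−1
(7 for an 8-nt TSD); consumers wanting a single canonical coordinate must
pick a convention on top. Deletions/insertions at TSD positions 2–3
frequently defeat recovery (terminal anchor too small to pay the gap
penalty) — the same gradient the published benchmarks show — and inserted
bases that extend an adjacent homopolymer can shift the optimum by a
column or two. Whole-mammalian-genome scale is out of scope.
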