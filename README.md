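# tirmap

**tirmap** maps artificial-transposon insertions — and transposon
self-insertions — at single-nucleotide accuracy from transposon–genome
junction sequences, the Sanger-length reads (~100–1000 nt) produced by
inverse PCR (iPCR), vectorette or splinkerette protocols in small- to
medium-scale insertional mutagenesis experiments (*Drosophila*
P-element screens being the classic case).

## The problem

A junction read is a composite: a fragment of the transposon construct
ending in a terminal inverted repeat (TIR), joined to the genomic flank of
the insertion. Mapping the insertion means finding the reference coordinate
of the **terminal genomic nucleotide (TGN)** — the genomic base immediately
adjacent to the TIR terminus. The standard recipe (trim the transposon tag,
then align the rest with a general-purpose aligner) breaks exactly where
precision matters most: a SNP, small indel or sequencing artifact sitting
2–6 nt from the junction ends up at the *edge* of the trimmed query, local
aligners drop the terminal bases, and a nucleotide preceding the mutation
gets reported as the insertion site. Self-insertions (a construct hopping
into another copy of itself, e.g. into its own *mini-white*-style marker)
are invisible to tag-trimming mappers altogether.

## The method

tirmap keeps the whole composite read and aligns it against **two reference
namespaces** at once — genomic sequences and transposon constructs:

1. **Seeding.** Both strands of the query are scanned with overlapping
   decamers (10-mers, step 1) against a hash index of every reference;
   matching decamers on one diagonal merge into exact *association
   intervals*.
2. **SW1 — gliding-window extension.** Each interval is extended outward
   with a 4-nt window score (match +2, mismatch −1, threshold 0), which
   strides over isolated SNPs; overlapping extended intervals merge (MEIs).
3. **SW2 — full local alignment.** Each MEI is realigned by affine-gap
   Smith–Waterman (gap of length *k* costs 3 + *k*), giving scored *partial
   alignments* (PAs), genomic (GPA) or transposon (TPA). Each PA has a
   *nucleus*: the span between its outermost runs of ≥10 consecutive
   matches.
4. **Joining + SW3.** TPAs and GPAs are chained to cover the query. At a
   contested border a nucleus beats a tail; nuclei may overlap at most 40 %
   of either, and shared columns always go to the transposon. Every trimmed
   fragment is then **realigned against its reference window elongated by
   the next 10 reference nucleotides on each side (SW3)** — this is what
   lets a TGN hiding beyond a junction-proximal SNP or indel re-enter the
   final alignment as a terminal match.
5. **Calling.** At a transposon–genome border whose transposon side ends at
   a TIR terminus (construct coordinate 1 or *L*), the TGN is the first
   genomic coordinate after the border. Borders between two transposon
   references are called self-insertions. An optional **bonus of +500 per
   transposon–genome border** helps rank true insertions in noisy reads —
   and must be left off when hunting self-insertions, because markers
   cloned from the genome make the bonus promote a false genomic call.

Because the insertion machinery duplicates an 8-nt target site (TSD) for
P-element-class constructs, the 5′- and 3′-end reads of one insertion
legitimately report two TGNs separated by exactly 7 positions; tirmap
reports whichever junction was sequenced, plus the orientation (type I/II)
and sequenced end decoded from the junction geometry.

A bundled simulator (`tirmap simulate …`) builds seeded synthetic genomes,
TIR-bearing constructs with a genome-derived marker, junction reads with
configurable TSD, and the grid of junction-proximal mutations (SNPs,
deletions, insertions at TSD positions 2–6) used to benchmark robustness.

## Worked example

```bash
tirmap simulate make-world --seed 7 --out-dir world
tirmap simulate reads --seed 7 --n 2 --out-fasta reads.fasta --out-truth truth.tsv
tirmap map reads.fasta -g world/chrSim.fasta -t world/pSim.fasta \
       -a chrSim=world/chrSim.features.tsv --out-json calls.json
```

prints, for the first read:

```
## query tir_genome_type_I_three_prime_000 (280 nt)
call: genomic_insertion  ref=chrSim  TGN=32756  TIR_terminus=10000  orientation=type_I  end=three_prime  score=560
flanks: gene4 | gene5
# alignment 1: score=560 (SW 560), 2 segment(s)
  [TPA] pSim -> query 1..120 ref 9881..10000 score 240
  ...
  [GPA] chrSim -> query 121..280 ref 32756..32915 score 320
  ...
```

Read it as: the first 120 nt of the query align to the construct `pSim`
ending exactly at its 3′ TIR terminus (coordinate 10000), the remaining
160 nt align to the genome starting at coordinate **32756** — the TGN, i.e.
the reported insertion site (matching `truth.tsv` for this simulated
insertion), between flanking annotations `gene4` and `gene5`. The total
score 560 is the sum of the two segment alignment scores; no bonus was
requested. Lower-ranked alignments (e.g. the 31-nt match of the 3′ TIR to
the reverse strand of the 5′ TIR — inverted repeats guarantee it) are
listed below, score-ranked.

`calls.json` carries the same calls machine-readably (query id, call kind,
reference, TGN, TIR terminus, orientation, end, strand, score, bonus flag,
affected/flanking features).

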