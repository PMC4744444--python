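"""Synthetic mutagenesis worlds and the mapping-robustness harness.

The generator emulates a small insertional-mutagenesis study: a random
genome, a transposon-like construct bounded by terminal inverted repeats
(TIRs, reverse complements of each other) and carrying an internal genetic
marker copied verbatim from the genome (the classic marker-in-construct
situation that makes self-insertion calls ambiguous when the bonus is on),
plus junction reads of simulated insertions with an 8-nt target site
duplication (TSD).  Small-scale mutations — transversion SNPs, deletions,
insertions — are planted inside the TSD copy adjacent to the TIR at
positions 2..6 counted from the terminal genomic nucleotide (TGN), which
itself is never mutated: if the mapper overcomes the mutation it should
still report the TGN's coordinate.

The evaluation harness is black-box: it scores any mapper given a
``query id -> reported coordinate`` mapping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refdb import AnnotationTrack, Feature, ReferenceDatabase, reverse_complement

_BASES = np.array(list("ACGT"))
_TRANSVERSION = {"A": "T", "T": "A", "C": "G", "G": "C"}

SNP = "snp_transversion"
DELETION = "deletion"
INSERTION = "insertion"


@dataclass(frozen=True)
class MutationSpec:
    """A simulated small-scale mutation at stated TSD positions relative to
    the TGN (position 1, never touched)."""

    kind: str                      # snp_transversion | deletion | insertion
    positions: tuple[int, ...]     # consecutive, within 2..6

    def __post_init__(self) -> None:
        if self.kind not in (SNP, DELETION, INSERTION):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        p = self.positions
        if not p or len(p) > 3:
            raise ValueError("width must be 1, 2 or 3 consecutive positions")
        if any(x < 2 or x > 6 for x in p):
            raise ValueError("positions must lie in 2..6 (the TGN is never mutated)")
        if list(p) != list(range(p[0], p[0] + len(p))):
            raise ValueError("positions must be consecutive")

    @property
    def label(self) -> str:
        return f"{self.kind}@{','.join(map(str, self.positions))}"


def mutation_grid() -> list[MutationSpec]:
    """The full simulation grid: for each mutation kind, single positions
    2..6, the (3,4) double and the (3,4,5) triple."""
    specs = []
    for kind in (SNP, DELETION, INSERTION):
        for p in range(2, 7):
            specs.append(MutationSpec(kind, (p,)))
        specs.append(MutationSpec(kind, (3, 4)))
        specs.append(MutationSpec(kind, (3, 4, 5)))
    return specs


@dataclass
class JunctionRead:
    query_id: str
    sequence: str
    truth_coordinate: int          # the TGN's reference coordinate
    truth_reference: str
    sequenced_end: str             # five_prime | three_prime (construct terminus)
    orientation: str               # type_I | type_II
    layout: str                    # tir_genome | genome_tir | tir_genome_tir | self_insertion
    tgn_index: int                 # 0-based read index of the TGN base
    away_step: int                 # +1 / -1: direction of TSD positions 2..6
    mutation: MutationSpec | None = None
    insertion_site: int = 0        # first TSD coordinate of the simulated insertion


@dataclass
class SyntheticWorld:
    seed: int
    genome: str
    construct: str
    genome_name: str = "chrSim"
    construct_name: str = "pSim"
    tir_length: int = 31
    tsd_length: int = 8
    marker_span: tuple[int, int] = (0, 0)         # construct coords, 1-based
    marker_source: tuple[int, int] = (0, 0)       # genome coords, 1-based
    genes: list[Feature] = field(default_factory=list)

    def database(self) -> ReferenceDatabase:
        db = ReferenceDatabase()
        db.register(
            self.genome_name, self.genome, "genomic",
            AnnotationTrack(self.genome_name, list(self.genes)),
        )
        L = len(self.construct)
        t = self.tir_length
        feats = [
            Feature("TIR5", 1, t, "+", "TIR"),
            Feature("TIR3", L - t + 1, L, "-", "TIR"),
            Feature("marker", self.marker_span[0], self.marker_span[1], "+", "marker"),
        ]
        db.register(
            self.construct_name, self.construct, "transposon",
            AnnotationTrack(self.construct_name, feats),
        )
        return db

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit references as FASTA plus annotation TSVs."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, seq, ns in (
            (self.genome_name, self.genome, "genomic"),
            (self.construct_name, self.construct, "transposon"),
        ):
            p = out / f"{name}.fasta"
            SeqIO.write([SeqRecord(Seq(seq), id=name, description=ns)], p, "fasta")
            paths[name] = p
        ann = out / f"{self.genome_name}.features.tsv"
        with open(ann, "w") as fh:
            for f in self.genes:
                fh.write(f"{f.label}\t{f.start}\t{f.end}\t{f.strand}\t{f.kind}\n")
        paths["annotations"] = ann
        L, t = len(self.construct), self.tir_length
        cann = out / f"{self.construct_name}.features.tsv"
        with open(cann, "w") as fh:
            fh.write(f"TIR5\t1\t{t}\t+\tTIR\n")
            fh.write(f"TIR3\t{L - t + 1}\t{L}\t-\tTIR\n")
            fh.write(f"marker\t{self.marker_span[0]}\t{self.marker_span[1]}\t+\tmarker\n")
        paths["construct_annotations"] = cann
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_world(
    seed: int,
    genome_length: int = 100_000,
    construct_length: int = 10_000,
    tir_length: int = 31,
    tsd_length: int = 8,
    marker_length: int = 1_500,
    n_genes: int = 12,
) -> SyntheticWorld:
    """Build a reproducible synthetic study world from one seed."""
    if 2 * tir_length + marker_length >= construct_length:
        raise ValueError("TIRs plus marker do not fit in the construct")
    if marker_length + 200 >= genome_length:
        raise ValueError("marker longer than the genome allows")
    rng = np.random.default_rng(seed)
    genome = _random_seq(rng, genome_length)
    construct = list(_random_seq(rng, construct_length))
    tir = _random_seq(rng, tir_length)
    construct[:tir_length] = tir
    construct[-tir_length:] = reverse_complement(tir)
    # marker: an exact copy of a genomic segment, placed mid-construct
    src_start = int(rng.integers(genome_length // 2, genome_length - marker_length))
    marker = genome[src_start - 1 : src_start - 1 + marker_length]
    m_start = construct_length // 2
    construct[m_start : m_start + marker_length] = marker
    construct = "".join(construct)
    genes = []
    span = genome_length // n_genes
    for i in range(n_genes):
        g_start = i * span + int(rng.integers(1, span // 4))
        g_end = min(genome_length, g_start + int(rng.integers(span // 4, span // 2)))
        genes.append(Feature(f"gene{i + 1}", g_start, g_end, "+" if i % 2 else "-", "gene"))
    return SyntheticWorld(
        seed=seed,
        genome=genome,
        construct=construct,
        tir_length=tir_length,
        tsd_length=tsd_length,
        marker_span=(m_start + 1, m_start + marker_length),
        marker_source=(src_start, src_start + marker_length - 1),
        genes=genes,
    )


def _sample_sites(
    world: SyntheticWorld, n: int, rng: np.random.Generator, margin: int
) -> list[int]:
    """Distinct insertion sites (first TSD coordinate), clear of the genome
    ends and of the marker's genomic source so every site is unique."""
    lo = margin + 1
    hi = len(world.genome) - margin - world.tsd_length
    ban = range(world.marker_source[0] - margin, world.marker_source[1] + margin + 1)
    sites: set[int] = set()
    while len(sites) < n:
        s = int(rng.integers(lo, hi))
        if s not in ban:
            sites.add(s)
    return sorted(sites)


def make_junction_reads(
    world: SyntheticWorld,
    n: int,
    layout: str = "tir_genome",
    end: str | None = None,
    orientation: str = "type_I",
    seed: int = 0,
    genomic_length: int = 160,
    transposon_length: int = 120,
    second_fragment_length: int = 90,
) -> list[JunctionRead]:
    """Simulate ``n`` clean junction reads at distinct insertion sites.

    An insertion at site ``s`` duplicates the TSD ``genome[s..s+tsd-1]`` on
    both sides of the construct: the 5'-terminus junction read ends the
    genomic fragment at coordinate ``s+tsd-1`` and the 3'-terminus read
    starts it at ``s``, so paired reads report TGNs ``tsd-1`` apart.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    margin = genomic_length + world.tsd_length + 10
    sites = _sample_sites(world, n, rng, margin)
    reads = []
    for i, s in enumerate(sites):
        reads.append(
            _read_for_site(
                world, s, layout, end, orientation, i,
                genomic_length, transposon_length, second_fragment_length,
            )
        )
    return reads


def _read_for_site(
    world: SyntheticWorld,
    s: int,
    layout: str,
    end: str | None,
    orientation: str,
    idx: int,
    glen: int,
    tlen: int,
    tlen2: int,
) -> JunctionRead:
    g, c = world.genome, world.construct
    L, tsd = len(c), world.tsd_length
    inverted = orientation == "type_II"
    if layout == "genome_tir":
        end = end or "five_prime"
    elif layout in ("tir_genome", "tir_genome_tir"):
        end = end or "three_prime"
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if layout == "genome_tir":
        # genomic flank ends at the last base of the left TSD copy
        truth = s + tsd - 1
        gfrag = g[truth - glen : truth]
        tfrag = c[:tlen] if not inverted else reverse_complement(c[L - tlen :])
        seq = gfrag + tfrag
        tgn_index = glen - 1
        away = -1
        if inverted:
            end = "three_prime"
    else:
        truth = s
        gfrag = g[s - 1 : s - 1 + glen]
        tfrag = (
            c[L - tlen :] if not inverted else reverse_complement(c[:tlen])
        )
        if inverted:
            end = "five_prime"
        seq = tfrag + gfrag
        tgn_index = tlen
        away = +1
        if layout == "tir_genome_tir":
            # iPCR-style second construct fragment entering at an internal
            # restriction-site cut, well away from either terminus
            cut = world.marker_span[0] - tlen2 - 50
            seq = seq + c[cut - 1 : cut - 1 + tlen2]
    return JunctionRead(
        query_id=f"{layout}_{orientation}_{end}_{idx:03d}",
        sequence=seq,
        truth_coordinate=truth,
        truth_reference=world.genome_name,
        sequenced_end=end,
        orientation=orientation,
        layout=layout,
        tgn_index=tgn_index,
        away_step=away,
        insertion_site=s,
    )


def make_insertion_pair(
    world: SyntheticWorld,
    seed: int = 0,
    genomic_length: int = 160,
    transposon_length: int = 120,
) -> tuple[JunctionRead, JunctionRead]:
    """The 5'- and 3'-terminus junction reads of one simulated insertion
    (same site, both ends sequenced)."""
    rng = np.random.default_rng(seed)
    margin = genomic_length + world.tsd_length + 10
    s = _sample_sites(world, 1, rng, margin)[0]
    five = _read_for_site(
        world, s, "genome_tir", "five_prime", "type_I", 0,
        genomic_length, transposon_length, 0,
    )
    three = _read_for_site(
        world, s, "tir_genome", "three_prime", "type_I", 0,
        genomic_length, transposon_length, 0,
    )
    return five, three


def make_self_insertion_read(
    world: SyntheticWorld,
    seed: int = 0,
    fragment_length: int = 160,
    transposon_length: int = 120,
    marker_offset_from_end: int = 110,
) -> JunctionRead:
    """A construct-into-its-own-marker junction read.

    The target-side fragment starts inside the marker but runs past the
    marker's end into construct-only sequence, so the true (transposon-
    internal) alignment outscores the marker's genomic homolog by less than
    the bonus — the situation where an enabled bonus promotes the false
    genomic call.
    """
    c = world.construct
    L = len(c)
    m_start, m_end = world.marker_span
    target = m_end - marker_offset_from_end + 1   # construct coordinate of the TGN analogue
    if not (m_start <= target <= m_end):
        raise ValueError("marker_offset_from_end outside the marker")
    seq = c[L - transposon_length :] + c[target - 1 : target - 1 + fragment_length]
    return JunctionRead(
        query_id="self_insertion_000",
        sequence=seq,
        truth_coordinate=target,
        truth_reference=world.construct_name,
        sequenced_end="three_prime",
        orientation="type_I",
        layout="self_insertion",
        tgn_index=transposon_length,
        away_step=+1,
        insertion_site=target,
    )


def apply_mutation(
    read: JunctionRead,
    spec: MutationSpec,
    seed: int = 0,
    use_n: bool = False,
) -> JunctionRead:
    """Plant a small-scale mutation in the TSD copy adjacent to the TIR.

    Positions count from the TGN (position 1) sliding away from the TIR;
    the TGN base itself is never touched and the truth coordinate is
    unchanged.  SNPs are transversions (A<->T, C<->G); insertions insert
    random bases (or Ns with ``use_n=True``); deletions remove the stated
    positions.
    """
    rng = np.random.default_rng(seed)
    s = list(read.sequence)
    i = read.tgn_index
    step = read.away_step
    idx = [i + step * (p - 1) for p in spec.positions]
    if any(j < 0 or j >= len(s) for j in idx):
        raise ValueError("mutation positions fall outside the read")
    tgn_shift = 0
    if spec.kind == SNP:
        for j in idx:
            s[j] = _TRANSVERSION[s[j]]
    elif spec.kind == DELETION:
        for j in sorted(idx, reverse=True):
            del s[j]
        if step < 0:
            tgn_shift = -len(idx)
    else:  # insertion occupying the stated relative positions
        w = len(spec.positions)
        bases = "N" * w if use_n else _random_seq(rng, w)
        p_min = min(spec.positions)
        slot = i + p_min - 1 if step > 0 else i - (p_min - 2)
        s[slot:slot] = list(bases)
        if step < 0:
            tgn_shift = w
    return dataclasses.replace(
        read,
        sequence="".join(s),
        tgn_index=read.tgn_index + tgn_shift,
        mutation=spec,
        query_id=f"{read.query_id}|{spec.label}",
    )


def evaluate_recovery(
    reads: list[JunctionRead],
    reported: dict[str, int | None],
) -> pd.DataFrame:
    """Per (mutation kind, positions) recovery table.

    ``reported`` maps query id to the coordinate a mapper reported (None
    for unmapped).  The harness never inspects mapper internals, so any
    tool's output can be scored.
    """
    rows: dict[tuple[str, str], list[int]] = {}
    for r in reads:
        key = (
            (r.mutation.kind, ",".join(map(str, r.mutation.positions)))
            if r.mutation
            else ("clean", "-")
        )
        cell = rows.setdefault(key, [0, 0])
        cell[0] += 1
        if reported.get(r.query_id) == r.truth_coordinate:
            cell[1] += 1
    records = [
        {"kind": k, "positions": p, "n": v[0], "recovered": v[1],
         "fraction": v[1] / v[0]}
        for (k, p), v in sorted(rows.items())
    ]
    return pd.DataFrame.from_records(records)
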