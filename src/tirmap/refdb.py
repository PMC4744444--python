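"""Reference sequence database: 2-bit encoding, decamer hash indexing,
annotation tracks and persistence.

References live in two namespaces, ``genomic`` and ``transposon``.  Each
registered sequence is packed 2 bits per base (A=0, C=1, G=2, T=3) and
indexed by every overlapping decamer (10-mer, step 1), so a lookup of a
query decamer returns all of its 1-based start positions on the forward
("standard") strand.  Ambiguous bases (N and friends) have no slot in the
2-bit code: they are carried in a separate validity mask, decamers touching
them are omitted from the index, and they can only ever align as mismatches
in the dynamic-programming stages.

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

K = 10  # decamer length; fixed by design, see docs/methods.md

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = np.array(list("ACGT"))

# byte -> 2-bit code lookup (255 marks anything not in ACGTacgt)
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c
    _LUT[ord(_b.lower())] = _c

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

_POWERS = (4 ** np.arange(K - 1, -1, -1)).astype(np.int64)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved, N kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_base(b: str) -> int:
    """Map a single nucleotide letter to its 2-bit code (A=0, C=1, G=2, T=3).

    Case-insensitive.  Anything outside ACGT is rejected.
    """
    if len(b) != 1:
        raise ValueError(f"expected a single base, got {b!r}")
    code = _LUT[ord(b)]
    if code == 255:
        raise ValueError(f"illegal or ambiguous base {b!r} at position 1")
    return int(code)


def encode_sequence(seq: str, *, allow_ambiguous: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Encode a sequence into (codes, valid_mask) arrays.

    ``codes`` holds the 2-bit code per base (0 where ambiguous); ``valid``
    is False at ambiguous positions.  With ``allow_ambiguous=False`` the
    first offending base raises, naming its 1-based position.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    valid = codes != 255
    if not allow_ambiguous and not valid.all():
        pos = int(np.flatnonzero(~valid)[0])
        raise ValueError(
            f"illegal or ambiguous base {seq[pos]!r} at position {pos + 1}"
        )
    codes = np.where(valid, codes, 0).astype(np.uint8)
    return codes, valid


def decode_codes(codes: np.ndarray, valid: np.ndarray | None = None) -> str:
    out = _BASE[codes]
    if valid is not None:
        out = np.where(valid, out, "N")
    return "".join(out)


def pack_codes(codes: np.ndarray) -> bytes:
    """Pack 2-bit codes, 4 bases per byte, first base in the high bits."""
    n = len(codes)
    padded = np.zeros((n + 3) // 4 * 4, dtype=np.uint8)
    padded[:n] = codes
    padded = padded.reshape(-1, 4)
    return (
        (padded[:, 0] << 6) | (padded[:, 1] << 4) | (padded[:, 2] << 2) | padded[:, 3]
    ).astype(np.uint8).tobytes()


def unpack_codes(payload: bytes, length: int) -> np.ndarray:
    raw = np.frombuffer(payload, dtype=np.uint8)
    out = np.empty(len(raw) * 4, dtype=np.uint8)
    out[0::4] = (raw >> 6) & 3
    out[1::4] = (raw >> 4) & 3
    out[2::4] = (raw >> 2) & 3
    out[3::4] = raw & 3
    return out[:length]


def decamer_key(s: str) -> int:
    """Pack a 10-nt string into an integer in [0, 4**10), base-4, MSB first."""
    if len(s) != K:
        raise ValueError(f"decamer must be {K} nt, got {len(s)}")
    codes, valid = encode_sequence(s)
    if not valid.all():
        pos = int(np.flatnonzero(~valid)[0])
        raise ValueError(f"ambiguous base {s[pos]!r} at position {pos + 1}")
    return int(codes.astype(np.int64) @ _POWERS)


@dataclass(frozen=True)
class Feature:
    """One annotated feature on a reference (1-based inclusive span)."""

    label: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"  # gene | TIR | marker | natural_transposon


@dataclass
class AnnotationTrack:
    reference_name: str
    features: list[Feature] = field(default_factory=list)

    def validate(self, ref_length: int) -> None:
        for f in self.features:
            if not (1 <= f.start <= f.end <= ref_length):
                raise ValueError(
                    f"feature {f.label!r} span {f.start}..{f.end} outside "
                    f"reference {self.reference_name!r} (length {ref_length})"
                )

    def overlapping(self, coord: int) -> list[Feature]:
        return [f for f in self.features if f.start <= coord <= f.end]

    def flanking(self, coord: int) -> tuple[Feature | None, Feature | None]:
        """Nearest features strictly left / right of ``coord``."""
        left = [f for f in self.features if f.end < coord]
        right = [f for f in self.features if f.start > coord]
        left_f = max(left, key=lambda f: f.end) if left else None
        right_f = min(right, key=lambda f: f.start) if right else None
        return left_f, right_f


class EncodedReference:
    """A 2-bit packed reference sequence in one namespace.

    The namespace (genomic vs transposon) is fixed at registration and
    decides whether downstream partial alignments are GPAs or TPAs.
    """

    def __init__(self, name: str, namespace: str, sequence: str):
        if namespace not in ("genomic", "transposon"):
            raise ValueError(f"unknown namespace {namespace!r}")
        if not sequence:
            raise ValueError(f"empty sequence for reference {name!r}")
        self.name = name
        self._namespace = namespace
        codes, valid = encode_sequence(sequence)
        self.length = len(codes)
        self.packed = pack_codes(codes)
        self._codes = codes
        self._valid = valid
        self._decoded: str | None = None
        self.coordinate_origin = 1

    @property
    def namespace(self) -> str:
        return self._namespace

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @property
    def valid(self) -> np.ndarray:
        return self._valid

    def sequence(self, start: int = 1, end: int | None = None) -> str:
        """Decode the forward strand over the 1-based inclusive span."""
        if end is None:
            end = self.length
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"span {start}..{end} outside 1..{self.length}")
        if self._decoded is None:
            self._decoded = decode_codes(self._codes, self._valid)
        return self._decoded[start - 1 : end]


class DecamerIndex:
    """Hash table from 20-bit decamer key to ascending 1-based start positions.

    Every overlapping decamer of the reference (overlap 9, i.e. step 1) gets
    an entry; decamers containing an ambiguous base are omitted.
    """

    def __init__(self, ref: EncodedReference):
        if ref.length < K:
            raise ValueError(
                f"reference {ref.name!r} shorter than {K} nt cannot be indexed"
            )
        self.ref_name = ref.name
        self.namespace = ref.namespace
        self.k = K
        self.step = 1
        keys, starts = _window_keys(ref.codes, ref.valid)
        order = np.argsort(keys, kind="stable")
        keys_sorted = keys[order]
        starts_sorted = starts[order]
        uniq, first = np.unique(keys_sorted, return_index=True)
        bounds = np.append(first, len(keys_sorted))
        self.table: dict[int, np.ndarray] = {
            int(u): np.sort(starts_sorted[bounds[i] : bounds[i + 1]])
            for i, u in enumerate(uniq)
        }

    def lookup(self, key: int) -> np.ndarray:
        return self.table.get(key, np.empty(0, dtype=np.int64))

    def n_positions(self) -> int:
        return sum(len(v) for v in self.table.values())


def _window_keys(codes: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All decamer (key, 1-based start) pairs of a code array, skipping
    windows that contain an ambiguous base."""
    n = len(codes)
    if n < K:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), K)
    keys = win @ _POWERS
    ok = np.lib.stride_tricks.sliding_window_view(valid, K).all(axis=1)
    starts = np.arange(1, n - K + 2, dtype=np.int64)
    return keys[ok], starts[ok]


def query_window_keys(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Decamer keys of a query string: (keys, 1-based query starts)."""
    codes, valid = encode_sequence(seq)
    return _window_keys(codes, valid)


def build_index(ref: EncodedReference) -> DecamerIndex:
    return DecamerIndex(ref)


class ReferenceDatabase:
    """Registry of encoded references and their indexes and annotations."""

    def __init__(self) -> None:
        self._refs: dict[tuple[str, str], EncodedReference] = {}
        self._indexes: dict[tuple[str, str], DecamerIndex] = {}
        self._annotations: dict[tuple[str, str], AnnotationTrack] = {}

    def register(
        self,
        name: str,
        sequence: str,
        namespace: str,
        annotations: AnnotationTrack | None = None,
    ) -> EncodedReference:
        key = (namespace, name)
        if key in self._refs:
            raise ValueError(f"duplicate reference {name!r} in namespace {namespace!r}")
        ref = EncodedReference(name, namespace, sequence)
        if annotations is not None:
            annotations.validate(ref.length)
        self._refs[key] = ref
        self._indexes[key] = DecamerIndex(ref)
        if annotations is not None:
            self._annotations[key] = annotations
        return ref

    def remove(self, name: str, namespace: str) -> None:
        key = (namespace, name)
        if key not in self._refs:
            raise KeyError(f"no reference {name!r} in namespace {namespace!r}")
        del self._refs[key]
        del self._indexes[key]
        self._annotations.pop(key, None)

    def get(self, name: str, namespace: str) -> EncodedReference:
        return self._refs[(namespace, name)]

    def annotations_for(self, name: str, namespace: str) -> AnnotationTrack | None:
        return self._annotations.get((namespace, name))

    def references(self, namespace: str | None = None) -> Iterator[EncodedReference]:
        for (ns, _), ref in self._refs.items():
            if namespace is None or ns == namespace:
                yield ref

    def indexes(self, namespace: str | None = None) -> Iterator[DecamerIndex]:
        for (ns, _), idx in self._indexes.items():
            if namespace is None or ns == namespace:
                yield idx

    def __len__(self) -> int:
        return len(self._refs)

    # -- persistence ------------------------------------------------------

    def save(self, out_dir: str | os.PathLike) -> None:
        """Persist every reference (packed payload + index + annotations)
        under ``out_dir``, one JSON container per reference, written
        atomically so re-indexing overwrites cleanly."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (ns, name), ref in self._refs.items():
            idx = self._indexes[(ns, name)]
            ann = self._annotations.get((ns, name))
            doc = {
                "format": "tirmap-ref-v1",
                "name": name,
                "namespace": ns,
                "length": ref.length,
                "k": idx.k,
                "packed_hex": ref.packed.hex(),
                "ambiguous_positions": np.flatnonzero(~ref.valid).astype(int).tolist(),
                "index": {str(k): v.astype(int).tolist() for k, v in idx.table.items()},
                "annotations": [
                    [f.label, f.start, f.end, f.strand, f.kind]
                    for f in (ann.features if ann else [])
                ],
            }
            path = out / f"{ns}__{name}.json"
            fd, tmp = tempfile.mkstemp(dir=out, suffix=".tmp")
            try:
                with os.fdopen(fd, "w") as fh:
                    json.dump(doc, fh)
                os.replace(tmp, path)
            finally:
                if os.path.exists(tmp):
                    os.unlink(tmp)

    @classmethod
    def load(cls, in_dir: str | os.PathLike) -> "ReferenceDatabase":
        db = cls()
        for path in sorted(Path(in_dir).glob("*.json")):
            with open(path) as fh:
                doc = json.load(fh)
            if doc.get("format") != "tirmap-ref-v1":
                raise ValueError(f"{path} is not a tirmap reference container")
            codes = unpack_codes(bytes.fromhex(doc["packed_hex"]), doc["length"])
            valid = np.ones(doc["length"], dtype=bool)
            valid[np.asarray(doc["ambiguous_positions"], dtype=int)] = False
            seq = decode_codes(codes, valid)
            ann = None
            if doc["annotations"]:
                ann = AnnotationTrack(
                    doc["name"],
                    [Feature(a[0], a[1], a[2], a[3], a[4]) for a in doc["annotations"]],
                )
            db.register(doc["name"], seq, doc["namespace"], ann)
        return db


# -- annotation file import -----------------------------------------------


def read_annotation_tsv(path: str | os.PathLike, reference_name: str) -> AnnotationTrack:
    """Read a 4/5-column TSV: label, start, end, strand[, kind]."""
    feats = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{line_no}: expected >=4 tab-separated columns")
            kind = parts[4] if len(parts) > 4 else "gene"
            feats.append(Feature(parts[0], int(parts[1]), int(parts[2]), parts[3], kind))
    return AnnotationTrack(reference_name, feats)


def read_annotation_gff3(path: str | os.PathLike, reference_name: str) -> AnnotationTrack:
    """Import features for one seqid from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = []
    for f in db.all_features():
        if f.seqid != reference_name:
            continue
        label = f.attributes.get("Name", f.attributes.get("ID", [f.featuretype]))[0]
        ftype = f.featuretype.upper()
        kind = "TIR" if ("TIR" in ftype or "INVERTED_REPEAT" in ftype) else "gene"
        feats.append(Feature(label, f.start, f.end, f.strand or "+", kind))
    return AnnotationTrack(reference_name, feats)
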