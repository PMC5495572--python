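"""Reference sequences and an exact-match suffix-array index.

The mapper places read fragments by exact substring lookup only, so the
index is a plain suffix array over the concatenation of all reference
sequences.  Each sequence is terminated by a sentinel character that sorts
below every nucleotide, which keeps matches from spanning sequence
boundaries (queries never contain sentinel characters).

Coordinates are 0-based throughout; conversion to 1-based happens only at
output boundaries (e.g. SAM).
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .errors import FastaFormatError

# Sentinels must sort strictly below 'A' (codepoint 65); codepoints 1..63
# give distinct terminators for up to 63 sequences and are cycled beyond
# that.  Cycling only affects tie-breaking between suffixes that reach a
# sentinel, never lookup correctness, because queries are sentinel-free.
_SENTINEL_CODES = range(1, 64)

_REFERENCE_ALPHABET = frozenset("ACGTN")

INDEX_FORMAT_VERSION = 1


@dataclass
class ReferenceSet:
    """Ordered collection of named nucleotide sequences (A/C/G/T/N)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise FastaFormatError("reference set is empty")
        for name, seq in self.records.items():
            if not name:
                raise FastaFormatError("empty sequence id")
            if not seq:
                raise FastaFormatError(f"sequence {name!r} is empty")
            bad = set(seq) - _REFERENCE_ALPHABET
            if bad:
                raise FastaFormatError(
                    f"sequence {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


def _normalize(seq: str, name: str) -> str:
    out = seq.upper().replace("U", "T")
    bad = set(out) - _REFERENCE_ALPHABET
    if bad:
        raise FastaFormatError(
            f"record {name!r} contains characters outside A/C/G/T/U/N: {sorted(bad)}"
        )
    return out


def read_fasta(path) -> ReferenceSet:
    """Parse a (multi-)FASTA file into a :class:`ReferenceSet`.

    Sequences are uppercased and U is converted to T.  Duplicate headers,
    empty files and non-nucleotide characters raise
    :class:`~exactrna.errors.FastaFormatError` naming the offending record.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaFormatError(f"duplicate FASTA header {rec.id!r}")
        records[rec.id] = _normalize(str(rec.seq), rec.id)
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return ReferenceSet(records)


def write_fasta(refs: ReferenceSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in refs.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _suffix_sort(codes: np.ndarray) -> np.ndarray:
    """Suffix array of an integer string by prefix doubling (Manber–Myers)."""
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        new = np.empty(n, dtype=np.int64)
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
        new[sa] = np.concatenate(([0], np.cumsum(changed)))
        rank = new
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


@dataclass
class SuffixIndex:
    """Suffix array over sentinel-joined reference sequences.

    ``suffix_table`` holds the global offsets of every non-sentinel
    position, sorted by the lexicographic order of the suffix starting
    there.  ``starts`` gives each sequence's global start offset in
    ``text``, enabling O(log n) global→(sequence, local) conversion.
    """

    text: str
    suffix_table: np.ndarray
    seq_ids: list[str]
    starts: np.ndarray  # global offset of each sequence in text
    seq_lengths: np.ndarray
    version: int = INDEX_FORMAT_VERSION

    def offset_map(self, global_offset: int) -> tuple[str, int]:
        """Map a global text offset to (sequence_id, 0-based local position)."""
        i = int(np.searchsorted(self.starts, global_offset, side="right")) - 1
        local = global_offset - int(self.starts[i])
        if not (0 <= local < int(self.seq_lengths[i])):
            raise ValueError(f"offset {global_offset} falls on a sentinel")
        return self.seq_ids[i], local

    def global_offset(self, seq_id: str, local: int) -> int:
        i = self.seq_ids.index(seq_id)
        return int(self.starts[i]) + local

    def find_exact_offsets(self, query: str) -> list[int]:
        """Global offsets of all verbatim occurrences of ``query``."""
        if not query:
            raise ValueError("empty query")
        q = query.upper().replace("U", "T")
        bad = set(q) - _REFERENCE_ALPHABET
        if bad:
            raise ValueError(f"query contains non-nucleotide characters {sorted(bad)}")
        if "N" in q:
            return []  # exact matching: N never matches
        text, m = self.text, len(q)
        sa = self.suffix_table
        key = lambda s: text[s : s + m]
        lo = bisect_left(sa, q, key=key)
        hi = bisect_right(sa, q, key=key)
        return sorted(int(s) for s in sa[lo:hi])

    def find_exact(self, query: str) -> list[tuple[str, int]]:
        """All (sequence_id, 0-based position) occurrences, sorted."""
        hits = [self.offset_map(g) for g in self.find_exact_offsets(query)]
        return sorted(hits)

    # -- serialization: versioned JSON blob ------------------------------
    def save(self, path) -> None:
        blob = {
            "format": "exactrna-suffix-index",
            "version": self.version,
            "seq_ids": self.seq_ids,
            "sequences": {
                sid: self.text[int(s) : int(s) + int(l)]
                for sid, s, l in zip(self.seq_ids, self.starts, self.seq_lengths)
            },
            "suffix_table": [int(x) for x in self.suffix_table],
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "SuffixIndex":
        with open(path) as fh:
            blob = json.load(fh)
        if blob.get("format") != "exactrna-suffix-index":
            raise ValueError(f"{path} is not an exactrna index")
        if blob.get("version") != INDEX_FORMAT_VERSION:
            raise ValueError(
                f"index version {blob.get('version')} unsupported "
                f"(expected {INDEX_FORMAT_VERSION})"
            )
        refs = ReferenceSet({sid: blob["sequences"][sid] for sid in blob["seq_ids"]})
        idx = build_index(refs)
        # sanity: stored table must match deterministic reconstruction
        if blob["suffix_table"] != [int(x) for x in idx.suffix_table]:
            raise ValueError(f"corrupt suffix table in {path}")
        return idx


def build_index(refs: ReferenceSet) -> SuffixIndex:
    """Build the suffix-array index for a reference set.

    Deterministic for a given input; sentinel positions are excluded from
    the suffix table so every entry addresses a real reference base.
    """
    if refs.total_length == 0:
        raise FastaFormatError("total reference length is zero")
    pieces: list[str] = []
    seq_ids: list[str] = []
    starts: list[int] = []
    lengths: list[int] = []
    pos = 0
    for i, (name, seq) in enumerate(refs.records.items()):
        seq_ids.append(name)
        starts.append(pos)
        lengths.append(len(seq))
        sentinel = chr(_SENTINEL_CODES[i % len(_SENTINEL_CODES)])
        pieces.append(seq + sentinel)
        pos += len(seq) + 1
    text = "".join(pieces)
    codes = np.frombuffer(text.encode("latin1"), dtype=np.uint8)
    sa = _suffix_sort(codes)
    sa = sa[codes[sa] >= ord("A")]  # drop sentinel suffixes
    return SuffixIndex(
        text=text,
        suffix_table=sa.astype(np.int64),
        seq_ids=seq_ids,
        starts=np.asarray(starts, dtype=np.int64),
        seq_lengths=np.asarray(lengths, dtype=np.int64),
    )
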