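"""Ungapped read-to-hairpin alignment and miRNA read counting.

Reads are placed on hairpin precursors by an exhaustive ungapped Hamming
scan over every offset of every hairpin, keeping placements with at most
``max_mismatches`` substitutions (default 2) and then only those achieving
the minimal observed mismatch count. Placements are assigned to an
annotated mature arm when the read 5' end falls within a small window of
the arm's annotated 5' end and the read/arm overlap is long enough;
otherwise the read is hairpin-only and not counted.

Reads assigned to more than one mature arm at the same (minimal) mismatch
count contribute a fractionally split weight, so column totals equal the
number of assigned reads exactly. IsomiR classes are keyed by the signed
5'/3' end offsets relative to the annotated mature plus the mismatch count.

The scan is vectorized with numpy over unique read sequences; a pure-Python
reimplementation used in the test suite serves as the independent oracle.
"""

from __future__ import annotations

import collections
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .refio import Hairpin, HairpinReference, ReadSet, _normalize

__all__ = [
    "Alignment",
    "IsomiRTable",
    "CountTable",
    "align_read",
    "assign_to_mature",
    "count_libraries",
]

logger = logging.getLogger(__name__)

TOTAL_ROW = "TOTAL_MAPPED"

MultimapPolicy = Literal["split", "discard", "first-by-id"]


@dataclass(frozen=True)
class Alignment:
    """A single ungapped placement of a read on a hairpin (1-based start)."""

    read_id: str
    hairpin_id: str
    start: int
    length: int
    mismatches: int
    assigned_mature: str | None = None

    @property
    def end(self) -> int:
        """1-based inclusive end position on the hairpin."""
        return self.start + self.length - 1


@dataclass
class CountTable:
    """Per-library read counts per mature miRNA.

    ``counts`` is a mature_id x library DataFrame of non-negative weights
    (fractional under multi-map splitting); ``total_mapped`` are the column
    sums, the denominators for reads-per-million normalization.
    """

    counts: pd.DataFrame
    total_mapped: pd.Series

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CountTable":
        counts = counts.astype(float)
        return cls(counts=counts, total_mapped=counts.sum(axis=0))

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(self.counts.sum(axis=0).values, self.total_mapped.values):
            raise ValueError("total_mapped does not equal column sums")

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.loc[TOTAL_ROW] = self.total_mapped
        out.to_csv(path, sep="\t", index_label="mature_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="mature_id")
        df.index.name = None
        if TOTAL_ROW not in df.index:
            raise ValueError(f"{path}: missing {TOTAL_ROW} row")
        totals = df.loc[TOTAL_ROW]
        counts = df.drop(index=TOTAL_ROW)
        tab = cls(counts=counts.astype(float), total_mapped=totals.astype(float))
        tab.validate()
        return tab


@dataclass
class IsomiRTable:
    """IsomiR spectrum of one library.

    ``table`` columns: mature_id, offset5, offset3, mismatches, count,
    fraction. offset5/offset3 are signed nt shifts of the read ends
    relative to the annotated mature 5'/3' ends (negative = upstream).
    """

    library: str
    table: pd.DataFrame

    def dominant_fraction(self, mature_id: str) -> float:
        sub = self.table[self.table["mature_id"] == mature_id]
        if sub.empty:
            raise KeyError(mature_id)
        return float(sub["fraction"].max())

    def dominant_class(self, mature_id: str) -> tuple[int, int, int]:
        sub = self.table[self.table["mature_id"] == mature_id]
        if sub.empty:
            raise KeyError(mature_id)
        row = sub.sort_values(
            ["count", "offset5", "offset3", "mismatches"],
            ascending=[False, True, True, True],
        ).iloc[0]
        return int(row["offset5"]), int(row["offset3"]), int(row["mismatches"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# vectorized Hamming scan

_SENTINEL = 0  # byte that never equals A/C/G/T


class _ReferenceIndex:
    """Concatenated byte encoding of all hairpins for window comparisons."""

    def __init__(self, ref: HairpinReference):
        self.ref = ref
        gap = bytes([_SENTINEL]) * 4
        chunks: list[bytes] = []
        self.offsets: list[int] = []  # concat offset of each hairpin start
        pos = 0
        for hp in ref:
            self.offsets.append(pos)
            chunks.append(hp.sequence.encode())
            pos += len(hp.sequence) + len(gap)
            chunks.append(gap)
        self.concat = np.frombuffer(b"".join(chunks), dtype=np.uint8)
        self.hairpins = list(ref)
        # per concat position: hairpin index, local 0-based position
        self.hp_index = np.full(len(self.concat), -1, dtype=np.int64)
        self.local_pos = np.full(len(self.concat), -1, dtype=np.int64)
        for i, hp in enumerate(self.hairpins):
            s = self.offsets[i]
            self.hp_index[s : s + len(hp.sequence)] = i
            self.local_pos[s : s + len(hp.sequence)] = np.arange(len(hp.sequence))

    def windows(self, length: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All valid windows of ``length``: (matrix, hairpin idx, 1-based start)."""
        if length > len(self.concat):
            return (
                np.empty((0, length), dtype=np.uint8),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int64),
            )
        win = np.lib.stride_tricks.sliding_window_view(self.concat, length)
        starts = np.arange(win.shape[0])
        # valid iff window lies entirely within one hairpin
        hp_start = self.hp_index[starts]
        hp_end = self.hp_index[starts + length - 1]
        valid = (hp_start >= 0) & (hp_start == hp_end)
        starts = starts[valid]
        return win[valid], self.hp_index[starts], self.local_pos[starts] + 1


def _encode_reads(seqs: Sequence[str]) -> np.ndarray:
    joined = "".join(seqs).encode()
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(seqs), -1)


def _align_unique(
    seqs: Sequence[str],
    index: _ReferenceIndex,
    max_mismatches: int,
    chunk: int = 512,
) -> list[list[tuple[int, int, int]]]:
    """Minimal-mismatch placements for unique same-length sequences.

    Returns, per sequence, a list of (hairpin index, 1-based start,
    mismatches) restricted to the minimal mismatch count; empty when no
    placement is within ``max_mismatches``.
    """
    if not seqs:
        return []
    length = len(seqs[0])
    win, hp_idx, starts = index.windows(length)
    if win.shape[0] == 0:
        return [[] for _ in seqs]
    reads = _encode_reads(seqs)
    results: list[list[tuple[int, int, int]]] = []
    for lo in range(0, len(seqs), chunk):
        block = reads[lo : lo + chunk]
        # (B, W) mismatch counts; non-ACGT read symbols simply never match
        mism = (block[:, None, :] != win[None, :, :]).sum(axis=2, dtype=np.int32)
        for row in mism:
            best = int(row.min(initial=max_mismatches + 1))
            if best > max_mismatches:
                results.append([])
                continue
            hits = np.flatnonzero(row == best)
            results.append(
                [(int(hp_idx[h]), int(starts[h]), best) for h in hits]
            )
    return results


def align_read(
    read: str,
    ref: HairpinReference,
    max_mismatches: int = 2,
    read_id: str = "read",
) -> list[Alignment]:
    """All minimal-mismatch ungapped placements of one read (forward strand).

    Returns an empty list when no placement has at most ``max_mismatches``
    substitutions. Non-ACGT symbols in the read count as mismatches at
    their positions. Output order follows reference entry order, then
    position.
    """
    seq = _normalize(read)
    index = _ReferenceIndex(ref)
    hits = _align_unique([seq], index, max_mismatches)[0]
    hits.sort()
    return [
        Alignment(read_id, index.hairpins[hp].hairpin_id, start, len(seq), mm)
        for hp, start, mm in hits
    ]


def assign_to_mature(
    aln: Alignment,
    ref: HairpinReference,
    window5: int = 3,
    min_overlap: int = 16,
) -> str | None:
    """Mature arm for an alignment, or None (hairpin-only placement).

    The read start must lie within +/- ``window5`` nt of the arm's annotated
    5' end and the read/arm overlap must span at least ``min_overlap`` nt.
    When several arms qualify the one with the closest 5' end wins (ties:
    larger overlap, then lexicographic mature_id).
    """
    hp = ref.hairpin(aln.hairpin_id)
    candidates = []
    for arm in hp.matures:
        off5 = aln.start - arm.start
        if abs(off5) > window5:
            continue
        overlap = min(aln.end, arm.end) - max(aln.start, arm.start) + 1
        if overlap < min_overlap:
            continue
        candidates.append((abs(off5), -overlap, arm.mature_id))
    if not candidates:
        return None
    return min(candidates)[2]


def _mature_lookup(ref: HairpinReference) -> dict[str, list]:
    return {hp.hairpin_id: list(hp.matures) for hp in ref}


def count_libraries(
    readsets: Sequence[ReadSet],
    ref: HairpinReference,
    max_mismatches: int = 2,
    window5: int = 3,
    min_overlap: int = 16,
    multimap: MultimapPolicy = "split",
) -> tuple[CountTable, dict[str, IsomiRTable]]:
    """Count mature-assigned reads per library and tabulate isomiRs.

    Each read of weight 1 is distributed over its minimal-mismatch mature
    assignments according to ``multimap``: "split" (equal fractions,
    default), "discard" (multi-mapped reads dropped), or "first-by-id"
    (whole weight to the lexicographically first mature). IsomiR classes
    are (offset5, offset3, mismatches) per mature arm.
    """
    index = _ReferenceIndex(ref)
    arms = _mature_lookup(ref)
    mature_ids = ref.mature_ids
    libraries = [rs.label for rs in readsets]
    if len(set(libraries)) != len(libraries):
        raise ValueError(f"duplicate library labels: {libraries}")

    counts = pd.DataFrame(0.0, index=mature_ids, columns=libraries)
    isomir_tables: dict[str, IsomiRTable] = {}

    for rs in readsets:
        if len(rs) == 0:
            logger.warning("library %s is empty; zero column emitted", rs.label)
        # dedupe sequences; alignment depends on sequence only
        seq_counts: collections.Counter[str] = collections.Counter(
            _normalize(r.sequence) for r in rs.reads
        )
        by_len: dict[int, list[str]] = collections.defaultdict(list)
        for seq in seq_counts:
            by_len[len(seq)].append(seq)

        iso_counts: dict[tuple[str, int, int, int], float] = collections.defaultdict(float)
        for length in sorted(by_len):
            seqs = sorted(by_len[length])
            placements = _align_unique(seqs, index, max_mismatches)
            for seq, hits in zip(seqs, placements):
                if not hits:
                    continue
                n_reads = seq_counts[seq]
                # mature assignment per distinct placement
                assigned: dict[str, tuple[int, int, int]] = {}
                for hp_i, start, mm in hits:
                    hp = index.hairpins[hp_i]
                    aln = Alignment("", hp.hairpin_id, start, length, mm)
                    mat = assign_to_mature(aln, ref, window5, min_overlap)
                    if mat is None:
                        continue
                    arm = next(a for a in arms[hp.hairpin_id] if a.mature_id == mat)
                    assigned.setdefault(
                        mat, (start - arm.start, (start + length - 1) - arm.end, mm)
                    )
                if not assigned:
                    continue
                if len(assigned) > 1:
                    if multimap == "discard":
                        continue
                    if multimap == "first-by-id":
                        first = min(assigned)
                        assigned = {first: assigned[first]}
                weight = n_reads / len(assigned)
                for mat, (o5, o3, mm) in assigned.items():
                    counts.loc[mat, rs.label] += weight
                    iso_counts[(mat, o5, o3, mm)] += weight

        rows = [
            {
                "mature_id": mat,
                "offset5": o5,
                "offset3": o3,
                "mismatches": mm,
                "count": c,
            }
            for (mat, o5, o3, mm), c in sorted(iso_counts.items())
        ]
        iso = pd.DataFrame(
            rows, columns=["mature_id", "offset5", "offset3", "mismatches", "count"]
        )
        if not iso.empty:
            totals = iso.groupby("mature_id")["count"].transform("sum")
            iso["fraction"] = iso["count"] / totals
        else:
            iso["fraction"] = pd.Series(dtype=float)
        isomir_tables[rs.label] = IsomiRTable(rs.label, iso)

    table = CountTable.from_counts(counts)
    return table, isomir_tables
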