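"""Reference and read I/O plus adapter trimming.

Handles the three external formats the pipeline consumes:

* a hairpin (pre-miRNA) reference as FASTA with a companion TSV annotation
  giving the coordinates of each mature arm on its hairpin (1-based,
  inclusive, miRBase convention);
* small-RNA reads as 4-line FASTQ (qualities parsed, never used);
* 3'-adapter trimming with a Hamming-distance suffix/prefix scan and a
  minimum retained insert length.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "MatureArm",
    "Hairpin",
    "HairpinReference",
    "Read",
    "ReadSet",
    "TrimPolicy",
    "TrimSummary",
    "read_fasta_reference",
    "write_fasta_reference",
    "read_fastq",
    "write_fastq",
    "trim_adapters",
]

_VALID_BASES = frozenset("ACGTU")

# Illumina v1.5 small RNA 3' adapter; overridable everywhere it is used.
DEFAULT_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTG"


class ReferenceFormatError(ValueError):
    """Raised when a FASTA/annotation pair cannot be parsed or validated."""


class FastqFormatError(ValueError):
    """Raised on truncated or malformed FASTQ records."""


def _normalize(seq: str) -> str:
    """Uppercase and fold RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA annotated on its hairpin (1-based inclusive coords)."""

    mature_id: str
    start: int
    end: int


@dataclass(frozen=True)
class Hairpin:
    hairpin_id: str
    sequence: str
    matures: tuple[MatureArm, ...] = ()

    def mature_sequence(self, arm: MatureArm) -> str:
        return self.sequence[arm.start - 1 : arm.end]


@dataclass(frozen=True)
class HairpinReference:
    """Hairpin sequences with mature-arm coordinates; the alignment target.

    Sequences are stored T-normalized and uppercase so that RNA (U) and DNA
    (T) references are interchangeable.
    """

    entries: tuple[Hairpin, ...]

    def __post_init__(self) -> None:
        seen_hp: set[str] = set()
        seen_mat: set[str] = set()
        normed = []
        for hp in self.entries:
            if not hp.sequence:
                raise ReferenceFormatError(f"hairpin {hp.hairpin_id!r}: empty sequence")
            seq = _normalize(hp.sequence)
            bad = set(seq) - set("ACGT")
            if bad:
                raise ReferenceFormatError(
                    f"hairpin {hp.hairpin_id!r}: invalid characters {sorted(bad)}"
                )
            if hp.hairpin_id in seen_hp:
                raise ReferenceFormatError(f"duplicate hairpin id {hp.hairpin_id!r}")
            seen_hp.add(hp.hairpin_id)
            for arm in hp.matures:
                if not (1 <= arm.start <= arm.end <= len(seq)):
                    raise ReferenceFormatError(
                        f"mature {arm.mature_id!r} coordinates ({arm.start}, {arm.end}) "
                        f"outside hairpin {hp.hairpin_id!r} of length {len(seq)}"
                    )
                if arm.mature_id in seen_mat:
                    raise ReferenceFormatError(f"duplicate mature id {arm.mature_id!r}")
                seen_mat.add(arm.mature_id)
            normed.append(replace(hp, sequence=seq))
        object.__setattr__(self, "entries", tuple(normed))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def hairpin(self, hairpin_id: str) -> Hairpin:
        for hp in self.entries:
            if hp.hairpin_id == hairpin_id:
                return hp
        raise KeyError(hairpin_id)

    @property
    def mature_ids(self) -> list[str]:
        return [arm.mature_id for hp in self.entries for arm in hp.matures]

    def mature_sequences(self) -> dict[str, str]:
        return {
            arm.mature_id: hp.mature_sequence(arm)
            for hp in self.entries
            for arm in hp.matures
        }


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class ReadSet:
    """A small-RNA library: reads plus compartment/condition provenance."""

    reads: tuple[Read, ...]
    library_label: str  # "cell" or "EV"
    condition_label: str = ""

    def __post_init__(self) -> None:
        if not self.library_label:
            raise ValueError("library_label is mandatory")
        for r in self.reads:
            if not r.sequence:
                raise ValueError(f"read {r.read_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def label(self) -> str:
        if self.condition_label:
            return f"{self.library_label}_{self.condition_label}"
        return self.library_label


@dataclass(frozen=True)
class TrimPolicy:
    """Parameters of the 3'-adapter scan.

    The adapter is located as the leftmost suffix of the read matching a
    prefix of the adapter with at least ``min_overlap`` aligned bases and at
    most ``max_adapter_mismatches`` substitutions (no indels). Inserts
    shorter than ``min_read_length`` after trimming are discarded; the
    default of 16 nt keeps reads longer than 15 bp.
    """

    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 6
    max_adapter_mismatches: int = 1
    min_read_length: int = 16
    keep_untrimmed: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_read_length < 1:
            raise ValueError("min_read_length must be >= 1")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")


@dataclass
class TrimSummary:
    total: int = 0
    trimmed: int = 0
    untrimmed_kept: int = 0
    untrimmed_dropped: int = 0
    too_short: int = 0

    @property
    def kept(self) -> int:
        return self.trimmed + self.untrimmed_kept - self.too_short_trimmed

    # too-short reads are counted among 'trimmed' attempts; track separately
    too_short_trimmed: int = field(default=0, repr=False)


def read_fasta_reference(path: str | Path, annotation_path: str | Path) -> HairpinReference:
    """Load a hairpin FASTA plus its mature-arm TSV annotation.

    The annotation has (at least) four tab-separated columns:
    ``hairpin_id  mature_id  start  end`` with 1-based inclusive coordinates.
    Lines starting with ``#`` are ignored.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython error path
        raise ReferenceFormatError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise ReferenceFormatError(f"no FASTA records in {path}")

    matures: dict[str, list[MatureArm]] = collections.defaultdict(list)
    with open(annotation_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ReferenceFormatError(
                    f"{annotation_path}:{lineno}: expected >= 4 tab-separated columns"
                )
            hairpin_id, mature_id = parts[0], parts[1]
            try:
                start, end = int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ReferenceFormatError(
                    f"{annotation_path}:{lineno}: non-integer coordinates"
                ) from exc
            matures[hairpin_id].append(MatureArm(mature_id, start, end))

    known_ids = {rec.id for rec in records}
    unknown = set(matures) - known_ids
    if unknown:
        raise ReferenceFormatError(
            f"annotation references unknown hairpin ids: {sorted(unknown)}"
        )
    entries = tuple(
        Hairpin(rec.id, str(rec.seq), tuple(matures.get(rec.id, ())))
        for rec in records
    )
    return HairpinReference(entries)


def write_fasta_reference(
    ref: HairpinReference, path: str | Path, annotation_path: str | Path
) -> None:
    """Write a reference back to FASTA + TSV (inverse of read_fasta_reference)."""
    with open(path, "w") as fa:
        for hp in ref:
            fa.write(f">{hp.hairpin_id}\n{hp.sequence}\n")
    with open(annotation_path, "w") as ann:
        ann.write("#hairpin_id\tmature_id\tstart\tend\n")
        for hp in ref:
            for arm in hp.matures:
                ann.write(f"{hp.hairpin_id}\t{arm.mature_id}\t{arm.start}\t{arm.end}\n")


def read_fastq(
    path: str | Path, library_label: str, condition_label: str = ""
) -> ReadSet:
    """Read a (Phred+33) FASTQ file; qualities are discarded downstream."""
    reads = []
    try:
        with open(path) as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                reads.append(Read(title.split()[0], seq.upper()))
    except ValueError as exc:
        raise FastqFormatError(
            f"malformed FASTQ {path} near record {len(reads) + 1}: {exc}"
        ) from exc
    return ReadSet(tuple(reads), library_label, condition_label)


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def _find_adapter_start(seq: str, policy: TrimPolicy) -> int | None:
    """Leftmost position where the adapter starts, or None.

    A candidate position i aligns seq[i:] against the adapter prefix of the
    same length; the overlap must be >= min_overlap with at most
    max_adapter_mismatches Hamming mismatches.
    """
    adapter = policy.adapter
    n, m = len(seq), len(adapter)
    max_mm = policy.max_adapter_mismatches
    for i in range(0, n - policy.min_overlap + 1):
        overlap = min(n - i, m)
        mm = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return None


def trim_adapters(
    reads: ReadSet, policy: TrimPolicy | None = None
) -> tuple[ReadSet, TrimSummary]:
    """Remove 3' adapters and drop inserts shorter than the length floor.

    Reads with no detectable adapter are kept unmodified when
    ``policy.keep_untrimmed`` (default) and dropped otherwise. Returns the
    trimmed library and a summary of what was removed.
    """
    policy = policy or TrimPolicy()
    summary = TrimSummary(total=len(reads))
    # Trimming is per-sequence; dedupe so each distinct sequence is scanned once.
    cache: dict[str, int | None] = {}
    kept: list[Read] = []
    for r in reads.reads:
        seq = r.sequence
        if seq in cache:
            pos = cache[seq]
        else:
            pos = _find_adapter_start(_normalize(seq), policy)
            cache[seq] = pos
        if pos is None:
            if policy.keep_untrimmed:
                if len(seq) >= policy.min_read_length:
                    kept.append(r)
                    summary.untrimmed_kept += 1
                else:
                    summary.too_short += 1
            else:
                summary.untrimmed_dropped += 1
            continue
        summary.trimmed += 1
        insert = seq[:pos]
        if len(insert) < policy.min_read_length:
            summary.too_short += 1
            summary.too_short_trimmed += 1
            continue
        kept.append(Read(r.read_id, insert))
    out = ReadSet(tuple(kept), reads.library_label, reads.condition_label)
    return out, summary
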