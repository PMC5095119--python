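"""Read loading, constant-region handling, orientation, and V/J partitioning.

Rearranged receptor reads run 5'-V-(D)-J-C-3' once oriented forward.  The
constant (C) region, when present, anchors orientation: its first
``probe_len`` bases are searched on both strands with a small mismatch
budget, the read is flipped to V->J order if needed, and the C region plus
everything downstream is trimmed.  Each retained read is then split into an
overlapping "V part" (read minus its last ``vm`` bases) and "J part" (last
``jm`` bases), so that V and J segments can be inferred independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "RawRead",
    "UniqueRead",
    "PartitionedRead",
    "ParseError",
    "load_reads",
    "reverse_complement",
    "detect_and_trim_c",
    "partition",
    "dedupe",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input record cannot be parsed."""


@dataclass(frozen=True)
class RawRead:
    """A single input read: id, uppercase sequence, optional qualities."""

    id: str
    seq: str
    qual: Optional[list] = None


@dataclass(frozen=True)
class UniqueRead:
    """A deduplicated sequence with the number of identical raw reads."""

    seq: str
    count: int


@dataclass(frozen=True)
class PartitionedRead:
    v_part: str
    j_part: str
    source_id: str


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    raise ParseError(f"cannot infer format from extension {suffix!r}; pass format=")


def load_reads(path, format: Optional[str] = None) -> list[RawRead]:
    """Load FASTA/FASTQ records as :class:`RawRead` with uppercase sequences.

    Raises :class:`ParseError` naming the (0-based) record index at which
    parsing failed, or if a sequence contains characters outside A/C/G/T/N.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or _guess_format(path)
    reads: list[RawRead] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            seq = str(rec.seq).upper()
            if not seq or not _ALPHABET.issuperset(seq):
                raise ParseError(f"record {i} ({rec.id}): invalid sequence")
            qual = rec.letter_annotations.get("phred_quality")
            reads.append(RawRead(id=rec.id, seq=seq, qual=qual))
    except ParseError:
        raise
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ParseError(f"record {len(reads)}: {exc}") from exc
    return reads


def _probe_mismatches(probe: str, window: str) -> int:
    """Hamming mismatches; any N (either side) counts as a mismatch."""
    mm = 0
    for a, b in zip(probe, window):
        if a != b or a == "N" or b == "N":
            mm += 1
    return mm


def detect_and_trim_c(
    read: RawRead | str,
    c_refs: Iterable[str],
    max_mismatch: int = 2,
    probe_len: int = 18,
) -> Optional[str]:
    """Locate a C-region probe on either strand; orient and trim the read.

    The first ``probe_len`` bases of every C reference are slid over the
    read and its reverse complement.  The window with the fewest mismatches
    wins; ties go to the most 3' window (the C region sits at the read's 3'
    terminus by library construction), and at equal position the forward
    strand is preferred.  Returns the forward-oriented read with the C
    region and everything downstream removed, or ``None`` when no window
    reaches ``max_mismatch``.
    """
    seq = read.seq if isinstance(read, RawRead) else read
    probes = [c[:probe_len].upper() for c in c_refs if len(c) >= probe_len]
    if not probes:
        raise ValueError("c_refs must contain at least one reference >= probe_len")
    best: Optional[tuple[int, int, int]] = None  # (mismatches, -start, strand)
    for strand, s in enumerate((seq, reverse_complement(seq))):
        for probe in probes:
            for start in range(len(s) - probe_len + 1):
                mm = _probe_mismatches(probe, s[start : start + probe_len])
                key = (mm, -start, strand)
                if best is None or key < best:
                    best = key
    if best is None or best[0] > max_mismatch:
        return None
    _, neg_start, strand = best
    oriented = seq if strand == 0 else reverse_complement(seq)
    return oriented[: -neg_start] if neg_start else ""


def partition(seq: str, jm: int = 60, vm: int = 40, source_id: str = "") -> Optional[PartitionedRead]:
    """Split a forward read into its J part (last ``jm`` bases) and V part
    (read with the last ``vm`` bases removed).  Reads of length <= ``vm``
    are unusable and return ``None``."""
    if len(seq) <= vm:
        return None
    return PartitionedRead(v_part=seq[:-vm], j_part=seq[-jm:], source_id=source_id)


def dedupe(seqs: Iterable[str]) -> list[UniqueRead]:
    """Collapse identical sequences, keeping abundance.  Output is sorted by
    descending count then sequence, so results are order-independent."""
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    return [
        UniqueRead(seq=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
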