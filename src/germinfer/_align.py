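"""Internal ungapped offset alignment shared by annotation and evaluation.

Germline V/J alleles differ almost exclusively by substitutions, so the
primary comparison is end-free and ungapped: slide one sequence along the
other, take the offset with the most matches, and count substitutions over
the overlap.  Terminal overhangs are not penalized here; they are reported
separately as signed "deviated bases" at the junction-facing end.  A gapped
global alignment (edlib) is consulted only as a fallback for length-
discordant pairs where the ungapped fit is poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

__all__ = ["Alignment", "best_ungapped", "deviated_bases", "align_to_reference"]

MIN_OVERLAP = 20


@dataclass(frozen=True)
class Alignment:
    offset: int  # position of query[0] in reference coordinates (may be negative)
    matches: int
    mismatches: int
    overlap: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.overlap if self.overlap else 0.0


def best_ungapped(query: str, ref: str) -> Alignment:
    """Best end-free ungapped placement of ``query`` against ``ref``.

    Offsets requiring less overlap than ``MIN_OVERLAP`` (or the shorter
    sequence, if shorter than that) are not considered; ties on match count
    are broken toward the smaller absolute offset, then the smaller offset.
    """
    nq, nr = len(query), len(ref)
    min_ov = min(MIN_OVERLAP, nq, nr)
    best: Alignment | None = None
    best_key = None
    for off in range(-(nq - min_ov), nr - min_ov + 1):
        lo = max(0, -off)
        hi = min(nq, nr - off)
        if hi - lo < min_ov:
            continue
        matches = sum(1 for p in range(lo, hi) if query[p] == ref[p + off])
        aln = Alignment(offset=off, matches=matches, mismatches=(hi - lo) - matches,
                        overlap=hi - lo)
        key = (-matches, abs(off), off)
        if best_key is None or key < best_key:
            best, best_key = aln, key
    assert best is not None
    return best


def deviated_bases(aln: Alignment, query_len: int, ref_len: int, segment: str) -> int:
    """Signed extra (+) or missing (-) bases at the junction-facing end of
    the query relative to the reference terminus: the 3' end for V, the 5'
    end for J."""
    if segment == "V":
        return (aln.offset + query_len) - ref_len
    return -aln.offset


def align_to_reference(query: str, ref: str, segment: str) -> tuple[Alignment, int]:
    """Ungapped alignment with a gapped fallback for length-discordant,
    poorly fitting pairs.  Returns (alignment, deviated_bases).

    Exact containment of one sequence in the other is already the optimal
    ungapped placement, so it short-circuits the offset scan.
    """
    aln = None
    if len(query) <= len(ref):
        idx = ref.find(query)
        if idx >= 0:
            aln = Alignment(offset=idx, matches=len(query), mismatches=0,
                            overlap=len(query))
    else:
        idx = query.find(ref)
        if idx >= 0:
            aln = Alignment(offset=-idx, matches=len(ref), mismatches=0,
                            overlap=len(ref))
    if aln is None:
        aln = best_ungapped(query, ref)
    if abs(len(query) - len(ref)) > 5 and aln.identity < 90.0:
        short, long = (query, ref) if len(query) <= len(ref) else (ref, query)
        res = edlib.align(short, long, mode="HW", task="locations")
        if res["editDistance"] >= 0:
            dist = res["editDistance"]
            gapped = Alignment(
                offset=res["locations"][0][0] if len(query) <= len(ref) else -res["locations"][0][0],
                matches=len(short) - dist,
                mismatches=dist,
                overlap=len(short),
            )
            if gapped.identity > aln.identity:
                aln = gapped
    return aln, deviated_bases(aln, len(query), len(ref), segment)
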