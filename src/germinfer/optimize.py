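"""Candidate optimization: false-positive filtering, redundancy merging, and
somatic-hypermutation / error elimination.

A genuine germline terminus faces the junction, where real rearrangements
exhibit diverse deletion and insertion lengths.  Trimming 5 bases off the
junction-facing end of a true candidate therefore gains substantial extra
read support (many rearrangements deleted a few terminal bases), whereas an
artifact of non-specific amplification or an over-extended candidate gains
nothing.  Five statistics capture this:

* ``Trim5 Ratio1/2`` - read / unique-read support of the 5bp-trimmed form
  relative to the candidate's own support (fold change; printed x100).
* ``Trim5 Rate1/2`` - the trimmed form's support relative to the cohort
  mean of trimmed-form supports (percent of mean).
* ``More5 Rate``    - unique-read support of the best 5-base extension
  beyond the junction-facing end, relative to the cohort mean (percent).

The ratio gates are compared on the fold scale (default > 1.5); the rate
gates on the percent-of-cohort-mean scale (default > 2, > 5), where they
act as weak absolute-support floors.  After filtering, candidates that are
sub/super-sequences of one another (up to two mismatches confined to the
junction-facing 5 bp of the overlap) are merged.  Finally candidates are
grouped by masked Hamming distance; each group models one gene, so at most
two members (the read-richest "center" plus its best-supported sibling
allele) survive, and any member more than ``ratio_cap``-fold rarer than the
center is discarded as SHM/PCR noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .preprocess import UniqueRead

__all__ = [
    "FilterMetrics",
    "FilterThresholds",
    "CandidateGermline",
    "candidate_supports",
    "compute_metrics",
    "cohort_metrics",
    "filter_fp",
    "merge_redundant",
    "masked_distance",
    "shm_filter",
    "intersect_individuals",
]

logger = logging.getLogger(__name__)

TRIM = 5  # bases trimmed/extended at the junction-facing end
MERGE_MISMATCH_ZONE = 5  # terminal window of the overlap where merge mismatches may sit
MASK = 3  # terminal bases masked in grouping distances

Segment = Literal["V", "J"]


@dataclass
class FilterMetrics:
    """Terminal-diversity statistics, stored on the printed (x100) scale."""

    trim5_ratio1: float
    trim5_ratio2: float
    trim5_rate1: float
    trim5_rate2: float
    more5_rate: float
    supp_s_reads: int = 0
    supp_s_unique: int = 0
    supp_trim5_reads: int = 0
    supp_trim5_unique: int = 0
    supp_more5_unique: int = 0
    more5_ext: str = ""


@dataclass
class FilterThresholds:
    trim5_ratio: float = 1.5  # fold scale
    trim5_rate: float = 2.0  # percent-of-cohort-mean scale
    trim5_rate_trbj: float = 0.5  # J override for TRB chains
    more5_rate: float = 5.0  # percent-of-cohort-mean scale


@dataclass
class CandidateGermline:
    sequence: str
    segment: Segment
    cluster_reads: list[UniqueRead] = field(default_factory=list)
    support_reads: int = 0
    support_unique: int = 0
    metrics: Optional[FilterMetrics] = None
    merged_from: list[str] = field(default_factory=list)
    group_id: Optional[int] = None
    ratio_to_center: Optional[float] = None
    is_major: bool = False
    status: str = "live"  # live | fp_filtered | merged | shm_filtered | retained
    sample_occurrence: int = 1


def candidate_supports(seq: str, reads: Sequence[UniqueRead]) -> tuple[int, int]:
    """(read count, unique-read count) of reads containing ``seq``."""
    r = u = 0
    for read in reads:
        if seq in read.seq:
            r += read.count
            u += 1
    return r, u


def _best_more5(seq: str, reads: Sequence[UniqueRead], segment: Segment) -> tuple[str, int]:
    """Most-supported 5-base continuation beyond the junction-facing end of
    ``seq`` among reads containing it; returns (extension, unique support)."""
    tallies: dict[str, int] = {}
    for read in reads:
        s = read.seq
        start = 0
        while True:
            idx = s.find(seq, start)
            if idx < 0:
                break
            if segment == "V":
                ext = s[idx + len(seq) : idx + len(seq) + TRIM]
            else:
                ext = s[max(0, idx - TRIM) : idx]
            if len(ext) == TRIM:
                tallies[ext] = tallies.get(ext, 0) + 1
            start = idx + 1
    if not tallies:
        return "", 0
    ext = min((e for e, c in tallies.items() if c == max(tallies.values())))
    return ext, tallies[ext]


def compute_metrics(
    candidate: str,
    reads: Sequence[UniqueRead],
    cohort: Optional[Sequence[FilterMetrics]] = None,
    segment: Segment = "V",
    _warn_empty: bool = True,
) -> FilterMetrics:
    """Compute the five statistics for one candidate.

    ``cohort`` supplies the supports of every same-segment candidate
    (including this one) for the Rate denominators; pass ``None`` for a
    cohort of size zero, in which case the rates are undefined and the rate
    gates pass vacuously (values set to +inf).
    """
    if len(candidate) <= TRIM:
        raise ValueError("candidate must be longer than the 5 bp trim")
    s_trim = candidate[:-TRIM] if segment == "V" else candidate[TRIM:]
    s_r, s_u = candidate_supports(candidate, reads)
    t_r, t_u = candidate_supports(s_trim, reads)
    ext, m_u = _best_more5(candidate, reads, segment)

    ratio1 = 100.0 * t_r / s_r if s_r else float("inf")
    ratio2 = 100.0 * t_u / s_u if s_u else float("inf")
    metrics = FilterMetrics(
        trim5_ratio1=ratio1,
        trim5_ratio2=ratio2,
        trim5_rate1=float("inf"),
        trim5_rate2=float("inf"),
        more5_rate=float("inf"),
        supp_s_reads=s_r,
        supp_s_unique=s_u,
        supp_trim5_reads=t_r,
        supp_trim5_unique=t_u,
        supp_more5_unique=m_u,
        more5_ext=ext,
    )
    if cohort:
        mean_t_r = sum(m.supp_trim5_reads for m in cohort) / len(cohort)
        mean_t_u = sum(m.supp_trim5_unique for m in cohort) / len(cohort)
        mean_m_u = sum(m.supp_more5_unique for m in cohort) / len(cohort)
        metrics.trim5_rate1 = 100.0 * t_r / mean_t_r if mean_t_r else float("inf")
        metrics.trim5_rate2 = 100.0 * t_u / mean_t_u if mean_t_u else float("inf")
        metrics.more5_rate = 100.0 * m_u / mean_m_u if mean_m_u else float("inf")
    elif _warn_empty:
        logger.warning("empty cohort: rate gates pass vacuously")
    return metrics


def cohort_metrics(candidates: Sequence[CandidateGermline]) -> None:
    """Fill ``metrics`` for every candidate of one segment, with the Rate
    denominators averaged over the whole (same-segment) cohort."""
    partial = [
        compute_metrics(c.sequence, c.cluster_reads, cohort=None, segment=c.segment,
                        _warn_empty=False)
        for c in candidates
    ]
    n = len(partial)
    if n:
        mean_t_r = sum(m.supp_trim5_reads for m in partial) / n
        mean_t_u = sum(m.supp_trim5_unique for m in partial) / n
        mean_m_u = sum(m.supp_more5_unique for m in partial) / n
        for m in partial:
            m.trim5_rate1 = 100.0 * m.supp_trim5_reads / mean_t_r if mean_t_r else float("inf")
            m.trim5_rate2 = 100.0 * m.supp_trim5_unique / mean_t_u if mean_t_u else float("inf")
            m.more5_rate = 100.0 * m.supp_more5_unique / mean_m_u if mean_m_u else float("inf")
    for c, m in zip(candidates, partial):
        c.metrics = m
        c.support_reads = m.supp_s_reads
        c.support_unique = m.supp_s_unique


def filter_fp(
    candidates: Sequence[CandidateGermline],
    thresholds: FilterThresholds | None = None,
    chain: Optional[str] = None,
) -> tuple[list[CandidateGermline], list[CandidateGermline]]:
    """Partition candidates by the five gates.  A candidate is retained iff
    both Trim5 Ratios exceed the fold threshold AND both Trim5 Rates and the
    More5 Rate exceed their percent thresholds (TRB J rate override
    applies when ``chain`` is 'TRB')."""
    th = thresholds or FilterThresholds()
    kept: list[CandidateGermline] = []
    dropped: list[CandidateGermline] = []
    for c in candidates:
        m = c.metrics
        if m is None:
            raise ValueError("metrics not computed")
        rate_th = th.trim5_rate_trbj if (c.segment == "J" and chain == "TRB") else th.trim5_rate
        ok = (
            m.trim5_ratio1 > th.trim5_ratio * 100.0
            and m.trim5_ratio2 > th.trim5_ratio * 100.0
            and m.trim5_rate1 > rate_th
            and m.trim5_rate2 > rate_th
            and m.more5_rate > th.more5_rate
        )
        if ok:
            kept.append(c)
        else:
            c.status = "fp_filtered"
            dropped.append(c)
    return kept, dropped


def _containable(short: str, long: str, segment: Segment, max_mismatch: int = 2) -> bool:
    """True when ``short`` fits inside ``long`` at some offset with at most
    ``max_mismatch`` mismatches, all confined to the junction-facing
    terminal window of the overlap."""
    n = len(short)
    for off in range(len(long) - n + 1):
        window = long[off : off + n]
        mm = [p for p in range(n) if short[p] != window[p]]
        if len(mm) > max_mismatch:
            continue
        if segment == "V":
            zone_ok = all(p >= n - MERGE_MISMATCH_ZONE for p in mm)
        else:
            zone_ok = all(p < MERGE_MISMATCH_ZONE for p in mm)
        if zone_ok:
            return True
    return False


def merge_redundant(
    candidates: Sequence[CandidateGermline], segment: Segment
) -> list[CandidateGermline]:
    """Merge sub/super-sequence candidates into the longer, better-supported
    one.  Merge history and support accumulate onto the survivor; absorbed
    candidates are marked ``merged``."""
    order = sorted(
        candidates, key=lambda c: (-len(c.sequence), -c.support_reads, c.sequence)
    )
    survivors: list[CandidateGermline] = []
    for c in order:
        target = None
        for s in survivors:
            if c.sequence == s.sequence or _containable(c.sequence, s.sequence, segment):
                target = s
                break
        if target is None:
            survivors.append(c)
        else:
            target.merged_from.extend(c.merged_from + [c.sequence])
            target.support_reads += c.support_reads
            target.support_unique += c.support_unique
            c.status = "merged"
    return survivors


def masked_distance(a: str, b: str, segment: Segment, mask: int = MASK) -> int:
    """Substitution distance between two same-segment candidates at their
    best ungapped offset, with each sequence's junction-facing ``mask``
    terminal bases (V: 3' end; J: 5' end) excluded.  Offset alignment lets
    partial assemblies of a gene group with its full-length center."""
    from ._align import best_ungapped

    aln = best_ungapped(a, b)
    off = aln.offset  # position of a[0] in b coordinates
    lo = max(0, -off)
    hi = min(len(a), len(b) - off)
    mm = 0
    for p in range(lo, hi):
        if a[p] == b[p + off]:
            continue
        if segment == "V":
            if p >= len(a) - mask or p + off >= len(b) - mask:
                continue
        elif p < mask or p + off < mask:
            continue
        mm += 1
    return mm


def shm_filter(
    candidates: Sequence[CandidateGermline],
    segment: Segment,
    ratio_cap: float = 10.0,
    group_dist: Optional[int] = None,
) -> list[CandidateGermline]:
    """Quality-threshold grouping and the allele-ratio rule.

    Groups are seeded by the unassigned candidate with the most supporting
    reads (the center); candidates within the masked Hamming distance join
    it.  A gene can show at most two alleles in one individual, and the
    rarer allele of a pair is rarely >10x rarer than the major one, so each
    group keeps the center plus the sibling with the smallest
    Ratio(S) = center support / S support, and drops members whose ratio
    exceeds ``ratio_cap``.
    """
    d = group_dist if group_dist is not None else (3 if segment == "V" else 2)
    pool = sorted(candidates, key=lambda c: (-c.support_reads, c.sequence))
    retained: list[CandidateGermline] = []
    gid = 0
    while pool:
        center = pool.pop(0)
        members = [c for c in pool if masked_distance(center.sequence, c.sequence, segment) <= d]
        member_ids = {id(c) for c in members}
        pool = [c for c in pool if id(c) not in member_ids]
        center.group_id = gid
        center.ratio_to_center = 1.0
        center.is_major = True
        center.status = "retained"
        retained.append(center)
        scored = []
        for c in members:
            c.group_id = gid
            c.is_major = False
            c.ratio_to_center = (
                center.support_reads / c.support_reads if c.support_reads else float("inf")
            )
            if c.ratio_to_center > ratio_cap:
                c.status = "shm_filtered"
            else:
                scored.append(c)
        scored.sort(key=lambda c: (c.ratio_to_center, c.sequence))
        for rank, c in enumerate(scored):
            if rank == 0:
                c.status = "retained"
                retained.append(c)
            else:
                c.status = "shm_filtered"
        gid += 1
    return retained


def intersect_individuals(
    per_sample: Sequence[Sequence[CandidateGermline]],
    min_samples: int = 1,
) -> dict[str, int]:
    """Count, for every sequence, the number of samples it was inferred in,
    and stamp ``sample_occurrence`` on each candidate.  Returns the
    occurrence map; candidates below ``min_samples`` are marked
    ``shm_filtered`` (cross-individual evidence is the paper-level guard
    against shared-looking hotspot artifacts)."""
    occurrence: dict[str, int] = {}
    for sample in per_sample:
        for seq in {c.sequence for c in sample}:
            occurrence[seq] = occurrence.get(seq, 0) + 1
    for sample in per_sample:
        for c in sample:
            c.sample_occurrence = occurrence[c.sequence]
            if c.sample_occurrence < min_samples:
                c.status = "shm_filtered"
    return occurrence
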