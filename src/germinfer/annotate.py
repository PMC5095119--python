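"""Scoring, classification against known references, naming, and output.

Every retained candidate receives a confidence score built from its
terminal-diversity statistics and merge history, normalized by the cohort
maxima so the strongest candidate of a segment scores 100.  Candidates are
then compared to any known germline alleles: an exact (masked) match is
``known``; fewer than 7 substitutions for V (at most 5 for J) against the
nearest allele makes a ``novel_allele`` of that gene; anything farther is a
``novel_gene``.  The 7/5 dividing lines are the empirical Hamming gaps
separating alleles of one gene from the closest allele of a different
gene.  Novel genes are grouped by the same distance rule, one assumed gene
per group, and named ``GENE<letter>*<allele index>``; names are
suggestions, not official nomenclature.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd

from ._align import align_to_reference
from .optimize import CandidateGermline, FilterMetrics, masked_distance

__all__ = [
    "ScoreWeights",
    "GermlineCall",
    "score",
    "cohort_maxima",
    "classify",
    "name_novel_genes",
    "annotate_candidates",
    "write_outputs",
]

V_NOVEL_CUT = 7  # mismatches below this -> novel allele (V)
J_NOVEL_CUT = 5  # mismatches at or below this -> novel allele (J)
KNOWN_DEVIATION_TOL = 5

Segment = Literal["V", "J"]


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the seven scoring factors; the major branch sums to 100."""

    trim5_ratio1: float = 20.0
    trim5_ratio2: float = 20.0
    more5_rate: float = 15.0
    trim5_rate1: float = 10.0
    trim5_rate2: float = 10.0
    merged_num: float = 15.0
    major: float = 10.0
    minor: float = 5.0

    def major_total(self) -> float:
        return (self.trim5_ratio1 + self.trim5_ratio2 + self.more5_rate
                + self.trim5_rate1 + self.trim5_rate2 + self.merged_num + self.major)


@dataclass
class GermlineCall:
    sequence: str
    segment: Segment
    score: float = 0.0
    nearest_allele: Optional[str] = None
    identity: float = 0.0
    mismatches: int = 0
    deviated_bases: int = 0
    category: str = "novel_gene"  # known | novel_allele | novel_gene
    assigned_name: str = ""
    support_reads: int = 0
    n_merged: int = 0
    sample_occurrence: int = 1
    is_major: bool = True


def cohort_maxima(candidates: Sequence[CandidateGermline]) -> dict[str, float]:
    """Per-metric maxima over the reported cohort (used as score
    denominators)."""

    def mx(get) -> float:
        vals = [get(c) for c in candidates]
        vals = [v for v in vals if v == v and v != float("inf")]
        return max(vals) if vals else 0.0

    return {
        "trim5_ratio1": mx(lambda c: c.metrics.trim5_ratio1),
        "trim5_ratio2": mx(lambda c: c.metrics.trim5_ratio2),
        "more5_rate": mx(lambda c: c.metrics.more5_rate),
        "trim5_rate1": mx(lambda c: c.metrics.trim5_rate1),
        "trim5_rate2": mx(lambda c: c.metrics.trim5_rate2),
        "merged_num": mx(lambda c: float(len(c.merged_from))),
    }


def score(
    metrics: FilterMetrics,
    merged_num: int,
    maxima: dict[str, float],
    weights: ScoreWeights | None = None,
    is_major: bool = True,
) -> float:
    """Confidence score in [0, 100]: six cohort-normalized metric terms plus
    the major/minor allele bonus.  Terms whose cohort maximum is zero (or
    whose value is undefined) contribute nothing."""
    if not maxima:
        raise ValueError("empty cohort")
    w = weights or ScoreWeights()
    pairs = [
        (metrics.trim5_ratio1, maxima["trim5_ratio1"], w.trim5_ratio1),
        (metrics.trim5_ratio2, maxima["trim5_ratio2"], w.trim5_ratio2),
        (metrics.more5_rate, maxima["more5_rate"], w.more5_rate),
        (metrics.trim5_rate1, maxima["trim5_rate1"], w.trim5_rate1),
        (metrics.trim5_rate2, maxima["trim5_rate2"], w.trim5_rate2),
        (float(merged_num), maxima["merged_num"], w.merged_num),
    ]
    total = w.major if is_major else w.minor
    for value, mx, weight in pairs:
        if mx > 0 and value == value and value != float("inf"):
            total += min(value / mx, 1.0) * weight
    return max(0.0, min(100.0, total))


def classify(
    sequence: str,
    known_refs: dict[str, str] | None,
    segment: Segment = "V",
    v_cut: int = V_NOVEL_CUT,
    j_cut: int = J_NOVEL_CUT,
    mask_terminal: bool = True,
) -> GermlineCall:
    """Assign nearest known allele, mismatch count, deviated bases, and
    category.  With no references everything is a novel gene.

    Mismatches are counted after masking the junction-facing 3 terminal
    bases of the candidate (mirroring the grouping mask) unless
    ``mask_terminal`` is False.  Ties on identity break by fewer mismatches
    then reference name, so reference file order never matters.
    """
    call = GermlineCall(sequence=sequence, segment=segment)
    if not known_refs:
        return call
    best = None
    for name in sorted(known_refs):
        ref = known_refs[name].upper()
        aln, dev = align_to_reference(sequence, ref, segment)
        mm = aln.mismatches
        if mask_terminal and mm:
            mm = _masked_mismatches(sequence, ref, aln.offset, segment)
        key = (-aln.identity, mm, name)
        if best is None or key < best[0]:
            best = (key, name, aln, mm, dev)
    _, name, aln, mm, dev = best
    call.nearest_allele = name
    call.identity = aln.identity
    call.mismatches = mm
    call.deviated_bases = dev
    cut = v_cut if segment == "V" else j_cut
    if mm == 0 and abs(dev) <= KNOWN_DEVIATION_TOL:
        call.category = "known"
    elif (segment == "V" and mm < cut) or (segment == "J" and mm <= cut):
        call.category = "novel_allele"
    else:
        call.category = "novel_gene"
    return call


def _masked_mismatches(query: str, ref: str, offset: int, segment: Segment) -> int:
    """Substitutions in the ungapped overlap, excluding the candidate's
    junction-facing 3 terminal bases."""
    lo = max(0, -offset)
    hi = min(len(query), len(ref) - offset)
    if segment == "V":
        hi = min(hi, len(query) - 3)
    else:
        lo = max(lo, 3)
    return sum(1 for p in range(lo, hi) if query[p] != ref[p + offset])


def _gene_letters():
    letters = list(string.ascii_uppercase)
    for a in string.ascii_uppercase:
        for b in string.ascii_uppercase:
            letters.append(a + b)
    return letters


def name_novel_genes(
    calls: Sequence[GermlineCall],
    v_cut: int = V_NOVEL_CUT,
    j_cut: int = J_NOVEL_CUT,
) -> None:
    """Group novel-gene calls of one segment by masked Hamming distance
    (< v_cut for V, <= j_cut for J); each group is one assumed gene.
    Groups are seeded by the highest-scoring unassigned call; members are
    named GENE<letter>*<index> with allele indices ordered by descending
    score."""
    for segment in ("V", "J"):
        pool = sorted(
            (c for c in calls if c.segment == segment and c.category == "novel_gene"),
            key=lambda c: (-c.score, c.sequence),
        )
        letters = _gene_letters()
        g = 0
        while pool:
            center = pool.pop(0)
            cut = v_cut if segment == "V" else j_cut
            members = [center]
            rest = []
            for c in pool:
                dist = masked_distance(center.sequence, c.sequence, segment)
                close = dist < cut if segment == "V" else dist <= cut
                (members if close else rest).append(c)
            pool = rest
            gene = f"{segment}GENE{letters[g]}"
            for idx, c in enumerate(members, start=1):
                c.assigned_name = f"{gene}*{idx:02d}"
            g += 1


def annotate_candidates(
    retained: Sequence[CandidateGermline],
    known_refs: dict[str, str] | None,
    segment: Segment,
    weights: ScoreWeights | None = None,
    v_cut: int = V_NOVEL_CUT,
    j_cut: int = J_NOVEL_CUT,
    mask_terminal: bool = True,
) -> list[GermlineCall]:
    """Score, classify, and name the retained candidates of one segment."""
    if not retained:
        return []
    maxima = cohort_maxima(retained)
    calls: list[GermlineCall] = []
    for c in retained:
        call = classify(c.sequence, known_refs, segment, v_cut, j_cut, mask_terminal)
        call.score = score(c.metrics, len(c.merged_from), maxima, weights, c.is_major)
        call.support_reads = c.support_reads
        call.n_merged = len(c.merged_from)
        call.sample_occurrence = c.sample_occurrence
        call.is_major = c.is_major
        calls.append(call)
    name_novel_genes(calls, v_cut, j_cut)
    # Known alleles keep their reference name; novel alleles take the
    # nearest gene with a fresh allele index.
    per_gene: dict[str, int] = {}
    for call in sorted(calls, key=lambda c: -c.score):
        if call.category == "known":
            call.assigned_name = call.nearest_allele
        elif call.category == "novel_allele":
            gene = call.nearest_allele.split("*")[0]
            per_gene[gene] = per_gene.get(gene, 0) + 1
            call.assigned_name = f"{gene}*n{per_gene[gene]:02d}"
    return calls


ANNOTATION_COLUMNS = [
    "name", "segment", "category", "score", "nearest_allele", "identity",
    "mismatches", "deviated_bases", "support_reads", "n_merged",
    "sample_occurrence",
]


def write_outputs(calls: Sequence[GermlineCall], prefix: str | Path) -> tuple[Path, Path]:
    """Write the inferred-sequence FASTA and the annotation TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_name(prefix.name + ".germline.fasta")
    tsv = prefix.with_name(prefix.name + ".annotation.tsv")
    with open(fasta, "w") as fh:
        for c in calls:
            fh.write(f">{c.assigned_name} score={c.score:.1f}\n{c.sequence}\n")
    rows = [
        {
            "name": c.assigned_name,
            "segment": c.segment,
            "category": c.category,
            "score": round(c.score, 2),
            "nearest_allele": c.nearest_allele or "NA",
            "identity": round(c.identity, 2),
            "mismatches": c.mismatches,
            "deviated_bases": c.deviated_bases,
            "support_reads": c.support_reads,
            "n_merged": c.n_merged,
            "sample_occurrence": c.sample_occurrence,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(tsv, sep="\t", index=False)
    return fasta, tsv
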