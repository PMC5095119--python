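"""Recovery scoring of inferred germline sets against a truth reference.

Each inferred sequence is assigned its nearest truth allele by maximal
ungapped identity (ties: fewer mismatches, then name).  A call is *correct*
when identity exceeds 90% and the junction-facing terminus deviates by at
most 5 bases; it is an *exact* recovery when it equals the source allele
base for base.  Mean identity / deviation / mismatch summaries follow the
correct-calls-only convention, with all-call means reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd

from ._align import align_to_reference

__all__ = ["EvalRecord", "EvalSummary", "evaluate", "read_fasta", "summary_row"]

IDENTITY_CUT = 90.0
DEVIATION_CUT = 5


@dataclass(frozen=True)
class EvalRecord:
    name: str
    sequence: str
    nearest: str
    identity: float
    mismatches: int
    deviated_bases: int
    correct: bool
    exact: bool


@dataclass(frozen=True)
class EvalSummary:
    n_predicted: int
    n_correct: int
    accuracy: float  # % of predictions that are correct
    mean_identity: float  # means over correct calls only
    mean_abs_deviated: float
    mean_mismatch: float
    all_mean_identity: float  # means over every call
    all_mean_abs_deviated: float
    all_mean_mismatch: float
    genes_recovered: int
    genes_total: int
    n_exact: int
    exact_fraction: float  # fraction of predictions recovered base-exactly


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def _gene(name: str) -> str:
    return name.split("*")[0]


def evaluate(
    inferred: dict[str, str] | Sequence[tuple[str, str]],
    truth: dict[str, str],
    segment: Literal["V", "J"] = "V",
) -> tuple[list[EvalRecord], EvalSummary]:
    """Score an inferred set against truth alleles of the same segment."""
    if not truth:
        raise ValueError("truth set must be non-empty")
    items = sorted(inferred.items()) if isinstance(inferred, dict) else list(inferred)
    records: list[EvalRecord] = []
    for name, seq in items:
        seq = seq.upper()
        best = None
        for ref_name in sorted(truth):
            ref = truth[ref_name].upper()
            aln, dev = align_to_reference(seq, ref, segment)
            key = (-aln.identity, aln.mismatches, ref_name)
            if best is None or key < best[0]:
                best = (key, ref_name, aln, dev, ref)
        _, ref_name, aln, dev, ref = best
        correct = aln.identity > IDENTITY_CUT and abs(dev) <= DEVIATION_CUT
        records.append(
            EvalRecord(name=name, sequence=seq, nearest=ref_name, identity=aln.identity,
                       mismatches=aln.mismatches, deviated_bases=dev, correct=correct,
                       exact=(seq == ref))
        )
    n = len(records)
    good = [r for r in records if r.correct]

    def _mean(rows, get):
        return sum(get(r) for r in rows) / len(rows) if rows else 0.0

    summary = EvalSummary(
        n_predicted=n,
        n_correct=len(good),
        accuracy=100.0 * len(good) / n if n else 0.0,
        mean_identity=_mean(good, lambda r: r.identity),
        mean_abs_deviated=_mean(good, lambda r: abs(r.deviated_bases)),
        mean_mismatch=_mean(good, lambda r: r.mismatches),
        all_mean_identity=_mean(records, lambda r: r.identity),
        all_mean_abs_deviated=_mean(records, lambda r: abs(r.deviated_bases)),
        all_mean_mismatch=_mean(records, lambda r: r.mismatches),
        genes_recovered=len({_gene(r.nearest) for r in good}),
        genes_total=len({_gene(name) for name in truth}),
        n_exact=sum(r.exact for r in records),
        exact_fraction=sum(r.exact for r in records) / n if n else 0.0,
    )
    return records, summary


def summary_row(summary: EvalSummary, label: str = "") -> str:
    """One evaluation summary formatted as a table row."""
    return (
        f"{label}\t{summary.n_predicted}\t{summary.n_correct} ({summary.accuracy:.1f})"
        f"\t{summary.mean_identity:.1f}\t{summary.mean_abs_deviated:.1f}"
        f"\t{summary.mean_mismatch:.1f}\t{summary.n_exact}"
    )


def write_records_tsv(records: Sequence[EvalRecord], path) -> Path:
    path = Path(path)
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)
    return path
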