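"""End-to-end germline inference: partition -> cluster -> assemble ->
optimize -> annotate, run independently for the V and the J side."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import annotate as _annotate
from . import assembly as _assembly
from . import optimize as _optimize
from . import preprocess as _pre
from . import seedclust as _seedclust
from .annotate import GermlineCall, ScoreWeights
from .optimize import CandidateGermline, FilterThresholds

__all__ = ["PipelineParams", "InferenceResult", "infer_repertoire", "infer_samples"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    # data processing
    jm: int = 60
    vm: int = 40
    min_part_len: int = 30
    c_refs: Optional[list[str]] = None  # None: reads are pre-oriented forward
    c_max_mismatch: int = 2
    c_probe_len: int = 18
    # clustering
    v_seed_len: int = 40
    j_seed_len: int = 20
    min_cluster_reads: int = 10
    scorer: str = "count"
    # assembly
    ar_v: float = 0.15
    ur_v: float = 0.12
    ar_j: float = 0.12
    ur_j: float = 0.10
    min_extend_cov: int = 2
    min_branch_unique: int = 3
    max_paths: int = 16
    # optimization
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    chain: Optional[str] = None  # e.g. "TRB": relaxes the J Trim5 Rate gate
    group_dist_v: int = 3
    group_dist_j: int = 2
    ratio_cap: float = 10.0
    # annotation
    known_v: Optional[dict[str, str]] = None
    known_j: Optional[dict[str, str]] = None
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    v_novel_cut: int = 7
    j_novel_cut: int = 5
    mask_terminal: bool = True

    def assembly_thresholds(self) -> dict[str, tuple[float, float]]:
        return {"V": (self.ar_v, self.ur_v), "J": (self.ar_j, self.ur_j)}


@dataclass
class InferenceResult:
    v_calls: list[GermlineCall]
    j_calls: list[GermlineCall]
    stats: dict = field(default_factory=dict)

    @property
    def calls(self) -> list[GermlineCall]:
        return self.v_calls + self.j_calls

    def sequences(self, segment: Optional[str] = None) -> set[str]:
        calls = self.calls if segment is None else (
            self.v_calls if segment == "V" else self.j_calls
        )
        return {c.sequence for c in calls}


def _infer_segment(
    parts: list[str], segment: str, params: PipelineParams, stats: dict
) -> list[GermlineCall]:
    unique = _pre.dedupe(p for p in parts if len(p) >= params.min_part_len)
    k = params.v_seed_len if segment == "V" else params.j_seed_len
    clusters, residue = _seedclust.extract_clusters(
        unique, k, segment, params.min_cluster_reads, params.scorer
    )
    stats[f"{segment}_unique_reads"] = len(unique)
    stats[f"{segment}_clusters"] = len(clusters)
    stats[f"{segment}_residue_unique"] = len(residue)
    candidates: list[CandidateGermline] = []
    for cluster in clusters:
        tree = _assembly.build_tree(cluster)
        paths = _assembly.assemble(
            tree,
            thresholds=params.assembly_thresholds(),
            segment=segment,
            min_extend_cov=params.min_extend_cov,
            max_paths=params.max_paths,
            min_branch_unique=params.min_branch_unique,
        )
        reads = [r for r, _ in cluster.members]
        for p in paths:
            if len(p.sequence) <= _optimize.TRIM:
                continue
            candidates.append(
                CandidateGermline(sequence=p.sequence, segment=segment, cluster_reads=reads)
            )
    stats[f"{segment}_assembled"] = len(candidates)
    if not candidates:
        return []
    _optimize.cohort_metrics(candidates)
    kept, _ = _optimize.filter_fp(candidates, params.thresholds, params.chain)
    stats[f"{segment}_fp_filtered"] = len(candidates) - len(kept)
    merged = _optimize.merge_redundant(kept, segment)
    stats[f"{segment}_after_merge"] = len(merged)
    group_dist = params.group_dist_v if segment == "V" else params.group_dist_j
    retained = _optimize.shm_filter(merged, segment, params.ratio_cap, group_dist)
    stats[f"{segment}_retained"] = len(retained)
    known = params.known_v if segment == "V" else params.known_j
    return _annotate.annotate_candidates(
        retained, known, segment, params.weights,
        params.v_novel_cut, params.j_novel_cut, params.mask_terminal,
    )


def infer_repertoire(
    seqs: Iterable[str], params: PipelineParams | None = None
) -> InferenceResult:
    """Infer germline V and J sequences from forward-oriented rearranged
    reads (run C-region detection first when orientation is unknown)."""
    params = params or PipelineParams()
    stats: dict = {"n_input": 0, "n_short": 0, "n_no_c": 0}
    v_parts: list[str] = []
    j_parts: list[str] = []
    for seq in seqs:
        stats["n_input"] += 1
        seq = seq.upper()
        if params.c_refs:
            oriented = _pre.detect_and_trim_c(
                seq, params.c_refs, params.c_max_mismatch, params.c_probe_len
            )
            if oriented is None:
                stats["n_no_c"] += 1
                continue
            seq = oriented
        part = _pre.partition(seq, params.jm, params.vm)
        if part is None:
            stats["n_short"] += 1
            continue
        v_parts.append(part.v_part)
        j_parts.append(part.j_part)
    v_calls = _infer_segment(v_parts, "V", params, stats)
    j_calls = _infer_segment(j_parts, "J", params, stats)
    return InferenceResult(v_calls=v_calls, j_calls=j_calls, stats=stats)


def infer_samples(
    samples: Sequence[Iterable[str]],
    params: PipelineParams | None = None,
    min_samples: int = 1,
) -> list[InferenceResult]:
    """Run inference per sample and annotate each call with the number of
    samples its sequence was inferred in; calls seen in fewer than
    ``min_samples`` samples are dropped from every result."""
    results = [infer_repertoire(s, params) for s in samples]
    for segment in ("V", "J"):
        occurrence: dict[str, int] = {}
        for res in results:
            calls = res.v_calls if segment == "V" else res.j_calls
            for seq in {c.sequence for c in calls}:
                occurrence[seq] = occurrence.get(seq, 0) + 1
        for res in results:
            calls = res.v_calls if segment == "V" else res.j_calls
            kept = []
            for c in calls:
                c.sample_occurrence = occurrence[c.sequence]
                if c.sample_occurrence >= min_samples:
                    kept.append(c)
            if segment == "V":
                res.v_calls = kept
            else:
                res.j_calls = kept
    return results
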