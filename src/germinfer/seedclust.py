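"""Seed_Clust: greedy k-mer seed clustering of unique reads.

Reads that originate from the same germline segment share long exact
substrings even in the presence of scattered mutations, so a k-mer "seed"
shared by many reads marks a cluster of common origin.  Seeds are
enumerated from each read's germline-confident region (the junction-facing
margin is excluded), every seed is scored by the abundance of the reads
containing it, and clusters are peeled off greedily: the top-scoring seed
defines a cluster, its reads are removed, scores are updated, and the loop
repeats until no remaining seed gathers enough reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .preprocess import UniqueRead

__all__ = ["SeedIndex", "Cluster", "enumerate_seeds", "seed_score", "extract_clusters"]

logger = logging.getLogger(__name__)

# Junction-facing margins excluded from seed creation: the last 10 bases of
# a V part and the first 5 bases of a J part may belong to the junction
# rather than the germline segment.
V_TAIL_EXCLUDE = 10
J_HEAD_EXCLUDE = 5

Segment = Literal["V", "J"]


@dataclass
class SeedIndex:
    """Maps each eligible k-mer to the set of unique-read indices containing
    it (plain substring containment, anywhere in the read)."""

    seeds: dict[str, set[int]]
    k: int
    segment: Segment


@dataclass
class Cluster:
    seed: str
    members: list[tuple[UniqueRead, int]]  # (read, offset of seed in read)
    score: float

    @property
    def n_reads(self) -> int:
        return sum(r.count for r, _ in self.members)

    @property
    def n_unique(self) -> int:
        return len(self.members)


def _eligible_starts(length: int, k: int, segment: Segment) -> range:
    if segment == "V":
        return range(0, length - V_TAIL_EXCLUDE - k + 1)
    return range(J_HEAD_EXCLUDE, length - k + 1)


def enumerate_seeds(reads: Sequence[UniqueRead], k: int, segment: Segment) -> SeedIndex:
    """Build the seed index.  Seeds are drawn only from eligible positions
    (see module constants) and never contain N; membership, however, is
    plain substring containment anywhere in the read."""
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible: set[str] = set()
    for r in reads:
        for p in _eligible_starts(len(r.seq), k, segment):
            km = r.seq[p : p + k]
            if "N" not in km:
                eligible.add(km)
    if not eligible:
        logger.warning("no eligible %s seeds at k=%d", segment, k)
    seeds: dict[str, set[int]] = {km: set() for km in eligible}
    for i, r in enumerate(reads):
        s = r.seq
        for p in range(len(s) - k + 1):
            km = s[p : p + k]
            members = seeds.get(km)
            if members is not None:
                members.add(i)
    return SeedIndex(seeds=seeds, k=k, segment=segment)


def seed_score(
    index: SeedIndex,
    seed: str,
    counts: Sequence[int],
    scorer: str = "count",
    live: Sequence[int] | None = None,
) -> float:
    """Score T for one seed over the live read set.

    ``count`` sums the abundances of the reads containing the seed.
    ``matrix`` additionally lets every non-containing live read contribute
    0.2 x its abundance; since that term is shared across seeds at a given
    iteration the two scorers rank seeds identically.
    """
    if seed not in index.seeds:
        raise KeyError(seed)
    live_set = set(live) if live is not None else set(range(len(counts)))
    members = index.seeds[seed] & live_set
    contained = sum(counts[i] for i in members)
    if scorer == "count":
        return float(contained)
    if scorer == "matrix":
        total = sum(counts[i] for i in live_set)
        return float(contained + 0.2 * (total - contained))
    raise ValueError(f"unknown scorer {scorer!r}")


def extract_clusters(
    reads: Sequence[UniqueRead],
    k: int,
    segment: Segment,
    min_cluster_reads: int = 10,
    scorer: str = "count",
) -> tuple[list[Cluster], list[int]]:
    """Greedy cluster extraction.

    Repeatedly takes the seed with the highest score over the still-live
    reads (ties broken by lexicographically smallest seed), emits the live
    reads containing it as one cluster, removes them, and decrements every
    affected seed's score.  Stops when the best cluster would hold fewer
    than ``min_cluster_reads`` reads; leftover reads are returned as the
    unclustered residue.  The incremental score updates are exactly
    equivalent to full recomputation.
    """
    if scorer not in ("count", "matrix"):
        raise ValueError(f"unknown scorer {scorer!r}")
    n = len(reads)
    if n == 0:
        return [], []

    # Seed enumeration (eligible windows only), then a containment pass.
    kmer_id: dict[str, int] = {}
    for r in reads:
        s = r.seq
        for p in _eligible_starts(len(s), k, segment):
            km = s[p : p + k]
            if "N" not in km and km not in kmer_id:
                kmer_id[km] = len(kmer_id)
    if not kmer_id:
        logger.warning("no eligible %s seeds at k=%d; all reads residual", segment, k)
        return [], list(range(n))
    per_read_ids: list[np.ndarray] = []
    for r in reads:
        s = r.seq
        ids = {kmer_id[s[p : p + k]] for p in range(len(s) - k + 1) if s[p : p + k] in kmer_id}
        per_read_ids.append(np.fromiter(ids, dtype=np.int64, count=len(ids)))

    counts = np.array([r.count for r in reads], dtype=np.int64)
    scores = np.zeros(len(kmer_id), dtype=np.int64)
    for i in range(n):
        scores[per_read_ids[i]] += counts[i]
    kmers = list(kmer_id)  # id -> string

    live = np.ones(n, dtype=bool)
    live_total = int(counts.sum())
    clusters: list[Cluster] = []
    while True:
        best = int(scores.max(initial=0))
        if best < min_cluster_reads or best <= 0:
            break
        tied = np.flatnonzero(scores == best)
        seed = min(kmers[i] for i in tied)
        member_idx = [i for i in np.flatnonzero(live) if seed in reads[i].seq]
        if scorer == "matrix":
            t = best + 0.2 * (live_total - best)
        else:
            t = float(best)
        clusters.append(
            Cluster(
                seed=seed,
                members=[(reads[i], reads[i].seq.find(seed)) for i in member_idx],
                score=t,
            )
        )
        for i in member_idx:
            scores[per_read_ids[i]] -= counts[i]
            live[i] = False
            live_total -= int(counts[i])
    residue = [int(i) for i in np.flatnonzero(live)]
    return clusters, residue
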