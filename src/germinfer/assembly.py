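"""Seed-anchored consensus assembly over a per-cluster position tree.

Every cluster member contains the cluster seed exactly, so members can be
laid on a common coordinate system anchored at the seed (relative positions
0..k-1 for the seed itself, negative upstream, >= k downstream).  A
multiway position tree tallies, per position, the read and unique-read
support of each nucleotide.  Assembly starts from the seed and grows one
nucleotide at a time; a candidate base j at frontier position i is accepted
only when both support fractions clear their thresholds:

    Ar(i,j) = reads supporting the extended sequence / reads covering i
    Ur(i,j) = unique reads supporting it / unique reads covering i

A read *supports* the extended sequence when it carries j at i and agrees
with the path over the trailing ``support_window`` bases next to the
frontier (15 by default).  The window makes support path-dependent where it
matters - a read that just disagreed with the path cannot push it further,
which stops extension cold once the frontier leaves the germline segment
and enters read-specific junction sequence - while letting reads with a
scattered mutation elsewhere still vote, so a segment longer than the
typical mutation-free stretch of any single read can still be assembled.
Reads that end before position i drop out of both numerator and
denominator.  Several bases may pass at one position, in which case the
path forks and every qualified extension is pursued; low-frequency
variation (somatic hypermutation, PCR and sequencing error) fails the
gates and is filtered here for free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .seedclust import Cluster

__all__ = ["PositionTree", "ExtensionPath", "build_tree", "ar", "ur", "assemble",
           "DEFAULT_THRESHOLDS", "SUPPORT_WINDOW"]

logger = logging.getLogger(__name__)

#: (Ar, Ur) acceptance thresholds per segment; an extension must exceed both.
DEFAULT_THRESHOLDS: dict[str, tuple[float, float]] = {
    "V": (0.15, 0.12),
    "J": (0.12, 0.10),
}

#: Trailing path window (bases) over which a supporting read must agree
#: with the path, frontier included.
SUPPORT_WINDOW = 15

_BASES = "ACGT"


class PositionTree:
    """Per-cluster tally of nucleotide support on seed-anchored coordinates.

    ``coverage[p]`` is ``(reads, unique_reads)`` covering relative position
    p; ``branches[p][base]`` the same restricted to reads showing ``base``
    at p.  Positions nobody covers are absent.
    """

    def __init__(self, seed: str, members: Sequence[tuple[str, int, int]]):
        self.seed = seed
        self.k = len(seed)
        self.members = list(members)  # (seq, seed_offset, count)
        cov: dict[int, list[int]] = {}
        br: dict[int, dict[str, list[int]]] = {}
        for seq, off, count in self.members:
            for p in range(-off, len(seq) - off):
                c = cov.setdefault(p, [0, 0])
                c[0] += count
                c[1] += 1
                b = br.setdefault(p, {}).setdefault(seq[p + off], [0, 0])
                b[0] += count
                b[1] += 1
        self.coverage: dict[int, tuple[int, int]] = {p: (c[0], c[1]) for p, c in cov.items()}
        self.branches: dict[int, dict[str, tuple[int, int]]] = {
            p: {b: (v[0], v[1]) for b, v in d.items()} for p, d in br.items()
        }

    def covers(self, m: int, pos: int) -> bool:
        seq, off, _ = self.members[m]
        return -off <= pos < len(seq) - off

    def base_at(self, m: int, pos: int) -> str:
        seq, off, _ = self.members[m]
        return seq[pos + off]


@dataclass
class ExtensionPath:
    """An accepted assembly path: the seed plus every accepted extension."""

    sequence: str
    left: int  # leftmost relative position (inclusive)
    right: int  # rightmost relative position (exclusive)
    steps: list[tuple[int, str, float, float]]  # (position, base, Ar, Ur)
    support_reads: int = 0  # reads agreeing with the path at every covered position
    support_unique: int = 0
    min_ar: float = 1.0


def build_tree(cluster: Cluster) -> PositionTree:
    """Align cluster members on the seed and tally per-position support."""
    members = []
    for read, off in cluster.members:
        if read.seq[off : off + len(cluster.seed)] != cluster.seed:
            raise ValueError(f"cluster member does not contain seed at offset {off}")
        members.append((read.seq, off, read.count))
    return PositionTree(cluster.seed, members)


def _window_positions(path_left: int, path_right: int, i: int, window: int) -> range:
    """Path positions a supporting read must match, next to frontier i."""
    if i >= path_right:  # rightward extension
        return range(max(path_left, i - window + 1), path_right)
    return range(path_left, min(path_right, i + window))  # leftward


def _support(tree: PositionTree, path: "ExtensionPath", i: int, j: str,
             window: int = SUPPORT_WINDOW) -> tuple[int, int]:
    """Reads/unique reads covering i, carrying j there, and agreeing with
    the path over the trailing window."""
    win = _window_positions(path.left, path.right, i, window)
    reads = uniq = 0
    for m, (seq, off, count) in enumerate(tree.members):
        if not tree.covers(m, i) or seq[i + off] != j:
            continue
        ok = True
        for p in win:
            if tree.covers(m, p) and seq[p + off] != path.sequence[p - path.left]:
                ok = False
                break
        if ok:
            reads += count
            uniq += 1
    return reads, uniq


def ar(tree: PositionTree, path: ExtensionPath, i: int, j: str,
       window: int = SUPPORT_WINDOW) -> Optional[float]:
    """Read-count support fraction for extending ``path`` with ``j`` at
    ``i``; ``None`` when no read covers position i."""
    cov = tree.coverage.get(i)
    if cov is None or cov[0] == 0:
        return None
    return _support(tree, path, i, j, window)[0] / cov[0]


def ur(tree: PositionTree, path: ExtensionPath, i: int, j: str,
       window: int = SUPPORT_WINDOW) -> Optional[float]:
    """Unique-read support fraction; ``None`` when no read covers i."""
    cov = tree.coverage.get(i)
    if cov is None or cov[1] == 0:
        return None
    return _support(tree, path, i, j, window)[1] / cov[1]


def _full_path_support(tree: PositionTree, left: int, right: int, sequence: str) -> tuple[int, int]:
    reads = uniq = 0
    for m, (seq, off, count) in enumerate(tree.members):
        lo = max(left, -off)
        hi = min(right, len(seq) - off)
        if all(seq[p + off] == sequence[p - left] for p in range(lo, hi)):
            reads += count
            uniq += 1
    return reads, uniq


def assemble(
    tree: PositionTree,
    thresholds: dict[str, tuple[float, float]] | None = None,
    segment: Literal["V", "J"] = "V",
    min_extend_cov: int = 2,
    max_paths: int = 16,
    window: int = SUPPORT_WINDOW,
    min_branch_unique: int = 3,
) -> list[ExtensionPath]:
    """Grow every qualified path outward from the seed.

    V assembly extends 3'-ward (right subtree, toward the junction) first
    and then 5'-ward; J mirrors this, junction side first.  At a frontier
    position all four bases are examined before descending; each base whose
    Ar and Ur strictly exceed the segment thresholds spawns a path.  A
    direction terminates when no base qualifies or coverage falls below
    ``min_extend_cov``.  Besides the fractional gates, an extension must be
    observed in at least ``min_branch_unique`` distinct unique reads:
    branches carried by one or two molecules cannot be told apart from
    mutation or error noise.  If more than ``max_paths`` maximal paths emerge the
    set is pruned to the paths with the highest minimum per-step Ar.
    """
    th_ar, th_ur = (thresholds or DEFAULT_THRESHOLDS)[segment]
    if not tree.members:
        raise ValueError("empty tree")
    order = ("R", "L") if segment == "V" else ("L", "R")
    hard_cap = max(4 * max_paths, max_paths)
    results: list[ExtensionPath] = []
    truncated = False
    n_members = len(tree.members)
    NONE = -(10**9)

    # Per member we track the rightmost (max_mm) and leftmost (min_mm)
    # position at which it disagrees with the current path: a member
    # supports a rightward extension at i only when max_mm <= i - window,
    # and a leftward one only when min_mm >= i + window.
    def run(left: int, right: int, sequence: str, steps,
            max_mm: list[int], min_mm: list[int], phase: int, min_ar: float) -> None:
        nonlocal truncated
        while True:
            if len(results) >= hard_cap:
                truncated = True
                return
            rightward = order[phase] == "R"
            i = right if rightward else left - 1
            cov = tree.coverage.get(i, (0, 0))
            cands: list[tuple[str, float, float]] = []
            if cov[0] >= min_extend_cov:
                tally: dict[str, list[int]] = {}
                for m in range(n_members):
                    if not tree.covers(m, i):
                        continue
                    if rightward:
                        if max_mm[m] > i - window:
                            continue
                    elif min_mm[m] < i + window:
                        continue
                    b = tree.base_at(m, i)
                    t = tally.setdefault(b, [0, 0])
                    t[0] += tree.members[m][2]
                    t[1] += 1
                for b in _BASES:
                    t = tally.get(b)
                    if t is None:
                        continue
                    a = t[0] / cov[0]
                    u = t[1] / cov[1]
                    if a > th_ar and u > th_ur and t[1] >= min_branch_unique:
                        cands.append((b, a, u))
            if not cands:
                if phase + 1 < len(order):
                    phase += 1
                    continue
                sup_r, sup_u = _full_path_support(tree, left, right, sequence)
                results.append(
                    ExtensionPath(sequence, left, right, list(steps),
                                  support_reads=sup_r, support_unique=sup_u,
                                  min_ar=min_ar)
                )
                return

            def advanced(b: str) -> tuple:
                nseq = sequence + b if rightward else b + sequence
                nl, nr = (left, right + 1) if rightward else (left - 1, right)
                nmax, nmin = list(max_mm), list(min_mm)
                for m in range(n_members):
                    if tree.covers(m, i) and tree.base_at(m, i) != b:
                        nmax[m] = max(nmax[m], i)
                        nmin[m] = min(nmin[m], i)
                return nl, nr, nseq, nmax, nmin

            if len(cands) == 1:
                b, a, u = cands[0]
                left, right, sequence, max_mm, min_mm = advanced(b)
                steps = steps + [(i, b, a, u)]
                min_ar = min(min_ar, a)
                continue
            for b, a, u in cands:
                nl, nr, nseq, nmax, nmin = advanced(b)
                run(nl, nr, nseq, steps + [(i, b, a, u)], nmax, nmin, phase, min(min_ar, a))
            return

    run(0, tree.k, tree.seed, [], [NONE] * n_members, [-NONE] * n_members, 0, 1.0)
    if truncated:
        logger.warning("assembly path explosion for seed %s...: exploration truncated "
                       "at %d paths", tree.seed[:12], hard_cap)
    if len(results) > max_paths:
        logger.warning("pruning %d assembly paths to max_paths=%d by minimum Ar",
                       len(results), max_paths)
        results = sorted(results, key=lambda p: (-p.min_ar, p.sequence))[:max_paths]
    return results
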