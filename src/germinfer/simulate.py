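"""Synthetic rearranged-repertoire generator with full truth labels.

Each synthetic read mimics one V(D)J recombination event: a V allele with a
junctional 3' deletion, random non-templated insertions (optionally
flanking a D stub), and a J allele with a 5' deletion.  Deletion lengths
follow truncated geometric distributions with the mass concentrated at 0-1
bases, matching the observed tendency of junctional deletions to become
rarer with length (for V, more than half of rearrangements delete at most
1 base).  Three mutation layers are then applied in order, each recorded in
the truth set: per-base sequencing error on every read, random somatic
hypermutation on a configurable fraction of reads, and per-allele
"hotspot" substitutions where a fixed fraction of an allele's reads share
one identical mutation - the hardest artifact to distinguish from a real
novel allele.  Replaying the recorded events on the clean rearrangement
reproduces every emitted read exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "SimRead",
    "TruthSet",
    "make_germline_set",
    "simulate_rearrangements",
    "apply_mutations",
    "simulate_repertoire",
    "spike_in",
    "write_reads_fasta",
]

_BASES = np.array(list("ACGT"))
_ALT = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are per-base probabilities unless noted.  ``shm_fraction`` is the
    fraction of reads that receive random SHM at ``shm_rate``;
    ``hotspot_rate`` is the fraction of each V allele's reads sharing that
    allele's fixed substitution.
    """

    n_reads: int = 100_000
    seq_error_rate: float = 0.005
    shm_fraction: float = 0.8
    shm_rate: float = 0.01
    hotspot_rate: float = 0.0
    v_del_decay: float = 0.30  # P(deletion length L) ~ (1-q)^L, truncated
    v_del_max: int = 10
    j_del_decay: float = 0.25
    j_del_max: int = 15
    ins_decay: float = 0.12  # per insertion zone; junctions carry two zones
    ins_max: int = 12  # cap per zone
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("seq_error_rate", "shm_fraction", "shm_rate", "hotspot_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass
class SimRead:
    id: str
    v_name: str
    j_name: str
    v_del: int
    j_del: int
    insert: str
    clean_seq: str
    seq: str
    events: list[tuple[int, str, str, str]] = field(default_factory=list)  # (pos, from, to, class)
    spiked: bool = False


@dataclass
class TruthSet:
    """Per-read provenance: source alleles, junction lengths, and the full
    ordered mutation history (classes: seqerr, shm, hotspot)."""

    records: list[SimRead]
    v_alleles: dict[str, str]
    j_alleles: dict[str, str]
    hotspots: dict[str, tuple[int, str]] = field(default_factory=dict)  # allele -> (pos, to)

    def replay_ok(self) -> bool:
        """True iff applying each read's events to its clean rearrangement
        reproduces the emitted sequence exactly."""
        for r in self.records:
            s = list(r.clean_seq)
            for pos, _frm, to, _cls in r.events:
                s[pos] = to
            if "".join(s) != r.seq:
                return False
        return True

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tv_allele\tj_allele\tv_del\tj_del\tinsert\tspiked\tevents\n")
            for r in self.records:
                ev = ";".join(f"{p}:{f}>{t}:{c}" for p, f, t, c in r.events)
                fh.write(f"{r.id}\t{r.v_name}\t{r.j_name}\t{r.v_del}\t{r.j_del}"
                         f"\t{r.insert or '.'}\t{int(r.spiked)}\t{ev or '.'}\n")


def _trunc_geom(rng: np.random.Generator, q: float, cap: int, size: int) -> np.ndarray:
    """Sample lengths with P(L) proportional to (1-q)^L for L = 0..cap."""
    probs = (1.0 - q) ** np.arange(cap + 1)
    probs /= probs.sum()
    return rng.choice(cap + 1, size=size, p=probs)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_germline_set(
    n_v: int = 20,
    n_j: int = 10,
    v_len: int = 150,
    j_len: int = 50,
    seed: int | np.random.Generator | None = 0,
    prefix: str = "SYN",
) -> tuple[dict[str, str], dict[str, str]]:
    """A synthetic germline allele panel of random sequences.  Random
    sequences of these lengths are pairwise ~75% divergent, i.e. they model
    distinct genes; allelic variants can be derived by substituting a few
    bases of an existing allele."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = {f"{prefix}V{i + 1:02d}*01": _random_seq(rng, v_len) for i in range(n_v)}
    j = {f"{prefix}J{i + 1:02d}*01": _random_seq(rng, j_len) for i in range(n_j)}
    return v, j


def simulate_rearrangements(
    v_alleles: dict[str, str],
    j_alleles: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    d_alleles: dict[str, str] | None = None,
    id_prefix: str = "read",
) -> list[SimRead]:
    """Draw clean rearrangements (no mutations yet): V allele with 3'
    deletion + insert (+ optional D stub) + J allele with 5' deletion.
    Allele usage is uniform.  Deterministic given the generator state."""
    if not v_alleles or not j_alleles:
        raise ValueError("need at least one V and one J allele")
    rng = rng or np.random.default_rng(config.seed)
    v_names = sorted(v_alleles)
    j_names = sorted(j_alleles)
    n = config.n_reads
    vi = rng.integers(0, len(v_names), size=n)
    ji = rng.integers(0, len(j_names), size=n)
    v_dels = _trunc_geom(rng, config.v_del_decay, config.v_del_max, n)
    j_dels = _trunc_geom(rng, config.j_del_decay, config.j_del_max, n)
    # Two non-templated addition zones per junction (V-D and D-J), so a
    # junction with zero inserted bases is rare, as in real rearrangements.
    ins_lens = (_trunc_geom(rng, config.ins_decay, config.ins_max, n)
                + _trunc_geom(rng, config.ins_decay, config.ins_max, n))
    d_names = sorted(d_alleles) if d_alleles else None
    reads: list[SimRead] = []
    for i in range(n):
        vn, jn = v_names[vi[i]], j_names[ji[i]]
        vseq = v_alleles[vn]
        jseq = j_alleles[jn]
        vd = int(min(v_dels[i], len(vseq) - 1))
        jd = int(min(j_dels[i], len(jseq) - 1))
        insert = _random_seq(rng, int(ins_lens[i]))
        if d_names:
            dn = d_names[rng.integers(0, len(d_names))]
            dseq = d_alleles[dn]
            d5 = int(rng.integers(0, len(dseq) // 2 + 1))
            d3 = int(rng.integers(0, (len(dseq) - d5) // 2 + 1))
            half = len(insert) // 2
            middle = insert[:half] + dseq[d5 : len(dseq) - d3] + insert[half:]
        else:
            middle = insert
        clean = vseq[: len(vseq) - vd] + middle + jseq[jd:]
        reads.append(
            SimRead(id=f"{id_prefix}{i}", v_name=vn, j_name=jn, v_del=vd, j_del=jd,
                    insert=middle, clean_seq=clean, seq=clean)
        )
    return reads


def apply_mutations(
    reads: list[SimRead],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    v_alleles: dict[str, str] | None = None,
) -> dict[str, tuple[int, str]]:
    """Mutate reads in place: sequencing error on all reads, random SHM on
    ``shm_fraction`` of reads, then one shared hotspot substitution per V
    allele on ``round(hotspot_rate x n_allele_reads)`` of that allele's
    reads.  Later events overwrite earlier bases at the same position; the
    truth history keeps every event.  Returns the hotspot map
    (allele -> (position, target base))."""
    rng = rng or np.random.default_rng(config.seed)
    n = len(reads)

    def _mutate(read: SimRead, positions, cls: str) -> None:
        s = list(read.seq)
        for pos in positions:
            frm = s[pos]
            if frm not in _ALT:
                continue
            to = _ALT[frm][rng.integers(0, 3)]
            read.events.append((int(pos), frm, to, cls))
            s[pos] = to
        read.seq = "".join(s)

    if config.seq_error_rate > 0:
        for read in reads:
            hits = np.flatnonzero(rng.random(len(read.seq)) < config.seq_error_rate)
            if hits.size:
                _mutate(read, hits, "seqerr")

    if config.shm_rate > 0 and config.shm_fraction > 0:
        n_shm = round(config.shm_fraction * n)
        chosen = rng.choice(n, size=n_shm, replace=False)
        for idx in chosen:
            read = reads[idx]
            hits = np.flatnonzero(rng.random(len(read.seq)) < config.shm_rate)
            if hits.size:
                _mutate(read, hits, "shm")

    hotspots: dict[str, tuple[int, str]] = {}
    if config.hotspot_rate > 0:
        if v_alleles is None:
            raise ValueError("hotspot mutations require the V allele sequences")
        by_allele: dict[str, list[int]] = {}
        for i, read in enumerate(reads):
            by_allele.setdefault(read.v_name, []).append(i)
        for vn in sorted(by_allele):
            ids = by_allele[vn]
            vseq = v_alleles[vn]
            # Keep the hotspot clear of the junction-deleted span so every
            # read of the allele can carry it.
            hi = len(vseq) - max(config.v_del_max, 3) - TRIM_GUARD
            pos = int(rng.integers(0, max(hi, 1)))
            to = _ALT[vseq[pos]][rng.integers(0, 3)]
            hotspots[vn] = (pos, to)
            n_carriers = round(config.hotspot_rate * len(ids))
            carriers = rng.choice(len(ids), size=n_carriers, replace=False)
            for c in carriers:
                read = reads[ids[c]]
                frm = read.seq[pos]
                read.events.append((pos, frm, to, "hotspot"))
                read.seq = read.seq[:pos] + to + read.seq[pos + 1 :]
    return hotspots


TRIM_GUARD = 5


def simulate_repertoire(
    v_alleles: dict[str, str],
    j_alleles: dict[str, str],
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
    d_alleles: dict[str, str] | None = None,
) -> TruthSet:
    """Full protocol: rearrangement followed by the three mutation layers."""
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    reads = simulate_rearrangements(v_alleles, j_alleles, config, rng, d_alleles)
    hotspots = apply_mutations(reads, config, rng, v_alleles)
    return TruthSet(records=reads, v_alleles=dict(v_alleles), j_alleles=dict(j_alleles),
                    hotspots=hotspots)


def spike_in(
    base: TruthSet,
    novel_v: dict[str, str],
    config: SimConfig | None = None,
    seed: int | np.random.Generator | None = 0,
    n_reads_per_novel: int = 1000,
) -> TruthSet:
    """Simulate reads from novel V sequences (recombined with the base J
    panel) and append them to the base repertoire, marked as spiked.
    Defaults follow the spike-in protocol: 0.5% sequencing error, 1% SHM."""
    if not novel_v:
        return TruthSet(records=list(base.records), v_alleles=dict(base.v_alleles),
                        j_alleles=dict(base.j_alleles), hotspots=dict(base.hotspots))
    cfg = config or SimConfig(seq_error_rate=0.005, shm_rate=0.01)
    cfg = replace(cfg, n_reads=n_reads_per_novel, hotspot_rate=0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spiked_records: list[SimRead] = []
    for k, vn in enumerate(sorted(novel_v)):
        reads = simulate_rearrangements({vn: novel_v[vn]}, base.j_alleles, cfg, rng,
                                        id_prefix=f"spike{k}_")
        apply_mutations(reads, cfg, rng, {vn: novel_v[vn]})
        for r in reads:
            r.spiked = True
        spiked_records.extend(reads)
    merged_v = dict(base.v_alleles)
    merged_v.update(novel_v)
    return TruthSet(records=list(base.records) + spiked_records, v_alleles=merged_v,
                    j_alleles=dict(base.j_alleles), hotspots=dict(base.hotspots))


def write_reads_fasta(truth: TruthSet, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in truth.records:
            fh.write(f">{r.id}\n{r.seq}\n")
    return path
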