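import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import germinfer as g
from germinfer.preprocess import UniqueRead
from germinfer.seedclust import Cluster

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_worked_cluster() -> Cluster:
    """The 10-read worked cluster: all reads share the 4-mer seed GGCC;
    7 reads extend past it (3 of them with A; the A reads collapse to 2
    unique sequences) and 3 reads stop at the seed.  After deduplication
    6 unique reads cover the extension position, 2 of them with A."""
    raw = (
        ["GGCCA"] * 2          # A at the extension position (duplicated pair)
        + ["GGCCAT"]           # A again, distinct sequence
        + ["GGCCC", "GGCCG", "GGCCT", "GGCCTT"]  # other bases
        + ["GGCC"] * 3         # end at the seed: do not cover the position
    )
    unique = g.dedupe(raw)
    members = [(u, u.seq.find("GGCC")) for u in unique]
    return Cluster(seed="GGCC", members=members, score=10.0)


@pytest.fixture
def worked_cluster() -> Cluster:
    return make_worked_cluster()


@pytest.fixture(scope="session")
def germline_panel():
    """The synthetic 30-allele study panel: 20 V genes (150 bp) and 10 J
    genes (50 bp), one allele each."""
    return g.make_germline_set(n_v=20, n_j=10, seed=20260901)


def simulate_and_infer(v, j, n_reads=10_000, shm=0.01, hotspot=0.0, seed=0,
                       err=0.005, shm_fraction=0.8):
    cfg = g.SimConfig(n_reads=n_reads, seq_error_rate=err, shm_rate=shm,
                      shm_fraction=shm_fraction, hotspot_rate=hotspot)
    truth = g.simulate_repertoire(v, j, cfg, seed=np.random.default_rng(seed))
    result = g.infer_repertoire(r.seq for r in truth.records)
    return truth, result


def uniq(seqs_with_counts) -> list[UniqueRead]:
    return [UniqueRead(seq=s, count=c) for s, c in seqs_with_counts]
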