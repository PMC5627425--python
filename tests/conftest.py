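import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from profilebin import SimConfig, depth_for_mean_reads, simulate_community

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
settings.load_profile("default")


def make_config(K, P, N, mean_reads, seed, **kw) -> SimConfig:
    """SimConfig whose depth yields the requested mean reads per contig."""
    base = SimConfig(K=K, P=P, N=N, seed=seed, **kw)
    return dataclasses.replace(base, depth=depth_for_mean_reads(mean_reads, base))


@pytest.fixture(scope="session")
def small_community():
    """A well-separated K=3 community used by several test modules."""
    return simulate_community(make_config(3, 8, 200, 200, seed=1))


# --- hand-built SAM fixtures: 2 contigs x 2 samples, counts [[2,0],[1,4]] ---

_SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:1500\n@SQ\tSN:c2\tLN:2000\n"


def _sam_line(name, flag, rname, mapq=60):
    pos = "100" if rname != "*" else "0"
    cigar = "10M" if rname != "*" else "*"
    return f"{name}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\tACGTACGTAC\t!!!!!!!!!!\n"


@pytest.fixture
def sam_pair(tmp_path):
    """Two SAM files sharing a contig namespace.

    Sample 1: two reads on c1, one on c2, one unmapped, plus a secondary
    alignment of read a1 on c2 (must not be counted with primary_only).
    Sample 2: four reads on c2.
    Expected counts [[2, 0], [1, 4]]; library sizes [4, 4].
    """
    s1 = _SAM_HEADER
    s1 += _sam_line("a1", 0, "c1")
    s1 += _sam_line("a1", 256, "c2")  # secondary
    s1 += _sam_line("a2", 0, "c1")
    s1 += _sam_line("a3", 0, "c2")
    s1 += _sam_line("a4", 4, "*", mapq=0)  # unmapped
    s2 = _SAM_HEADER
    for i in range(4):
        s2 += _sam_line(f"b{i}", 0, "c2")
    p1 = tmp_path / "s1.sam"
    p2 = tmp_path / "s2.sam"
    p1.write_text(s1)
    p2.write_text(s2)
    return p1, p2


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
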