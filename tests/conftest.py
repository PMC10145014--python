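import numpy as np
import pytest

from hfscan.alignment_io import AlignmentRecord
from hfscan.synthetic_data import desk_preset


@pytest.fixture(scope="session")
def uniform_bundle():
    return desk_preset(seed=11, placement_model="uniform")


@pytest.fixture(scope="session")
def gene_bundle():
    return desk_preset(seed=12, placement_model="gene_biased")


@pytest.fixture(scope="session")
def clustered_bundle():
    return desk_preset(seed=13, placement_model="clustered")


def make_record(
    query="v1",
    subject="sc1",
    identity=95.0,
    length=100,
    mismatches=5,
    gaps=0,
    q_start=1,
    q_end=100,
    s_start=1001,
    s_end=1100,
    evalue=1e-20,
    bit=150.0,
) -> AlignmentRecord:
    return AlignmentRecord(
        query_id=query,
        subject_id=subject,
        pct_identity=identity,
        aln_length=length,
        mismatches=mismatches,
        gap_opens=gaps,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bit_score=bit,
    )


def random_records(rng: np.random.Generator, n: int, n_scaffolds: int = 3,
                   scaffold_len: int = 10_000, n_viruses: int = 4) -> list[AlignmentRecord]:
    """Random alignment tables with controlled overlap structure."""
    records = []
    for _ in range(n):
        length = int(rng.integers(30, 300))
        sc = f"sc{rng.integers(1, n_scaffolds + 1)}"
        # starts near a coarse lattice so near-identical overlapping hits are common
        s = int(rng.integers(0, scaffold_len // 100)) * 100 + int(rng.integers(-20, 21))
        s = max(0, s)
        minus = rng.random() < 0.3
        s1, e1 = s + 1, s + length
        qs = 1 + int(rng.integers(0, 1000))
        records.append(
            make_record(
                query=f"v{rng.integers(1, n_viruses + 1)}",
                subject=sc,
                identity=float(rng.uniform(70, 100)),
                length=length,
                mismatches=int(rng.integers(0, length // 4 + 1)),
                q_start=qs,
                q_end=qs + length - 1,
                s_start=e1 if minus else s1,
                s_end=s1 if minus else e1,
                evalue=float(10.0 ** rng.uniform(-40, 2)),
                bit=float(rng.uniform(20, 500)),
            )
        )
    return records
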