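import numpy as np
import pytest

from ltrclock.io import LTRRecord
from ltrclock.simulate import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """Six elements spanning recent to ancient ages, two injected duplicates."""
    cfg = SimConfig(
        n_elements=6,
        ltr_length=400,
        internal_length=600,
        ages=(0.0, 5.0, 20.0, 60.0, 100.0, 143.0),
        duplicate_injection=2,
        seed=11,
    )
    return simulate_genome(cfg)


def make_record(element_id="e1", seq_id="s1", left=(100, 300), right=(5800, 6000),
                element=None, strand="+", source_superfamily=None) -> LTRRecord:
    element = element or (left[0], right[1])
    rec = LTRRecord(
        element_id=element_id, seq_id=seq_id,
        element_start=element[0], element_end=element[1],
        left_ltr_start=left[0], left_ltr_end=left[1],
        right_ltr_start=right[0], right_ltr_end=right[1],
        strand=strand, source_superfamily=source_superfamily,
    )
    rec.validate()
    return rec


def random_records(rng: np.random.Generator, n: int, n_scaffolds: int = 2):
    """Jittered records clustered around a few anchor loci, for dedup tests."""
    records = []
    anchors = [
        (f"s{rng.integers(1, n_scaffolds + 1)}",
         int(rng.integers(1000, 5000)), int(rng.integers(200, 400)))
        for _ in range(max(1, n // 4))
    ]
    for i in range(n):
        seq_id, left_start, ltr_len = anchors[int(rng.integers(0, len(anchors)))]
        j = rng.integers(-30, 31, size=4)
        ls = max(1, left_start + int(j[0]))
        le = ls + ltr_len + int(j[1])
        rs = le + 2000 + int(j[2])
        re = rs + ltr_len + int(j[3])
        records.append(make_record(
            element_id=f"r{i:03d}", seq_id=seq_id,
            left=(ls, le), right=(rs, re), element=(ls, re),
        ))
    return records
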