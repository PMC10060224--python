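import numpy as np
import pandas as pd
import pytest

from dropscreen import GuideRecord, Library
from dropscreen.quantify import CountMatrix


def _proto(rng, length=20):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_library(rng):
    """Two targeting genes (one 19-nt, one 20-nt design), controls included."""
    records = []
    seen = set()

    def unique_proto(length):
        # non-G leading, so oligo length = protospacer length + 1 throughout
        while True:
            p = _proto(rng, length)
            if p[0] == "G":
                continue
            oligo = "G" + p
            if oligo not in seen:
                seen.add(oligo)
                return p

    for j in range(1, 6):
        records.append(
            GuideRecord(f"sgGA#{j}", "GENEA", "targeting", unique_proto(20))
        )
    for j in range(1, 5):
        records.append(
            GuideRecord(f"sgGB#{j}", "GENEB", "targeting", unique_proto(19))
        )
    for j in range(1, 3):
        records.append(
            GuideRecord(f"sgPCNA#{j}", "PCNA", "positive_control",
                        unique_proto(20))
        )
    for i in range(1, 4):
        records.append(
            GuideRecord(f"sgNeg{i}", "non-targeting", "negative_control",
                        unique_proto(20))
        )
    return Library(tuple(records), name="toy")


def make_count_matrix(guide_ids, data, conditions=("ALT",)):
    """Build a CountMatrix with T0/Tend per condition from a dict of columns."""
    counts = pd.DataFrame(data, index=pd.Index(guide_ids, name="guide_id"))
    rows = []
    for sid in counts.columns:
        cond, tp = sid.rsplit("_", 1)
        rows.append({"sample_id": sid, "timepoint": tp, "condition": cond,
                     "replicate": "1"})
    samples = pd.DataFrame(rows).set_index("sample_id")
    return CountMatrix(counts=counts, samples=samples)


@pytest.fixture
def toy_counts(small_library):
    """Counts where every guide is abundant at T0 and some deplete."""
    ids = small_library.guide_ids
    n = len(ids)
    t0 = np.full(n, 1000)
    tend = np.full(n, 1000)
    tend[0] = 10  # sgGA#1 depleted
    return make_count_matrix(ids, {"ALT_T0": t0, "ALT_Tend": tend})
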