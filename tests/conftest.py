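import numpy as np
import pytest

import kdrpop as k
from kdrpop.io import TWO_LOCUS_CLASSES, GenotypeCountTable, GenotypeRecord


def two_locus_table(count_map: dict[str, int], period=(2014,), zone=None):
    """Build a two-locus GenotypeCountTable from a {class: count} dict."""
    counts = np.zeros(9, dtype=np.int64)
    for cls, n in count_map.items():
        counts[TWO_LOCUS_CLASSES.index(cls)] = n
    return GenotypeCountTable(period=period, zone=zone,
                              classes=TWO_LOCUS_CLASSES, counts=counts)


@pytest.fixture
def small_records():
    """A mixed bag of records across two months and two zones."""
    rows = [
        ("m1", 2013, 5, "spray", "VV", "FF", None),
        ("m2", 2013, 5, "spray", "VI", "FC", "VL"),
        ("m3", 2013, 5, "buffer", "II", "CC", "LL"),
        ("m4", 2013, 6, "buffer", "VV", "CC", None),
        ("m5", 2013, 6, "spray", "VI", "CC", None),
        ("m6", 2013, 6, "buffer", None, "FC", None),
    ]
    return [GenotypeRecord(sample_id=s, year=y, month=m, zone=z,
                           g1016=a, g1534=b, g410=c)
            for s, y, m, z, a, b, c in rows]


@pytest.fixture(scope="session")
def benchmark_series():
    """Synthetic monthly series from the selection/drift HMM benchmark
    (s=0.2, h=0.2, R0=0.25, A=5, Ne=500; 90 months, n=40/month)."""
    truth = k.HMMParams(s=0.2, h=0.2, R0=0.25, A=5.0, Ne=500)
    latent, series = k.simulate_hmm(truth, np.full(90, 40), seed=11)
    return truth, latent, series
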