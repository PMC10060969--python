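import numpy as np
import pandas as pd
import pytest

from replicall.simulate import SimConfig, simulate
from replicall.types import IntervalSet, SiteTable, TruthSet


def truthset_from_dataset(ds) -> TruthSet:
    """TruthSet over the dataset's VCF view (one confident block per chrom)."""
    v = ds.view()
    cats = {(str(c), int(p)): int(t)
            for c, p, t in zip(v.chrom, v.pos, v.truth) if t != 0}
    regions = {}
    for c in pd.unique(v.chrom):
        m = v.chrom == c
        regions[str(c)] = np.array([[int(v.pos[m].min()) - 1,
                                     int(v.pos[m].max())]])
    return TruthSet(cats, IntervalSet(regions))


def make_site_table(calls, dp=None, ab=None, qd=None, mq=None, gq=None,
                    difficult=None) -> SiteTable:
    """Assemble a SiteTable directly from arrays (test helper)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, R = calls.shape
    df = pd.DataFrame({
        "chrom": np.full(n, "1"), "pos": 1 + 2 * np.arange(n, dtype=np.int64),
        "ref": np.full(n, "A"), "alt": np.full(n, "G"),
    })
    for j in range(R):
        df[f"call_{j + 1}"] = calls[:, j]
    df["dp_mean"] = dp if dp is not None else np.full(n, 38.0)
    df["ab_mean"] = ab if ab is not None else np.full(n, 0.5)
    df["gq_mean"] = gq if gq is not None else np.full(n, 90.0)
    df["qd"] = qd if qd is not None else np.full(n, 16.0)
    df["mq"] = mq if mq is not None else np.full(n, 60.0)
    df["difficult"] = difficult if difficult is not None else np.zeros(n, bool)
    return SiteTable(df)


@pytest.fixture(scope="session")
def default_dataset():
    """One 20k-site draw from the calibrated default configuration."""
    return simulate(SimConfig(n_sites=20_000, seed=20240501))


@pytest.fixture(scope="session")
def default_table(default_dataset):
    return default_dataset.to_site_table()


@pytest.fixture(scope="session")
def default_truth(default_dataset):
    return truthset_from_dataset(default_dataset)
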