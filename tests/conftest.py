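import numpy as np
import pytest

from palm.data_io import CountTable, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts(tmp_path):
    """3x2 TSV count table with a zero-depth sample."""
    p = tmp_path / "counts.tsv"
    p.write_text(
        "sample_id\tfA\tfB\n"
        "s1\t1\t0\n"
        "s2\t2\t5\n"
        "s3\t0\t0\n"
    )
    return p


def random_feature(rng, n=30, rate=0.01, depth_range=(500, 5000)):
    """One overdispersed null feature: counts, depths."""
    depths = rng.integers(*depth_range, size=n)
    lam = rng.gamma(5.0, depths * rate / 5.0)
    return rng.poisson(lam), depths


@pytest.fixture
def null_feature(rng):
    y, depths = random_feature(rng)
    return y, depths


@pytest.fixture
def toy_study(rng):
    """A small two-group study with overdispersed counts, K=25 features."""
    n, k = 80, 25
    depths = rng.integers(2000, 20000, size=n)
    base = np.sort(rng.dirichlet(np.ones(k) * 0.3))[::-1]
    probs = rng.dirichlet(50 * base, size=n)
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, probs)])
    table = CountTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(k)],
        counts=counts,
        depths=depths,
    )
    x = np.repeat([0.0, 1.0], n // 2)
    design = StudyDesign(covariate=x, study_id="toy")
    return table, design
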