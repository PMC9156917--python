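import numpy as np
import pytest

import clinemap as cm
from clinemap.cline import _Cell


@pytest.fixture(scope="session")
def small_world():
    return cm.WorldSpec(n_records=4000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_world):
    return cm.sample_records(small_world)


@pytest.fixture(scope="session")
def small_grid(small_dataset):
    return cm.build_grid(small_dataset, cm.GridSpec(4.0))


@pytest.fixture
def cline_cells():
    """Factory: binomial allele-count data from a known sigmoid cline."""

    def make(seed=0, c=1500.0, w=400.0, n=100, x=None, pmin=0.0, pmax=1.0,
             decreasing=False):
        rng = np.random.default_rng(seed)
        if x is None:
            x = np.arange(0.0, 3100.0, 100.0)
        params = cm.ClineParams(c=c, w=w, pmin=pmin, pmax=pmax)
        spec = cm.ClineModelSpec(
            scaling="none" if (pmin, pmax) == (0.0, 1.0) else "free"
        )
        p = cm.cline_value(x, params, spec)
        if decreasing:
            p = pmin + pmax - p
        qhat = rng.binomial(2 * n, p) / (2 * n)
        return [_Cell(xi, qi, n) for xi, qi in zip(x, qhat)], params

    return make


@pytest.fixture
def records_csv(tmp_path):
    path = tmp_path / "records.csv"
    path.write_text(
        "record_id,source,date,lat,lon,locusA,locusB,locusC\n"
        "r1,research,2001-05-02,-1.3,36.8,rec,dom,rec\n"
        "r2,citizen,,-1.5,36.9,dom,NA,dom\n"
        "r3,citizen,2019-11-30,10.2,-4.0,dom,,rec\n"
    )
    return path
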