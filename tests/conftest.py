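import numpy as np
import pandas as pd
import pytest

from fgniche.core_data import AbundanceTable, FGTable


def make_table(values, taxa=None, reservoir="R1", seasons=None, cls=AbundanceTable, **kw):
    """Build a small table from a 2-D array (sites × taxa)."""
    arr = np.asarray(values, dtype=float)
    n = arr.shape[0]
    taxa = taxa or [f"t{j}" for j in range(arr.shape[1])]
    sites = [f"s{i}" for i in range(n)]
    seasons = seasons or ["wet"] * n
    meta = pd.DataFrame({"reservoir": [reservoir] * n, "season": seasons}, index=sites)
    vals = pd.DataFrame(arr, index=sites, columns=taxa)
    vals.index.name = meta.index.name = "site_id"
    return cls(vals, meta, **kw)


def make_fg_table(values, fgs=None, **kw):
    fgs = fgs or [f"G{j}" for j in range(np.asarray(values).shape[1])]
    return make_table(values, taxa=fgs, cls=FGTable, **kw)


@pytest.fixture
def toy_dominance_table():
    """4 sites; taxon A at half the sites, taxon B everywhere."""
    return make_table([[10, 10], [0, 10], [10, 10], [0, 10]], taxa=["A", "B"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
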