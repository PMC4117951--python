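import numpy as np
import pandas as pd
import pytest

from bisclass.core import COUNT_COLUMNS


def sites_frame(pos, n_meth, n_total, chrom="chr1", strand="+", context="CpG") -> pd.DataFrame:
    """Build a canonical count table from parallel arrays."""
    pos = np.asarray(pos)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "strand": strand,
            "context": context,
            "n_meth": np.asarray(n_meth, dtype=np.int64),
            "n_total": np.asarray(n_total, dtype=np.int64),
        },
        columns=COUNT_COLUMNS,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
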