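import numpy as np
import pandas as pd
import pytest

from oacgh import cgh
from oacgh.core import GenomeAssembly


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_601)


@pytest.fixture
def tiny_genome(rng):
    seqs = {
        "chr1": "".join(rng.choice(list("ACGT"), size=5_000)),
        "chr2": "".join(rng.choice(list("ACGT"), size=3_000)),
    }
    return GenomeAssembly("tiny", seqs)


def make_track(levels, chrom="c1", spacing=20_000, noise_sd=0.0, seed=0,
               start=0):
    """Ratio track from an explicit per-probe level vector."""
    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    values = levels + (rng.normal(0, noise_sd, len(levels)) if noise_sd else 0)
    df = pd.DataFrame(
        {
            "probe_id": [f"{chrom}_p{i}" for i in range(len(levels))],
            "chrom": chrom,
            "pos": start + np.arange(len(levels)) * spacing,
            "log2": values,
            "non_uniform": False,
            "saturated": False,
        }
    )
    return cgh.RatioTrack(df)
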