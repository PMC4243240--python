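import numpy as np
import pandas as pd
import pytest


def make_annotation(probes_per_chrom: dict[str, int], spacing: int = 100_000) -> pd.DataFrame:
    """Evenly spaced probe annotation over the given chromosomes."""
    rows = []
    for chrom, n in probes_per_chrom.items():
        for k in range(n):
            rows.append((f"{chrom}_p{k:05d}", chrom, k * spacing, (k + 1) * spacing))
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "start", "end"])


@pytest.fixture
def annotation():
    return make_annotation({"chr1": 100, "chr2": 100})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
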