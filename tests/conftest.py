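import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from karyostat import GenomeLayout, ProbeProfile

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    """Five 10-Mb chromosomes, 1-Mb bins: fast but structurally realistic."""
    return GenomeLayout({f"chr{i}": 10_000_000 for i in range(1, 6)}, bin_width=1_000_000)


def profile_from_values(values_by_chrom: dict[str, list[float]], sample_id: str = "t") -> ProbeProfile:
    """Build a probe profile from per-chromosome ratio lists (probes 1 Mb apart)."""
    rows = []
    for chrom, vals in values_by_chrom.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "probe_id": f"{chrom}_{i}",
                    "chrom": chrom,
                    "start": i * 1_000_000,
                    "end": i * 1_000_000 + 1,
                    "log2_ratio": float(v),
                }
            )
    return ProbeProfile(sample_id, pd.DataFrame(rows), list(values_by_chrom))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(91625)
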