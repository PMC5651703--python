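import numpy as np
import pandas as pd
import pytest

from starr_regvar import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_screen():
    """A 200-region screen with planted activities and allelic effects."""
    cfg = SimulationConfig(
        n_tag_snps=20,
        linked_per_tag=9,
        fragments_per_region=200.0,
        pre_fraction=0.1,
        nre_fraction=0.1,
        regsnp_fraction=0.05,
        seed=42,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_screen():
    """A screen with no planted effects of any kind."""
    cfg = SimulationConfig(
        n_tag_snps=50,
        linked_per_tag=9,
        pre_fraction=0.0,
        nre_fraction=0.0,
        regsnp_fraction=0.0,
        seed=7,
        materialize_fragments=False,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def tiny_panel():
    """Three SNPs on one synthetic contig (positions 1-based)."""
    return pd.DataFrame(
        {
            "chrom": ["chrS", "chrS", "chrS"],
            "pos": [1000, 1400, 5000],
            "snp_id": ["rsA", "rsB", "rsC"],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
            "maf": [0.2, 0.3, 0.4],
        }
    )


def design_of(counts: pd.DataFrame) -> dict:
    return {c: ("output" if str(c).startswith("out") else "input") for c in counts.columns}
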