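import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import barseqkit as bk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_catalog() -> bk.BarcodeCatalog:
    """Three strains; one lacks its downtag."""
    return bk.BarcodeCatalog(
        [
            bk.BarcodeRecord("yfg1", uptag="A" * 20, downtag="C" * 20),
            bk.BarcodeRecord("yfg2", uptag="G" * 20, downtag="T" * 20),
            bk.BarcodeRecord("yfg3", uptag="ACGT" * 5, downtag=None),
        ]
    )


@pytest.fixture
def random_catalog() -> bk.BarcodeCatalog:
    """50 strains with well-separated random tags (min Hamming 5)."""
    cfg = bk.SimConfig(n_strains=50, fraction_uptag_only=0.1, seed=42)
    return bk.make_catalog(cfg, np.random.default_rng(42), min_hamming=5)


@pytest.fixture
def small_sheet() -> bk.SampleSheet:
    rows = [
        ("T1", "drug", "treatment", 1),
        ("T2", "drug", "treatment", 2),
        ("C1", "ctrl", "control", 1),
        ("C2", "ctrl", "control", 2),
    ]
    return bk.SampleSheet(
        pd.DataFrame(
            [
                {
                    "sample_id": s,
                    "condition": c,
                    "role": r,
                    "replicate": i,
                    "assay": "HOP",
                    "generations": 5.0,
                }
                for s, c, r, i in rows
            ]
        )
    )


def toy_counts(values: dict[str, list[int]], strains=None) -> pd.DataFrame:
    """Counts frame over (strain, uptag)+(strain, downtag) rows.

    ``values`` maps sample id to a flat list ordered uptags-then-downtags.
    """
    n = len(next(iter(values.values()))) // 2
    strains = strains or [f"s{i}" for i in range(n)]
    idx = pd.MultiIndex.from_tuples(
        [(s, "uptag") for s in strains] + [(s, "downtag") for s in strains],
        names=["strain_id", "tag_class"],
    )
    return pd.DataFrame(values, index=idx).sort_index()
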