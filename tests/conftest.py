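import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231012)


@pytest.fixture
def atac_toy_meta():
    """Six ATAC nuclei bracketing the UMI and FRiP filter boundaries."""
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(6)],
        "total_umi": [500, 1000, 99_999, 100_000, 2000, 3000],
        "frip": [0.5] * 6,
    })


def make_barcode_meta(seed, n_contaminated=12_000, n_clean_cells=11_000,
                      n_clean_barcodes=20, mix=0.5):
    """Multi-barcode metadata with one cross-well contaminated barcode.

    Host sample composition is 90% class X; the donor sample is 90%
    class Y; the contaminated barcode receives ``mix`` of its labels
    from the donor composition. Subtypes split each class in two.
    """
    rng = np.random.default_rng(seed)
    classes = np.array(["X", "Y", "Z"], dtype=object)
    host_p = np.array([0.90, 0.05, 0.05])
    donor_p = np.array([0.05, 0.90, 0.05])

    rows = []
    for b in range(n_clean_barcodes + 1):
        n = n_contaminated if b == 0 else n_clean_cells
        labels = rng.choice(classes, size=n, p=host_p)
        if b == 0 and mix > 0:
            swap = rng.random(n) < mix
            labels[swap] = rng.choice(classes, size=int(swap.sum()), p=donor_p)
        rows.append(pd.DataFrame({
            "sample_id": "host",
            "rt_barcode": f"host_bc{b}",
            "cell_class": labels,
        }))
    meta = pd.concat(rows, ignore_index=True)
    meta["cell_subtype"] = [
        f"{c}_s{s}" for c, s in zip(meta["cell_class"], rng.integers(0, 2, len(meta)))
    ]
    meta.insert(0, "cell_id", [f"c{i}" for i in range(len(meta))])
    return meta
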