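import numpy as np
import pandas as pd
import pytest

from pathscreen import SimConfig, build_library, make_sample_sheet, simulate_counts
from pathscreen.readproc import SampleSheet


@pytest.fixture(scope="session")
def small_config():
    """Small but structured screen: 40 genes, modest depth, no read errors."""
    return SimConfig(n_genes=40, depth=50_000, error_rate=0.0, seed=11, n_replicates=3)


@pytest.fixture(scope="session")
def small_library(small_config):
    return build_library(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_library):
    lib, eff = small_library
    return simulate_counts(lib, eff, small_config)


@pytest.fixture(scope="session")
def small_sheet(small_config, small_counts):
    return SampleSheet(make_sample_sheet(small_counts.design, small_config.seed))


def toy_counts():
    """Tiny hand-checkable count matrix: 2 sensors x 3 barcodes each plus a
    calibrator, over reference/TTX/BIC samples."""
    from pathscreen.containers import CountMatrix, make_design

    design = make_design(
        [
            ("ref_r1", "reference", "r1", None),
            ("ref_r2", "reference", "r2", None),
            ("TTX_r1", "TTX", "r1", None),
            ("TTX_r2", "TTX", "r2", None),
            ("BIC2h_r1", "BIC", "r1", 2.0),
            ("BIC2h_r2", "BIC", "r2", 2.0),
            ("BIC4h_r1", "BIC", "r1", 4.0),
            ("BIC4h_r2", "BIC", "r2", 4.0),
            ("BIC8h_r1", "BIC", "r1", 8.0),
            ("BIC8h_r2", "BIC", "r2", 8.0),
        ]
    )
    rng = np.random.default_rng(7)
    feats = []
    rows = []
    for sensor, resp, cal in [("CAL", 0.0, True), ("S1", 2.0, False), ("S2", -1.0, False)]:
        for b in range(3):
            fid = f"{sensor}_bc{b + 1}"
            feats.append((fid, fid, sensor, cal))
            base = rng.integers(500, 1500)
            row = []
            for s in design.index:
                cond = design.loc[s, "condition"]
                fc = resp if cond == "BIC" else (resp / 2 if cond == "TTX" else 0.0)
                row.append(int(base * 2**fc))
            rows.append(row)
    features = pd.DataFrame(feats, columns=["feature", "shrna_id", "gene", "is_calibrator"]).set_index("feature")
    counts = pd.DataFrame(rows, index=features.index, columns=design.index)
    return CountMatrix(counts, design, features, level="barcode")
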