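import numpy as np
import pandas as pd
import pytest

import leadedge as le


@pytest.fixture
def small_imc():
    """A 2-ROI, 300-cell synthetic IMC table with ground truth."""
    cfg = le.ImcSimConfig(n_rois=2, cells_per_roi=150)
    table, truth = le.gen_imc_rois(cfg, seed=42)
    return cfg, table, truth


@pytest.fixture
def gated_table(small_imc):
    """The small IMC table after transform, thresholding, and gating."""
    cfg, table, _ = small_imc
    panel = list(cfg.panel)
    t = le.transform_intensities(table, panel, cofactor=1.0)
    th = le.fit_thresholds(t, panel)
    t = le.gate_cell_types(t, th)
    t = le.classify_fb_subtypes(t, th)
    return t, th


def truth_labeled(table: pd.DataFrame, truth) -> pd.DataFrame:
    """Attach ground-truth cell_type/fb_subtype labels to a generated table."""
    from leadedge.simulate import FB_SUBTYPES

    t = table.merge(truth.cells, on=["cell_id", "roi_id"])
    t["cell_type"] = np.where(
        t["true_type"].isin(FB_SUBTYPES), "stromal", t["true_type"]
    )
    t["fb_subtype"] = t["true_fb_subtype"]
    return t
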