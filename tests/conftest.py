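import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mixde

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """One simulated study at defaults, QC'd and REML-fitted, shared read-only."""
    cfg = mixde.SimulationConfig(n_probes=400, seed=11)
    design = mixde.generate_design(cfg)
    spots, truth = mixde.simulate_spots(design, cfg)
    qc = mixde.apply_qc(spots)
    md = mixde.build_design(qc, design)
    model = mixde.DyeSwapMixedModel().fit_model_data(md)
    return {"config": cfg, "design": design, "spots": spots, "truth": truth,
            "qc": qc, "model_data": md, "model": model}


@pytest.fixture(scope="session")
def annotation_fixtures():
    return mixde.generate_annotation_fixtures(n_probes=40, seed=17)


def qc_oracle_spot(fg_mean, fg_median, bg_mean, bg_sd,
                   snr_threshold=1.0, r_threshold=0.85, r_strict=False):
    """Independent per-spot re-application of both quality rules."""
    if bg_sd <= 0:
        return False, None
    corrected = fg_mean - bg_mean
    if not corrected / bg_sd > snr_threshold:
        return False, None
    if fg_mean <= 0 or fg_median <= 0:
        return False, None
    r = min(fg_mean, fg_median) / max(fg_mean, fg_median)
    r_ok = r > r_threshold if r_strict else r >= r_threshold
    if not r_ok:
        return False, None
    if corrected <= 0:
        return False, None
    return True, float(np.log2(corrected))


@pytest.fixture(scope="session")
def qc_oracle():
    return qc_oracle_spot


def make_stats_frame(x):
    """Wrap raw statistic values in the contrast-table layout."""
    x = np.asarray(x, float)
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(x))],
                         "contrast": "PvH", "raw_diff": x, "se": 1.0,
                         "statistic": x})
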