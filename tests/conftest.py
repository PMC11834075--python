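import numpy as np
import pytest

from laminar_swr.synth import SimConfig, generate_recording


@pytest.fixture(scope="session")
def sim_30min():
    """One 30-min default-condition recording with ground truth (seed 7)."""
    cfg = SimConfig(duration_s=1800.0, seed=7)
    rec, gt = generate_recording(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def detected_30min(sim_30min):
    """Pipeline run through detection on the shared 30-min recording."""
    from laminar_swr.core import NREM
    from laminar_swr.pipeline import Pipeline, PipelineConfig

    cfg, rec, gt = sim_30min
    pcfg = PipelineConfig(sim=cfg, seed=cfg.seed)
    p = Pipeline(pcfg, "scratch/test_run7")
    pre = p.preprocess(rec)
    hyp = p.score_states(pre)
    events = p.detect(pre, hyp)
    return {"pre": pre, "hyp": hyp, "events": events,
            "nrem_events": events[events["state"] == NREM],
            "pipeline": p, "gt": gt}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
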