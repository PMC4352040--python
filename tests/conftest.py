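import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sensiscreen.simulate as sim
from sensiscreen.screen import CONTROL, SENSITIZED

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_screen():
    """One small simulated screen: plates, gene map, truth, scored tables."""
    import sensiscreen.screen as screen

    cfg = sim.ScreenSimConfig(n_plates=2, wells_per_plate=96, n_control_wells_per_plate=12, seed=11)
    plates, gene_map, truth = sim.generate_screen_plates(cfg)
    per_rep, merged = screen.score_screen(plates, gene_map=gene_map)
    return {
        "cfg": cfg,
        "plates": plates,
        "gene_map": gene_map,
        "truth": truth,
        "per_rep": per_rep,
        "merged": merged,
    }


@pytest.fixture(scope="session")
def small_phospho():
    """One small simulated six-plex study (all three layouts) plus truth."""
    cfg = sim.PhosphoSimConfig(n_phosphosites=150, seed=11)
    experiments, truth, impurity = sim.generate_phospho_study(cfg)
    return {"cfg": cfg, "experiments": experiments, "truth": truth, "impurity": impurity}


def toy_plate(control_readings, candidate_readings, condition=SENSITIZED, replicate=1):
    """Hand-built single plate/condition/replicate reading table."""
    rows = []
    for i, r in enumerate(control_readings):
        rows.append(
            {
                "plate_id": "P1",
                "well": f"C{i:02d}",
                "condition": condition,
                "replicate": replicate,
                "amplicon_id": "CTRL",
                "is_control": True,
                "reading": r,
            }
        )
    for i, r in enumerate(candidate_readings):
        rows.append(
            {
                "plate_id": "P1",
                "well": f"W{i:02d}",
                "condition": condition,
                "replicate": replicate,
                "amplicon_id": f"A{i:03d}",
                "is_control": False,
                "reading": r,
            }
        )
    return pd.DataFrame(rows)
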