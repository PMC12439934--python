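import numpy as np
import pandas as pd
import pytest

from adccombo import (
    MifSimConfig,
    ScreenSimConfig,
    gen_mif_dataset,
    summarize_cores,
    summarize_tumors,
)


@pytest.fixture(scope="session")
def small_mif_cfg():
    return MifSimConfig(
        n_patients=10, n_tumors_total=30, cores_per_tumor=3, cells_per_core=80, seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_mif_cfg):
    cells, truth = gen_mif_dataset(small_mif_cfg)
    cores = summarize_cores(cells)
    tumors = summarize_tumors(cores)
    return {"cells": cells, "truth": truth, "cores": cores, "tumors": tumors}


@pytest.fixture(scope="session")
def screen_cfg():
    return ScreenSimConfig(seed=7, interaction_map={("duocarmycin-TM", "A-1331852"): 0.25})


def cells_from_classes(classes: dict[str, list[int]], core_id="c1", tumor_id="t1",
                       patient_id="p1", phenotype="AR+/NE-") -> pd.DataFrame:
    """Tiny cell table from explicit per-marker class lists."""
    n = len(next(iter(classes.values())))
    base = {
        "cell_id": np.arange(1, n + 1),
        "core_id": core_id,
        "tumor_id": tumor_id,
        "patient_id": patient_id,
        "phenotype": phenotype,
    }
    for marker in ("b7h3", "psma", "steap1"):
        base[f"{marker}_class"] = classes.get(marker, [0] * n)
    return pd.DataFrame(base)
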