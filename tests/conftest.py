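import numpy as np
import pandas as pd
import pytest

from fishpanel.probes import default_panel
from fishpanel.simulate import PlantedEffect, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """30 cases / 25 controls, default planted effects, seed 11."""
    cfg = SimulationConfig(n_cases=30, n_controls=25, seed=11)
    clinical, cells, panel = generate_cohort(cfg)
    return cfg, clinical, cells, panel


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    from fishpanel.enumeration import build_parameter_matrix

    _, clinical, cells, panel = small_cohort
    matrix, failures = build_parameter_matrix(cells, panel)
    assert not failures
    labels = clinical.set_index("specimen_id").loc[matrix.index, "outcome"].to_numpy()
    return matrix, labels, clinical


def locus_cells(counts, specimen_id="S1", probe_id="PTEN", mix_id=1):
    """Cell table fragment for a locus/centromere probe from raw signal counts."""
    n = len(counts)
    return pd.DataFrame(
        {
            "specimen_id": specimen_id,
            "mix_id": mix_id,
            "cell_index": np.arange(n),
            "probe_id": probe_id,
            "n_signals": pd.array(counts, dtype="Int64"),
            "n_fusion": pd.array([pd.NA] * n, dtype="Int64"),
            "n_single_red": pd.array([pd.NA] * n, dtype="Int64"),
            "n_single_green": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )


def break_apart_cells(patterns, specimen_id="S1", probe_id="ERG_BA", mix_id=1):
    """Cell table fragment from (n_fusion, n_single_red, n_single_green) triples."""
    n = len(patterns)
    fus, red, green = zip(*patterns) if patterns else ((), (), ())
    return pd.DataFrame(
        {
            "specimen_id": specimen_id,
            "mix_id": mix_id,
            "cell_index": np.arange(n),
            "probe_id": probe_id,
            "n_signals": pd.array([pd.NA] * n, dtype="Int64"),
            "n_fusion": pd.array(fus, dtype="Int64"),
            "n_single_red": pd.array(red, dtype="Int64"),
            "n_single_green": pd.array(green, dtype="Int64"),
        }
    )
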