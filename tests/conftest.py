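import dataclasses

import pandas as pd
import pytest

import spiderpref as sp
from spiderpref.data_model import FEATURES, INSTRUCTIONS, ORIENTATIONS


@pytest.fixture(scope="session")
def reference_cohort():
    """One reference synthetic cohort (45 participants x 24 trials)."""
    return sp.generate_cohort(sp.reference_config(seed=1))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Degenerate cohort: every trial equals its latent mean snapped to grid."""
    cfg = dataclasses.replace(
        sp.reference_config(seed=2), base_sd=0.0, participant_sd=0.0,
        sd_spq_slope=0.0, hairiness_incoherency_slope=0.0,
        cluster_spec=None, orientation_effect=0.0)
    return sp.generate_cohort(cfg)


@pytest.fixture()
def tiny_cohort():
    """Hand-built single-participant cohort with a full balanced session."""
    rows = []
    idx = 1
    level = 0
    for instr in INSTRUCTIONS:
        for orient in ORIENTATIONS:
            for _ in range(4):
                rows.append({
                    "participant_id": "P01", "trial_index": idx,
                    "instruction": instr, "orientation": orient,
                    **{f: (level % 10) / 9 for f in FEATURES},
                })
                idx += 1
                level += 1
    participants = pd.DataFrame([
        {"participant_id": "P01", "spq": 0, "included": True,
         "age": 25, "sex": "female"},
    ])
    return sp.CohortTable(participants=participants, trials=pd.DataFrame(rows))


def mmpd_reference(values):
    """Independent recount-and-average oracle for the modal-part mean."""
    above = [v for v in values if v > 0.5]
    below = [v for v in values if v < 0.5]
    mid = [v for v in values if v == 0.5]
    if len(above) > len(below):
        keep = above + mid
    elif len(below) > len(above):
        keep = below + mid
    else:
        keep = list(values)
    return sum(keep) / len(keep)
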