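import numpy as np
import pandas as pd
import pytest

from mirsig import (
    SampleTable,
    SimulationConfig,
    generate_cohort,
    normalize_delta_ct,
)


def make_sample_table(n_case=4, n_control=4, analysis_set="learning", seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("case", n_case), ("control", n_control)):
        for k in range(n):
            rows.append({
                "sample_id": f"{analysis_set}_{group}_{k:02d}",
                "group": group,
                "set": analysis_set,
                "platform": "array" if analysis_set == "learning" else "qrtpcr",
                "age": float(rng.integers(20, 60)),
                "sex": "M" if rng.random() < 0.5 else "F",
                "education": int(rng.integers(8, 18)),
                "smoking": "yes" if rng.random() < 0.3 else "no",
            })
    return SampleTable(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def small_cohort():
    """Compact 60-assay learning-only cohort with three planted markers."""
    cfg = SimulationConfig(
        seed=101, n_mirna=60, n_case_testing=0, n_control_testing=0,
        planted=[(0, -1.32), (1, -1.0), (2, 0.9)])
    ct, samples = generate_cohort(cfg)
    return cfg, ct, samples


@pytest.fixture(scope="session")
def small_expression(small_cohort):
    _, ct, samples = small_cohort
    return normalize_delta_ct(ct), samples


@pytest.fixture(scope="session")
def two_set_cohort():
    """Learning + testing cohort with planted markers, study-like sizes."""
    mags = np.linspace(0.7, 1.32, 7)
    signs = [-1, -1, 1, -1, 1, -1, -1]
    planted = [(i, s * d) for i, (s, d) in enumerate(zip(signs, mags))]
    cfg = SimulationConfig(seed=42, n_mirna=120, planted=planted)
    ct, samples = generate_cohort(cfg)
    return cfg, ct, samples
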