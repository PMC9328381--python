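import numpy as np
import pandas as pd
import pytest

from mtxresponse.data import ExpressionMatrix, SampleTable
from mtxresponse.simulate import ModuleSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared by downstream-stage tests: 300 genes,
    one shared and one nonresponder-only module, 20 signal genes."""
    config = SimulationConfig(
        n_good=20,
        n_nonresponder=20,
        n_genes=300,
        module_spec=[ModuleSpec(60, 0.7, "both"), ModuleSpec(40, 0.7, "nonresponder_only")],
        n_signal_genes=20,
        signal_effect=1.0,
        frac_unexpressed=0.02,
        seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture()
def tiny_expression():
    """3 probes x 2 samples, fixed values."""
    frame = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.5]],
        index=["pA", "pB", "pC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(frame, "log2")


def make_sample_table(n_patients: int = 4, response=("good", "nonresponder")) -> SampleTable:
    rows = []
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        resp = response[i % len(response)]
        for tp, suffix in [("pretreatment", "pre"), ("week4", "wk4")]:
            rows.append({
                "sample_id": f"{pid}-{suffix}",
                "patient_id": pid,
                "timepoint": tp,
                "response": resp,
                "sex": "female" if i % 2 == 0 else "male",
                "age_at_onset": 50.0 + i,
                "haq": 1.0,
                "smoking": ("never", "past", "current")[i % 3],
                "acpa_positive": bool(i % 2),
                "swollen28": 5,
                "tender28": 8,
                "crp": 9.0,
                "vas_global": 44.0,
            })
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture()
def sample_table():
    return make_sample_table()


def paired_matrices(n_probes: int, table: SampleTable, seed: int = 0):
    """Random paired matrices matching a sample table."""
    rng = np.random.default_rng(seed)
    probes = [f"g{i:04d}" for i in range(n_probes)]
    pre_cols = table.frame.loc[table.frame["timepoint"] == "pretreatment", "sample_id"].tolist()
    wk4_cols = table.frame.loc[table.frame["timepoint"] == "week4", "sample_id"].tolist()
    pre = ExpressionMatrix(pd.DataFrame(rng.normal(7, 1, (n_probes, len(pre_cols))),
                                        index=probes, columns=pre_cols), "normalized_log2")
    wk4 = ExpressionMatrix(pd.DataFrame(rng.normal(7, 1, (n_probes, len(wk4_cols))),
                                        index=probes, columns=wk4_cols), "normalized_log2")
    return pre, wk4
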