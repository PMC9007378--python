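import numpy as np
import pandas as pd
import pytest

from mthet.qc import apply_qc_cascade
from mthet.reference import load_annotation
from mthet.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def ann():
    return load_annotation()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused across modules (120 cases / 80 controls)."""
    return generate_cohort(SimulationConfig(n_cases=120, n_controls=80, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study size (700 cases / 360 controls)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_qc(default_cohort, ann):
    return apply_qc_cascade(default_cohort.calls, default_cohort.samples, ann.mask,
                            [default_cohort.panel_genbank, default_cohort.panel_kg])


def toy_calls(rows):
    """Build a call table from (sample_id, pos, ref, alt, hf) tuples with
    generous read support that passes the basic call filter."""
    df = pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt", "hf"])
    df["depth"] = 1000
    alt_total = np.maximum(1, np.rint(df["hf"] * 1000)).astype(int)
    df["alt_fwd"] = alt_total // 2
    df["alt_rev"] = alt_total - df["alt_fwd"]
    return df


def toy_samples(ids, group="HTN", **kw):
    n = len(ids)
    base = dict(group=group, age=60.0, sex="F", mean_depth=1000.0,
                mt_ancestry="European", covered_fraction=0.99,
                sbp=np.nan, dbp=np.nan, smoker=np.nan)
    base.update(kw)
    df = pd.DataFrame({"sample_id": list(ids)})
    for k, v in base.items():
        df[k] = v
    return df
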