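import numpy as np
import pandas as pd
import pytest

import spt07a_pbpk as pk
from spt07a_pbpk.pbpk import SAMPLING_SCHEDULES


@pytest.fixture(scope="session")
def rat_cfg():
    return pk.load_species("rat")


@pytest.fixture(scope="session")
def dog_cfg():
    return pk.load_species("dog")


@pytest.fixture(scope="session")
def human_cfg():
    return pk.load_species("human")


@pytest.fixture(scope="session")
def rat_model(rat_cfg):
    return pk.build_model(rat_cfg)


@pytest.fixture(scope="session")
def human_model(human_cfg):
    return pk.build_model(human_cfg)


@pytest.fixture(scope="session")
def human_infusion_regimen():
    """The clinical single-dose regimen: 10 mg over 1 h."""
    return pk.DoseRegimen("iv_infusion", 10_000.0, infusion_duration=60.0)


@pytest.fixture(scope="session")
def human_single_dose_profile(human_model, human_infusion_regimen):
    """Plasma profile of the 10 mg 1 h infusion on the human schedule."""
    sched = np.asarray(SAMPLING_SCHEDULES["human"], dtype=float)
    res = pk.simulate(human_model, human_infusion_regimen,
                      t_end=float(sched.max()), dt_out=float(sched.max()),
                      t_eval=sched)
    profile = pd.DataFrame({
        "time_min": sched,
        "conc_ng_ml": np.interp(sched, res.times, res.plasma),
    })
    return profile, res
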