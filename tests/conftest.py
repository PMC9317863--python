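import numpy as np
import pytest
from hypothesis import settings

import utilsurv as u

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def default_config():
    return u.WindowConfig()


@pytest.fixture
def study_series():
    """A well-behaved 80-month series (2015-03..2021-10), matched family."""
    spec = u.GeneratorSpec(
        alpha=np.log(5000.0),
        beta=-0.001,
        seasonal=u.seasonal_harmonic(0.03),
        phi=2.0,
        seed=2718,
    )
    return u.simulate_series(spec)


@pytest.fixture
def constant_series():
    """Constant count 100 over the full study span."""
    months = tuple(u.MonthStamp(2015, 3).shift(k) for k in range(80))
    return u.UtilizationSeries(
        outcome=u.Outcome.INPATIENTS_PER_DAY,
        stratum="total",
        months=months,
        values=(100,) * 80,
    )


@pytest.fixture
def panel_csv(tmp_path):
    """Long CSV holding the default synthetic 21-series panel."""
    path = tmp_path / "panel.csv"
    u.write_series(u.simulate_study_panel(seed=11), path)
    return path
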