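import numpy as np
import pytest

import gliotmz as g


@pytest.fixture(scope="session")
def fixture_data():
    return g.load_fixture()


@pytest.fixture(scope="session")
def patient3(fixture_data):
    return g.fixture_params(fixture_data.param_table, 3)


@pytest.fixture(scope="session")
def patient2(fixture_data):
    return g.fixture_params(fixture_data.param_table, 2)


@pytest.fixture
def default_params():
    return g.ModelParams(
        rho1=1e-3, rho2=4e-3, psi=0.5, alpha1=0.35, alpha2=0.06, tau=3e-3
    )


@pytest.fixture(scope="session")
def spacing_gains():
    """Median-survival gains (months) of ID protocols over C28.

    Five independently seeded 100-per-arm trials per spacing; shared by the
    trade-off and survival-gain tests.
    """
    gains = {}
    for k in (7, 14, 21, 28, 35, 42):
        per_trial = []
        for j in range(5):
            spec = g.TrialSpec(n_per_arm=100, seed=1000 * k + j)
            res = g.run_trial(spec, g.CohortSpec(), "C28", f"ID{k}")
            per_trial.append(res.gain_months)
        gains[k] = per_trial
    return gains


@pytest.fixture(scope="session")
def recovery_fit(patient2_noiseless_record):
    """Multi-start fit of the noiseless synthetic patient-2 record."""
    return g.fit_patient(
        patient2_noiseless_record, g.FitConfig(n_restarts=12, seed=11)
    )


@pytest.fixture(scope="session")
def patient2_noiseless_record(fixture_data, patient2):
    """Synthetic noiseless longitudinal record from patient-2 parameters."""
    schedule = g.build_c28(16, start=100.0)
    obs_times = np.linspace(0.0, 2200.0, 12)
    traj = g.simulate(patient2, 20.0, schedule, g.SimulationConfig(horizon=2300.0))
    volumes = np.interp(obs_times, traj.times, traj.total_volume)
    return g.PatientRecord("synthetic-p2", obs_times, volumes, schedule)
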