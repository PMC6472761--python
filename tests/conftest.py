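import numpy as np
import pytest

from mtme.synthetic import TrialParams, simulate_trial


def make_params(n_progeny=40, n_locations=2, n_blocks=3, traits=("DM",),
                sigma_g=None, sigma_int=None, sigma_e=None,
                means=None, missing_rate=0.0):
    t = len(traits)
    eye = np.eye(t)
    return TrialParams(
        n_progeny=n_progeny, n_locations=n_locations, n_blocks=n_blocks,
        trait_names=traits,
        grand_means=means if means is not None else 100.0 * np.ones(t),
        sigma_g=sigma_g if sigma_g is not None else 30.0 * eye,
        sigma_int=sigma_int if sigma_int is not None else 10.0 * eye,
        sigma_e=sigma_e if sigma_e is not None else 20.0 * eye,
        missing_rate=missing_rate,
    )


@pytest.fixture(scope="session")
def st_trial():
    """Balanced 40-progeny single-trait trial with known truth."""
    params = make_params()
    table, truth = simulate_trial(params, seed=101)
    return params, table, truth


@pytest.fixture(scope="session")
def two_trait_trial():
    """Balanced 60-progeny two-trait trial with correlated components."""
    params = make_params(
        n_progeny=60, traits=("A", "B"), means=[50.0, 100.0],
        sigma_g=np.array([[10.0, 8.0], [8.0, 40.0]]),
        sigma_int=np.diag([4.0, 8.0]),
        sigma_e=np.array([[6.0, 5.0], [5.0, 30.0]]))
    table, truth = simulate_trial(params, seed=202)
    return params, table, truth


def assert_monotone_loglik(fit, slack=1e-6):
    """EM-REML restricted logL must never decrease along the trace."""
    tr = np.asarray(fit.loglik_trace)
    drops = np.diff(tr)
    assert drops.min() >= -slack * (1.0 + np.abs(tr).max()), \
        f"logL decreased by {-drops.min():.3g}"
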