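import numpy as np
import pytest

from circamood import SimConfig, simulate_matrix
from circamood.modeling import LabelSpec, RFConfig, RollingScheme, rolling_evaluate


@pytest.fixture(scope="session")
def small_sim():
    """A small coupled cohort shared by feature/labeling/modeling tests."""
    cfg = SimConfig(n_patients=3, n_days=45, seed=11)
    matrix, cohort, truth = simulate_matrix(cfg)
    return cfg, matrix, cohort, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    """One patient, no HR noise, no coupling: cosinor truth is exact."""
    cfg = SimConfig(n_patients=1, n_days=16, hr_noise_sd=0.0, coupling=0.0, seed=5)
    matrix, cohort, truth = simulate_matrix(cfg)
    return cfg, matrix, cohort, truth


def _seed_mean_aucs(coupling: float, seeds, n_patients=3, n_days=60, trees=50):
    out = []
    for seed in seeds:
        m, _, _ = simulate_matrix(
            SimConfig(n_patients=n_patients, n_days=n_days, coupling=coupling, seed=seed)
        )
        rep = rolling_evaluate(
            m, RollingScheme(p=18, q=3), LabelSpec(), RFConfig(n_estimators=trees), seed=seed
        )
        out.append(rep.mean("auc"))
    return np.array(out)


@pytest.fixture(scope="session")
def null_aucs():
    """Round-averaged mood-state AUC per seed at coupling = 0."""
    return _seed_mean_aucs(0.0, range(6))


@pytest.fixture(scope="session")
def coupled_aucs():
    """Round-averaged mood-state AUC per seed at coupling = 1."""
    return _seed_mean_aucs(1.0, range(100, 110))
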