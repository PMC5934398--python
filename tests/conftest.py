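"""Shared fixtures: the canonical oscillator network and derived ensembles.

The canonical model (3 lower + 2 higher channels, 16 Hz resonance, pole
radius 0.9, top-down lag-1 couplings H1->L1 = 0.25 and H2->L2 = 0.15, no
bottom-up coupling) is the ground truth against which closed-form oracles
are computed. Expensive ensembles are session-scoped.
"""

import numpy as np
import pytest

from sgckit import ConditionPairSpec, VarModel, build_var, simulate_trials
from sgckit.spectral import model_spectra, subtract_ensemble_mean
from sgckit.synth import canonical_network

CANONICAL_PAIRS = [("H1", "L1"), ("H2", "L2")]
DELTAS_30 = {
    "contingency1": {("H1", "L1"): 1.3},
    "contingency2": {("H1", "L1"): 0.7},
}


@pytest.fixture(scope="session")
def canonical_net():
    return canonical_network()


@pytest.fixture(scope="session")
def canonical_true_var(canonical_net):
    return build_var(canonical_net)


def true_pair_model(coeffs, labels_idx, labels, rate=200.0):
    """Bivariate sub-VAR of the true model; valid because the selected
    channels receive no input from outside the subset."""
    sub = coeffs[np.ix_(range(coeffs.shape[0]), labels_idx, labels_idx)]
    return VarModel(
        coeffs=sub,
        noise_cov=np.eye(2),
        restricted_resid_var=None,
        n_trials=1,
        samples_per_trial=sub.shape[0] + 1,
        sampling_rate=rate,
        channel_labels=list(labels),
    )


@pytest.fixture(scope="session")
def true_h1_l1_model(canonical_true_var):
    coeffs, _ = canonical_true_var
    # channel order is L1 L2 L3 H1 H2
    return true_pair_model(coeffs, [0, 3], ["L1", "H1"])


@pytest.fixture(scope="session")
def true_h1_l1_spectrum(true_h1_l1_model):
    fine = np.arange(5.0, 90.0001, 0.1)
    return model_spectra(true_h1_l1_model, fine)


@pytest.fixture(scope="session")
def canonical_ensemble(canonical_net):
    spec = ConditionPairSpec(
        base=canonical_net,
        trials_per_condition=5000,
        samples_per_trial=17,
        seed=7,
    )
    return simulate_trials(spec)


@pytest.fixture(scope="session")
def canonical_centered(canonical_ensemble):
    return subtract_ensemble_mean(canonical_ensemble)


@pytest.fixture(scope="session")
def two_condition_ensemble(canonical_net):
    spec = ConditionPairSpec(
        base=canonical_net,
        condition_deltas=DELTAS_30,
        trials_per_condition=2000,
        samples_per_trial=17,
        seed=11,
    )
    return simulate_trials(spec)


@pytest.fixture(scope="session")
def two_condition_centered(two_condition_ensemble):
    return subtract_ensemble_mean(two_condition_ensemble)


@pytest.fixture(scope="session")
def null_ensemble():
    """Independent channels, no coupling anywhere (global null)."""
    spec = ConditionPairSpec(
        base=canonical_network(topdown=()),
        trials_per_condition=2000,
        samples_per_trial=17,
        seed=19,
    )
    return subtract_ensemble_mean(simulate_trials(spec))
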