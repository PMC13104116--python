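"""Shared fixtures: small synthetic sessions reused across test modules."""

import dataclasses

import numpy as np
import pytest

from craniodyn.synth import SessionParams, build_schedule, make_atlas, simulate_session


@pytest.fixture(scope="session")
def atlas():
    return make_atlas(19)


@pytest.fixture(scope="session")
def small_params():
    return SessionParams(n_neurons=80)


@pytest.fixture(scope="session")
def session(small_params, atlas):
    """Default-condition session at a reduced neuron count."""
    schedule = build_schedule(small_params, seed=11)
    return simulate_session(small_params, schedule, atlas, seed=12)


@pytest.fixture(scope="session")
def separable_session(atlas):
    """Sharply tuned, nearly noiseless session: orientations separable."""
    params = dataclasses.replace(
        SessionParams(n_neurons=80), kappa=8.0, obs_noise=0.01,
        within_noise=0.0, between_noise=0.0, responsive_fraction=1.0)
    schedule = build_schedule(params, seed=21)
    return simulate_session(params, schedule, atlas, seed=22)


@pytest.fixture(scope="session")
def noise_session(atlas):
    """Session with no stimulus drive and no shared factors: white noise."""
    params = dataclasses.replace(
        SessionParams(n_neurons=300), responsive_fraction=0.0,
        within_noise=0.0, between_noise=0.0)
    schedule = build_schedule(params, seed=31)
    return simulate_session(params, schedule, atlas, seed=32)


def brute_force_pearson(x, y):
    """Direct-sum Pearson coefficient, independent of numpy.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    num = ((x - xm) * (y - ym)).sum()
    den = np.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum())
    return num / den


def brute_force_modularity(A, labels, gamma=1.0):
    """Literal double-sum modularity over ordered pairs."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    two_m = A.sum()
    k = A.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m
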