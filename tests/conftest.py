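"""Shared fixtures and the exhaustive-enumeration oracle.

The oracle computes sequence likelihood, posterior marginals and the
best hidden path by brute force over all 3**L paths, independently of
the dynamic-programming implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from modalhmm import HMMParams
from modalhmm.panel_io import SOURCES


def random_params(rng: np.random.Generator) -> HMMParams:
    """Dense random stochastic parameters (no structural zeros)."""

    def rows(n: int) -> np.ndarray:
        m = rng.random((n, 3)) + 0.05
        return m / m.sum(axis=1, keepdims=True)

    return HMMParams(pi=rows(1)[0], T=rows(3), emissions={s: rows(3) for s in SOURCES})


def random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random (L, 4) sequence in panel encoding, 0 = missing."""
    return rng.integers(0, 4, size=(length, len(SOURCES)))


def enumerate_paths(params: HMMParams, seq: np.ndarray):
    """Brute-force oracle over all hidden paths.

    Returns ``(loglik, gamma, best_path, best_logp)`` where ``gamma``
    are the exact posterior state marginals and ``best_path`` (codes
    1..3) attains the maximal joint probability ``best_logp``.
    """
    L = seq.shape[0]
    total = 0.0
    post = np.zeros((L, 3))
    best_path, best_p = None, -1.0
    for path in itertools.product(range(3), repeat=L):
        p = params.pi[path[0]]
        for t in range(L):
            if t:
                p *= params.T[path[t - 1], path[t]]
            for s, src in enumerate(SOURCES):
                o = seq[t, s]
                if o:
                    p *= params.emissions[src][path[t], o - 1]
        total += p
        for t in range(L):
            post[t, path[t]] += p
        if p > best_p:
            best_p, best_path = p, path
    return np.log(total), post / total, np.asarray(best_path) + 1, np.log(best_p)


def path_joint_logp(params: HMMParams, seq: np.ndarray, path: np.ndarray) -> float:
    """Joint log-probability of one hidden path and the observations."""
    s0 = np.asarray(path) - 1
    logp = np.log(params.pi[s0[0]])
    for t in range(len(s0)):
        if t:
            logp += np.log(params.T[s0[t - 1], s0[t]])
        for s, src in enumerate(SOURCES):
            o = seq[t, s]
            if o:
                logp += np.log(params.emissions[src][s0[t], o - 1])
    return float(logp)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230914)
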