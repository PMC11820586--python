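"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from fecgnet.synthgen import (
    FETAL_MORPHOLOGY,
    MATERNAL_MORPHOLOGY,
    ScenarioSpec,
    make_scenario_record,
    synth_single_ecg,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_fetal_record():
    """Clean synthetic fetal ECG: 140 bpm, 60 s at 250 Hz."""
    return synth_single_ecg(140, 60, 250, FETAL_MORPHOLOGY, rr_jitter_pct=3,
                            seed=5, role="fetal_truth")


@pytest.fixture(scope="session")
def clean_maternal_record():
    """Clean synthetic maternal ECG: 80 bpm, 60 s at 250 Hz."""
    return synth_single_ecg(80, 60, 250, MATERNAL_MORPHOLOGY, rr_jitter_pct=0,
                            seed=1, role="maternal_truth")


@pytest.fixture(scope="session")
def mixture_record():
    """A C0 mixture at 6 dB noise, 30 s — the bread-and-butter test input."""
    return make_scenario_record(
        ScenarioSpec(scenario="C0", noise_snr_db=6.0, seed=3), 30, 250)


@pytest.fixture(scope="session")
def noise_free_record():
    """Baseline mixture with no noise at all."""
    return make_scenario_record(
        ScenarioSpec(scenario="baseline", noise_snr_db=None, seed=4), 30, 250)


# ---------------------------------------------------------------------------
# independent scalar-loop oracles (kept free of the package's autograd path)

def conv1d_naive(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 convolution by explicit scalar loops.

    x: (C, L); w: (O, C, K); b: (O,).  Returns (O, L).
    """
    O, C, K = w.shape
    L = x.shape[1]
    pad = K // 2
    out = np.zeros((O, L))
    for o in range(O):
        for pos in range(L):
            acc = b[o]
            for c in range(C):
                for k in range(K):
                    src = pos + k - pad
                    if 0 <= src < L:
                        acc += x[c, src] * w[o, c, k]
            out[o, pos] = acc
    return out


def rrc_naive(x, w_f, b_f, w_r, b_r, T, act):
    """Hand-unrolled recurrent residual computation on one sample.

    y(0) = act(conv_f(x)); y(t) = act(conv_f(x) + conv_r(y(t-1)));
    returns x + y(T)  (equal channel counts assumed).
    """
    z = conv1d_naive(x, w_f, b_f)
    y = act(z)
    for _ in range(T):
        y = act(z + conv1d_naive(y, w_r, b_r))
    return x + y


def attention_gate_naive(u, g, w_u, w_g, b_g, w_psi, b_psi):
    """Element-by-element additive attention: sigmoid(psi(relu(Wu u + Wg g)))."""
    inter = conv1d_naive(u, w_u, np.zeros(w_u.shape[0]))
    inter = inter + conv1d_naive(g, w_g, b_g)
    inter = np.maximum(inter, 0.0)
    q = conv1d_naive(inter, w_psi, b_psi)
    alpha = 1.0 / (1.0 + np.exp(-q))
    return alpha * u


def optimal_matching_count(pred: np.ndarray, truth: np.ndarray,
                           tol: float) -> int:
    """Maximum one-to-one matching size by exhaustive recursion (<= ~8 peaks)."""

    def rec(i: int, used: frozenset) -> int:
        if i == len(pred):
            return 0
        best = rec(i + 1, used)  # leave prediction i unmatched
        for j, t in enumerate(truth):
            if j not in used and abs(int(pred[i]) - int(t)) <= tol:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())
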