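"""Shared fixtures and independent reference implementations.

The reference scorers here are deliberately naive (per-position Python
loops, explicit reverse complementation) so they stay independent of the
vectorized implementations they check.
"""

import numpy as np
import pytest

from tfcoop.features import MotifModel, reverse_complement

BASES = "ACGT"


def brute_force_best_hit(sequence: str, pwm: np.ndarray) -> float:
    """Exhaustive two-strand scan: max sum of PWM cells over all words."""
    W = pwm.shape[0]
    best = None
    for seq in (sequence, reverse_complement(sequence)):
        for start in range(len(seq) - W + 1):
            word = seq[start:start + W]
            if "N" in word:
                continue
            score = 0.0
            for j, base in enumerate(word):
                score += pwm[j, BASES.index(base)]
            if best is None or score > best:
                best = score
    return best


def brute_force_trap(sequence: str, motif: MotifModel, lambda_trap: float,
                     r0: float, pseudocount=0.8) -> float:
    """Direct per-site summation of TRAP occupancies on both strands."""
    freqs = motif.frequencies(pseudocount=pseudocount)
    W = motif.width
    total = 0.0
    for seq in (sequence, reverse_complement(sequence)):
        for start in range(len(seq) - W + 1):
            word = seq[start:start + W]
            if "N" in word:
                continue
            energy = 0.0
            for j, base in enumerate(word):
                energy += np.log(freqs[j].max() / freqs[j, BASES.index(base)])
            energy /= lambda_trap
            x = r0 * np.exp(-energy)
            total += x / (1.0 + x)
    return total


def fista_lasso_logistic(Xs, y, lam, iters=100000):
    """Proximal-gradient (FISTA) reference for the L1 logistic objective
    (1/n) sum -loglik + lam * ||beta||_1 with unpenalized intercept."""
    n, p = Xs.shape
    Xt = np.hstack([np.ones((n, 1)), Xs])
    L = (np.linalg.norm(Xt, 2) ** 2) / (4 * n)
    w = np.zeros(p + 1)
    z = w.copy()
    t = 1.0
    for _ in range(iters):
        pv = 1.0 / (1.0 + np.exp(-(Xt @ z)))
        g = Xt.T @ (pv - y) / n
        w_new = z - g / L
        w_new[1:] = np.sign(w_new[1:]) * np.maximum(np.abs(w_new[1:]) - lam / L, 0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = w_new + ((t - 1) / t_new) * (w_new - w)
        w, t = w_new, t_new
    return w[0], w[1:]


def random_sequence(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def random_motif(rng, width: int) -> MotifModel:
    counts = rng.integers(0, 30, size=(width, 4)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1.0
    return MotifModel("TFrand", f"Mrand{rng.integers(1_000_000)}", counts)


@pytest.fixture
def simple_motif():
    # consensus ACG, sharply defined
    return MotifModel("TFX", "M1", np.array(
        [[97, 1, 1, 1], [1, 97, 1, 1], [1, 1, 97, 1]], dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
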