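import numpy as np
import pytest

from regkit import motifs as M


@pytest.fixture
def uniform_bg():
    return np.full(4, 0.25)


@pytest.fixture
def usp_motif():
    return M.iupac_to_pwm("GGGGTCACS")


@pytest.fixture
def jhre_motif():
    return M.iupac_to_pwm("GRCACGCKVS")


def brute_force_score_table(motif):
    """Score of every 4^w word by direct per-word scoring (oracle path)."""
    w = motif.width
    lom = motif.log_odds
    n = 4 ** w
    digits = np.empty((n, w), dtype=np.int64)
    idx = np.arange(n)
    for j in range(w - 1, -1, -1):
        digits[:, j] = idx % 4
        idx //= 4
    scores = np.zeros(n)
    for j in range(w):
        scores += lom[j, digits[:, j]]
    probs = np.ones(n)
    for j in range(w):
        probs *= motif.background[digits[:, j]]
    return scores, probs


def brute_force_threshold(motif, alpha):
    """Threshold by full enumeration of all words (independent of the
    convolution code path)."""
    scores, probs = brute_force_score_table(motif)
    order = np.argsort(scores)
    s, p = scores[order], probs[order]
    # merge scores equal up to summation-order noise
    starts = np.concatenate([[0], np.flatnonzero(np.diff(s) > 1e-9) + 1])
    uniq = s[starts]
    mass = np.add.reduceat(p, starts)
    tails = np.cumsum(mass[::-1])[::-1]
    ok = np.flatnonzero(tails <= alpha + 1e-12)
    return float(uniq[ok[0]]) if len(ok) else float("inf")
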