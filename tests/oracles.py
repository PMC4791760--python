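"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np

from dsdseq.cnv import COPY_STATES, NBParams, ZERO_COPY_FRACTION, _emission_logpmf


def emission_matrix(ratios, nb, expected_copies):
    n_states = len(COPY_STATES)
    log_emit = np.empty((len(ratios), n_states))
    for w in range(len(ratios)):
        count = ratios[w] * nb[w].mean
        for s, cn in enumerate(COPY_STATES):
            frac = cn / expected_copies if cn > 0 else ZERO_COPY_FRACTION
            log_emit[w, s] = _emission_logpmf(count, nb[w], nb[w].mean * frac)
    return log_emit


def enumerate_best_path(ratios, expected_copies, nb, stay_prob):
    """Exhaustive maximum-likelihood path over all |states|^n_windows paths.

    Full path enumeration; independent of the Viterbi recursion it checks.
    Feasible up to ~7 windows with 5 states.
    """
    n_win = len(ratios)
    n_states = len(COPY_STATES)
    log_emit = emission_matrix(ratios, nb, expected_copies)
    log_trans = np.full((n_states, n_states), np.log((1 - stay_prob) / (n_states - 1)))
    np.fill_diagonal(log_trans, np.log(stay_prob))
    paths = np.indices((n_states,) * n_win).reshape(n_win, -1).T
    scores = np.full(len(paths), -np.log(n_states))
    for w in range(n_win):
        scores += log_emit[w, paths[:, w]]
        if w > 0:
            scores += log_trans[paths[:, w - 1], paths[:, w]]
    best = int(scores.argmax())
    return np.array([COPY_STATES[s] for s in paths[best]]), float(scores[best])


def enumerate_best_score(ratios, expected_copies, nb, stay_prob):
    """Best path score by incremental expansion (score only, low memory).

    Handles up to ~10 windows; used where materializing every path is too big.
    """
    n_states = len(COPY_STATES)
    log_emit = emission_matrix(ratios, nb, expected_copies)
    log_trans = np.full((n_states, n_states), np.log((1 - stay_prob) / (n_states - 1)))
    np.fill_diagonal(log_trans, np.log(stay_prob))
    scores = np.full(n_states, -np.log(n_states)) + log_emit[0]
    last = np.arange(n_states, dtype=np.int8)
    for w in range(1, len(ratios)):
        scores = (scores[:, None] + log_trans[last, :] + log_emit[w][None, :]).ravel()
        last = np.tile(np.arange(n_states, dtype=np.int8), len(last))
    return float(scores.max())
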