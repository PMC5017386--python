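"""Left-to-right chain HMM over the WHO routine and Viterbi smoothing.

The routine prescribes the gesture order, so the sequence model is a 9-state
chain: each state may only persist or advance to its immediate successor,
and the last state is absorbing.  Observations are the classifier's hard
per-frame labels, emitted through a discrete 9x9 confusion-style matrix
(probability ``emission_correct`` on the diagonal, the remainder spread
uniformly).  Decoding the maximum a posteriori state path then acts as a
global smoother: isolated misclassifications are overridden because leaving
a state costs log((1-self_prob)/self_prob) while a wrong observation only
costs the emission log-ratio, so a switch needs a sustained run of evidence.

The chain structure is hard: backward transitions have probability zero, so
every decoded path is monotone in the routine order with at most 8 switches.
Emission and initial probabilities are floored before taking logs so that no
observation sequence has zero likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GestureLabel, N_GESTURES

__all__ = ["ChainHMM", "build_who_chain", "viterbi_decode", "smooth_predictions"]

# finite stand-in for log(0): forbidden transitions stay unreachable in
# practice (any feasible path scores far above this) without breeding NaNs
LOG_ZERO = -1e30


@dataclass(frozen=True)
class ChainHMM:
    """Transition matrix A (9x9, left-to-right), discrete emission matrix B
    (state -> observed label), initial distribution pi, and the probability
    floor applied to B and pi before logs."""

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray
    log_floor: float = 1e-12

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if A.shape != (N_GESTURES, N_GESTURES) or B.shape != (N_GESTURES, N_GESTURES):
            raise ValueError("A and B must be 9x9")
        if pi.shape != (N_GESTURES,):
            raise ValueError("pi must have length 9")
        for name, M in (("A", A), ("B", B)):
            if np.abs(M.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"rows of {name} must sum to 1")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        upper = np.triu(np.ones_like(A), 2) + np.tril(np.ones_like(A), -1)
        if np.any(A * upper != 0):
            raise ValueError("A must be left-to-right: only self and successor transitions")
        if not (0 < self.log_floor < 1):
            raise ValueError("log_floor must be in (0, 1)")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "pi", pi)

    def log_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(logA, logB, logpi) with B and pi floored at log_floor; structural
        zeros of A map to a large negative sentinel, keeping the chain hard."""
        logA = np.where(self.A > 0, np.log(np.maximum(self.A, self.log_floor)), LOG_ZERO)
        logB = np.log(np.maximum(self.B, self.log_floor))
        logpi = np.log(np.maximum(self.pi, self.log_floor))
        return logA, logB, logpi


def build_who_chain(
    self_prob: float = 0.995,
    emission_correct: float = 0.9,
    start_at_first: bool = True,
    log_floor: float = 1e-12,
) -> ChainHMM:
    """Construct the 9-state routine chain.

    ``self_prob`` is the per-frame probability of staying in the current
    gesture (at 50 Hz, 0.995 makes a switch cost ~log(0.005/0.995), i.e.
    roughly two frames of consistent contrary evidence); ``emission_correct``
    is the modeled classifier accuracy, with the remaining mass uniform over
    the other 8 labels.  ``start_at_first`` pins the initial state to G1
    (the routine starts at palm cleaning); otherwise pi is uniform.
    """
    if not (0 < self_prob < 1):
        raise ValueError("self_prob must be in (0, 1)")
    if not (1.0 / N_GESTURES < emission_correct < 1):
        raise ValueError("emission_correct must be in (1/9, 1)")
    A = np.zeros((N_GESTURES, N_GESTURES))
    for i in range(N_GESTURES - 1):
        A[i, i] = self_prob
        A[i, i + 1] = 1.0 - self_prob
    A[-1, -1] = 1.0
    off = (1.0 - emission_correct) / (N_GESTURES - 1)
    B = np.full((N_GESTURES, N_GESTURES), off)
    np.fill_diagonal(B, emission_correct)
    if start_at_first:
        pi = np.zeros(N_GESTURES)
        pi[0] = 1.0
    else:
        pi = np.full(N_GESTURES, 1.0 / N_GESTURES)
    return ChainHMM(A=A, B=B, pi=pi, log_floor=log_floor)


def viterbi_decode(observations, hmm: ChainHMM) -> list[GestureLabel]:
    """Maximum a posteriori state path for a sequence of observed labels.

    Standard log-space Viterbi; ties during backtracking break toward the
    lower state ordinal.  Raises on an empty sequence.
    """
    obs = np.asarray(
        [o.ordinal if isinstance(o, GestureLabel) else int(o) for o in observations],
        dtype=np.int64,
    )
    T = obs.size
    if T == 0:
        raise ValueError("observation sequence is empty")
    logA, logB, logpi = hmm.log_matrices()

    delta = logpi + logB[:, obs[0]]
    psi = np.zeros((T, N_GESTURES), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[i, j]: best-so-far ending i, then i->j
        # argmax over i with ties to the lower ordinal: argmax picks first max
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(N_GESTURES)] + logB[:, obs[t]]

    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return [GestureLabel.from_ordinal(i) for i in path]


def smooth_predictions(frame_labels, hmm: ChainHMM) -> list[GestureLabel]:
    """Decode the classifier's frame-label track into the most probable
    routine-consistent sequence.  Because the chain is left-to-right, the
    output is monotone non-decreasing in gesture ordinal, hence contains at
    most 8 label switches."""
    return viterbi_decode(frame_labels, hmm)
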