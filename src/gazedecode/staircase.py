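"""Weighted up/down adaptive staircase and a simulated observer.

The probe-jitter staircase starts at 15 deg, increases the jitter by 1 deg
after an incorrect response, and decreases it by 0.5488 deg after two
consecutive correct responses.  At equilibrium the expected drift of the
jitter is zero; in the pair approximation (responses independent given the
jitter) this solves

    0.5488 * p^2 = 1 * (1 - p^2)   =>   p = sqrt(1 / 1.5488) ~= 0.8036,

i.e. a theoretical target performance of about 80% correct.  A simulated
observer with a monotone psychometric function verifies the convergence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["StaircaseState", "update", "equilibrium_p_correct",
           "ObserverResult", "simulate_observer"]


@dataclass(frozen=True)
class StaircaseState:
    """Immutable staircase state; ``update`` returns a new state."""

    jitter: float = 15.0
    step_up: float = 1.0
    step_down: float = 0.5488
    floor: float = 0.1          # keeps the jitter physically positive
    consecutive_correct: int = 0


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one response to the staircase.

    Incorrect: jitter += step_up, streak reset.  Correct: streak counter
    increments; on the second consecutive correct response the jitter
    decreases by step_down and the streak resets.  The jitter never drops
    below ``state.floor``.
    """
    if not correct:
        return replace(state, jitter=state.jitter + state.step_up,
                       consecutive_correct=0)
    if state.consecutive_correct + 1 >= 2:
        return replace(state, jitter=max(state.jitter - state.step_down,
                                         state.floor),
                       consecutive_correct=0)
    return replace(state, consecutive_correct=state.consecutive_correct + 1)


def equilibrium_p_correct(step_up: float = 1.0,
                          step_down: float = 0.5488) -> float:
    """Pair-approximation equilibrium percent-correct of the staircase."""
    return math.sqrt(step_up / (step_up + step_down))


@dataclass
class ObserverResult:
    proportion_correct: float     # over the post-burn-in trials
    jitter_trace: np.ndarray      # jitter before each trial
    responses: np.ndarray         # boolean per trial
    burn_in: int


def simulate_observer(psychometric, n_trials: int, seed: int = 0,
                      state: StaircaseState | None = None,
                      burn_in: int | None = None) -> ObserverResult:
    """Run the staircase against a stochastic observer.

    Parameters
    ----------
    psychometric : callable jitter -> probability correct
        Monotone increasing (larger jitter = easier discrimination), with
        range inside (0.5, 1).
    burn_in : trials discarded before the asymptotic proportion correct
        (default: the first half).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if state is None:
        state = StaircaseState()
    if burn_in is None:
        burn_in = n_trials // 2
    if abs(psychometric(state.floor) - psychometric(state.jitter + 50.0)) < 1e-12:
        warnings.warn("psychometric function looks constant; the staircase "
                      "cannot converge to a target performance", stacklevel=2)
    rng = np.random.default_rng(seed)
    trace = np.empty(n_trials)
    responses = np.empty(n_trials, dtype=bool)
    for i in range(n_trials):
        trace[i] = state.jitter
        correct = rng.random() < psychometric(state.jitter)
        responses[i] = correct
        state = update(state, correct)
    prop = float(responses[burn_in:].mean())
    return ObserverResult(proportion_correct=prop, jitter_trace=trace,
                          responses=responses, burn_in=burn_in)
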