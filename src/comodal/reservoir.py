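"""A single echo-state module: weights, leaky rate dynamics, FORCE readout.

The reservoir is a random recurrent network of ``N`` tanh rate units with
leaky (Euler) integration

    tau dx/dt = -x + g W r + W_in i(t) + W_back z(t) + k xi(t),
    r = tanh(x),        z = W_out r,

where only the readout matrix ``W_out`` is plastic.  Each readout reads a
fixed ``S``-subset of the reservoir and is trained online by recursive least
squares (FORCE): the inverse-correlation matrix ``P`` (one per readout, over
its subset) starts at ``I / alpha`` and is rank-1 downdated every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ModelParams


@dataclass
class ModuleWeights:
    """All matrices of one module plus the RLS state.

    ``W_in`` is stored factored as ``(in_index, in_weight)`` because each
    reservoir unit listens to exactly one input line; ``W_out`` is dense
    ``O x N`` but structurally zero outside each readout's support set.
    """

    W: np.ndarray                 # (N, N) recurrent
    in_index: np.ndarray          # (N,) input line per reservoir unit
    in_weight: np.ndarray         # (N,) weight on that line
    W_back: np.ndarray            # (N, O) feedback
    W_out: np.ndarray             # (O, N) readout, zero off-support
    P: np.ndarray                 # (O, S, S) RLS inverse correlation
    support: np.ndarray           # (O, S) reservoir indices per readout
    params: ModelParams

    @property
    def W_in(self) -> np.ndarray:
        """Dense (N, I) input matrix (one nonzero per row)."""
        N, I = self.params.N, self.params.I
        W_in = np.zeros((N, I))
        W_in[np.arange(N), self.in_index] = self.in_weight
        return W_in

    def copy(self) -> "ModuleWeights":
        return ModuleWeights(
            self.W.copy(), self.in_index.copy(), self.in_weight.copy(),
            self.W_back.copy(), self.W_out.copy(), self.P.copy(),
            self.support.copy(), self.params,
        )


@dataclass
class ReservoirState:
    """Membrane variables, rates and readouts of one module at one instant."""

    x: np.ndarray
    r: np.ndarray
    z: np.ndarray


def init_weights(params: ModelParams, rng: np.random.Generator) -> ModuleWeights:
    """Draw a fresh module.

    Distributions: nonzeros of ``W`` ~ N(0, 1/(pN)) on a Bernoulli(p)
    pattern; one input weight per unit ~ N(0, 1); feedback uniform on
    [-1, 1]; initial readout weights ~ N(0, 1/N) on the support.
    """
    N, I, O, S, p = params.N, params.I, params.O, params.S, params.p
    vals = rng.normal(0.0, np.sqrt(1.0 / (p * N)), (N, N))
    mask = rng.random((N, N)) < p
    W = np.where(mask, vals, 0.0)
    in_index = rng.integers(0, I, N)
    in_weight = rng.normal(0.0, 1.0, N)
    W_back = rng.uniform(-1.0, 1.0, (N, O))
    if params.shared_support:
        base = np.sort(rng.choice(N, S, replace=False))
        support = np.tile(base, (O, 1))
    else:
        support = np.stack(
            [np.sort(rng.choice(N, S, replace=False)) for _ in range(O)]
        )
    W_out = np.zeros((O, N))
    for i in range(O):
        W_out[i, support[i]] = rng.normal(0.0, np.sqrt(1.0 / N), S)
    P = np.broadcast_to(np.eye(S) / params.alpha, (O, S, S)).copy()
    return ModuleWeights(W, in_index, in_weight, W_back, W_out, P, support, params)


def init_state(weights: ModuleWeights, rng: np.random.Generator) -> ReservoirState:
    """Initial state: small Gaussian jitter around the origin."""
    x = weights.params.x0_jitter * rng.standard_normal(weights.params.N)
    r = np.tanh(x)
    return ReservoirState(x=x, r=r, z=weights.W_out @ r)


def step(
    state: ReservoirState,
    input_i: np.ndarray,
    feedback_z: np.ndarray,
    weights: ModuleWeights,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    noise: Optional[np.ndarray] = None,
) -> ReservoirState:
    """One forward-Euler step of the leaky rate dynamics.

    ``x <- x + (dt/tau) (-x + g W r + W_in i + W_back z + k xi)`` followed by
    ``r = tanh(x)`` and ``z = W_out r``.  The noise vector ``xi`` is fresh
    standard normal per step (pass ``noise`` to inject a known draw).
    """
    if noise is None:
        if params.k > 0:
            if rng is None:
                raise ValueError("rng (or an explicit noise vector) required when k > 0")
            noise = rng.standard_normal(params.N)
        else:
            noise = np.zeros(params.N)
    with np.errstate(invalid="ignore", over="ignore"):
        drive = (
            params.g * (weights.W @ state.r)
            + weights.in_weight * np.asarray(input_i)[weights.in_index]
            + weights.W_back @ np.asarray(feedback_z)
            + params.k * noise
        )
        x = state.x + (params.dt / params.tau) * (drive - state.x)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            "reservoir state diverged (non-finite membrane variable)"
        )
    r = np.tanh(x)
    return ReservoirState(x=x, r=r, z=weights.W_out @ r)


def readout(state: ReservoirState, weights: ModuleWeights) -> np.ndarray:
    """Linear readout ``z = W_out r`` (support-restricted by construction)."""
    return weights.W_out @ state.r


def force_update(
    weights: ModuleWeights,
    r: np.ndarray,
    error_e: np.ndarray,
) -> ModuleWeights:
    """One recursive-least-squares (FORCE) update of the readout weights.

    Per readout ``i`` with ``r_s = r[support[i]]``::

        P <- P - (P r_s r_s^T P) / (1 + r_s^T P r_s)
        W_out[i, support[i]] <- W_out[i, support[i]] - e_i * (P_new r_s)

    which strictly reduces the instantaneous error on the same sample.
    Operates in place and returns ``weights``.
    """
    error_e = np.asarray(error_e, dtype=float)
    if not np.all(np.isfinite(error_e)):
        raise ValueError("non-finite error passed to force_update")
    for i in range(weights.params.O):
        s = weights.support[i]
        rs = r[s]
        Pr = weights.P[i] @ rs
        a = 1.0 / (1.0 + rs @ Pr)
        weights.P[i] -= a * np.outer(Pr, Pr)
        weights.W_out[i, s] -= error_e[i] * a * Pr
    return weights
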