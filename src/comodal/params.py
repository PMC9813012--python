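"""Parameter containers for the collaborative multimodal reservoir model.

Three groups of knobs exist: the dynamics of a single echo-state module
(:class:`ModelParams`), the cross-module teaching/readout machinery
(:class:`TeachingParams`), and the synthetic stimulus pipeline
(:class:`StimulusParams`, :class:`ScheduleParams`).  Defaults follow the
full-size configuration of the study this package reproduces; the shipped
desk-scale experiment configs override ``N``, ``S`` and ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class ModelParams:
    """Hyperparameters of one echo-state (reservoir) module.

    Parameters
    ----------
    N : int
        Number of rate units in the reservoir.
    S : int
        Fan-in of each linear readout (number of reservoir units it reads).
    p : float
        Connection probability of the recurrent matrix ``W``.
    tau : float
        Membrane time constant in ms.
    g : float
        Gain on the recurrent term; ``g > 1`` yields chaotic spontaneous
        activity in the autonomous reservoir.
    k : float
        Amplitude of the per-step white noise injected into each unit.
    alpha : float
        RLS regularizer; the inverse-correlation matrix ``P`` starts at
        ``I / alpha``.  Plays the role of a learning rate in FORCE training.
    I : int
        Input dimensionality (26 for the letter channel, 30 for the image
        channel).
    O : int
        Number of readout units.
    dt : float
        Euler integration step in ms.
    force_interval : int
        Apply the RLS readout update every ``force_interval`` steps.
    x0_jitter : float
        Standard deviation of the Gaussian jitter on the initial membrane
        state.
    shared_support : bool
        If True all readouts read the same ``S``-subset of the reservoir;
        otherwise each readout samples its own subset.
    """

    N: int = 1200
    S: int = 300
    p: float = 0.5
    tau: float = 5.0
    g: float = 1.0
    k: float = 0.2
    alpha: float = 100.0
    I: int = 26
    O: int = 3
    dt: float = 1.0
    force_interval: int = 1
    x0_jitter: float = 0.1
    shared_support: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.S <= self.N):
            raise ValueError(f"need N >= S >= 1, got N={self.N}, S={self.S}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"connection probability p must be in (0, 1], got {self.p}")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.O < 1:
            raise ValueError("need at least one readout")
        if self.force_interval < 1:
            raise ValueError("force_interval must be >= 1")

    def with_input(self, I: int) -> "ModelParams":
        return replace(self, I=I)


@dataclass
class TeachingParams:
    """Parameters of the cross-module teaching signal and output integration.

    ``beta`` divides the argument of the tanh in the soft winner-take-all
    transform, ``gamma`` weights the competition term (the summed activity of
    the other readouts), ``T`` is the sliding window (ms) over which readout
    mean and s.d. are tracked for normalization, and ``delta`` weights the
    integrated output ``o = delta * (z1 + z2)``.
    """

    beta: float = 3.0
    gamma: float = 0.5
    T: float = 15000.0
    delta: float = 0.5
    sigma_floor: float = 1e-6
    hebb_eta: float = 1e-4

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.T <= 0:
            raise ValueError("normalization window T must be positive")

    def window_steps(self, dt: float) -> int:
        return max(1, int(round(self.T / dt)))


@dataclass
class StimulusParams:
    """Geometry and timing of the synthetic two-modality stimuli.

    A letter occupies a fixed slot of ``letter_slot_ms``; within the slot a
    rectangular pulse of amplitude ``pulse_amplitude`` covers the leading
    ``pulse_fraction`` of the slot.  Images are ``image_size`` x
    ``image_size`` RGB rasters split into ``sections`` horizontal bands and
    scanned left to right with a ``window_cols``-wide mean-pooling window,
    giving a ``3 * sections``-dimensional time series (scaled by
    ``image_gain``) whose length matches the paired letter signal.

    The default drive amplitudes (``pulse_amplitude = image_gain = 8``) put
    the reservoirs in an input-dominated regime; with unit-scale inputs the
    self-generated feedback dynamics swamp the stimulus-locked response the
    collaborative teaching has to latch onto (see docs/methods.md).
    """

    alphabet: str = ALPHABET
    letter_slot_ms: float = 50.0
    pulse_fraction: float = 0.8
    pulse_amplitude: float = 8.0
    image_size: int = 60
    sections: int = 10
    window_cols: int = 6
    image_gain: float = 8.0
    dt: float = 1.0
    noise_image_mean: float = 0.5
    noise_image_sd: float = 0.25
    image_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.alphabet) == 0:
            raise ValueError("alphabet must be nonempty")
        if not (0.0 < self.pulse_fraction <= 1.0):
            raise ValueError("pulse_fraction must be in (0, 1]")
        if self.image_size % self.sections != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible into {self.sections} sections"
            )
        if not (1 <= self.window_cols <= self.image_size):
            raise ValueError("window_cols must be in [1, image_size]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def slot_steps(self) -> int:
        return max(1, int(round(self.letter_slot_ms / self.dt)))

    @property
    def n_image_dims(self) -> int:
        return 3 * self.sections

    @property
    def n_text_dims(self) -> int:
        return len(self.alphabet)


@dataclass
class ScheduleParams:
    """How chunk and random-separator epochs are interleaved into a stream.

    ``C`` counts *all* presentation epochs, random separators included.  With
    ``use_separators`` on, epochs alternate random / chunk; off, every epoch
    is a chunk.  ``m`` is the pair-replacement (non-co-occurrence)
    probability and ``d`` the inter-modal delay in ms; both default to the
    unmanipulated stream.
    """

    C: int = 2200
    chunk_probabilities: Tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    use_separators: bool = True
    m: float = 0.0
    d: float = 0.0
    delayed_modality: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("m must be in [0, 1]")
        if self.d < 0:
            raise ValueError("delay d must be >= 0")
        probs = tuple(float(q) for q in self.chunk_probabilities)
        if any(q < 0 for q in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("chunk_probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "chunk_probabilities", probs)
        if self.delayed_modality not in (1, 2):
            raise ValueError("delayed_modality must be 1 or 2")
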