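"""Two echo-state modules that teach each other.

The collaborative model couples two reservoir modules processing different
modalities.  Each module's readouts are normalized online to zero mean and
unit s.d. over a long sliding window; a soft winner-take-all transform of
the *partner's* normalized readouts serves as each module's FORCE teaching
signal, so the pair self-organizes chunk-selective, index-aligned readouts
without any labels.  The integrated output ``o = delta (z1 + z2)`` is the
quantity scored.

Alternative interaction architectures replace the cross-fed teaching signal
(which becomes module-local) with direct structural coupling:

* ``a1`` - sparse reservoir-to-reservoir input connections (density 0.1),
* ``a2`` - each module's readouts also feed back into the partner reservoir,
* ``a3`` - all-to-all additive coupling between the two readout vectors,

and an association layer with a normalized Hebbian rule then has to align
the two modules' independently learned readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _kernels
from .params import ModelParams, TeachingParams
from .reservoir import ModuleWeights, init_state, init_weights
from .stimulus import StimulusTrack

VARIANTS = ("original", "a1", "a2", "a3")
_VARIANT_CODE = {v: i for i, v in enumerate(VARIANTS)}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

class RunningStats:
    """Sliding-window mean and s.d. of a readout vector.

    Tracks the last ``window_steps`` samples per channel with O(1) updates
    (running sum and sum of squares over a circular buffer; the sums are
    recomputed exactly every wrap to cancel float drift).  ``warm`` becomes
    True once a full window has been observed.
    """

    def __init__(self, n_channels: int, window_steps: int):
        if window_steps < 1:
            raise ValueError("window must hold at least one sample")
        self.buf = np.zeros((window_steps, n_channels))
        self.sum = np.zeros(n_channels)
        self.sumsq = np.zeros(n_channels)
        self.count = 0
        self.pos = 0

    @property
    def window_steps(self) -> int:
        return self.buf.shape[0]

    @property
    def warm(self) -> bool:
        return self.count >= self.window_steps

    def push(self, z: np.ndarray) -> None:
        z = np.asarray(z, dtype=float)
        win = self.window_steps
        if self.count >= win:
            old = self.buf[self.pos]
            self.sum += z - old
            self.sumsq += z * z - old * old
        else:
            self.sum += z
            self.sumsq += z * z
        self.buf[self.pos] = z
        self.count += 1
        self.pos = (self.pos + 1) % win
        if self.pos == 0 and self.count >= win:
            self.sum = self.buf.sum(axis=0)
            self.sumsq = (self.buf ** 2).sum(axis=0)

    @property
    def n_eff(self) -> int:
        return min(self.count, self.window_steps)

    def mean(self) -> np.ndarray:
        if self.count == 0:
            raise ValueError("no samples observed yet")
        return self.sum / self.n_eff

    def std(self) -> np.ndarray:
        mu = self.mean()
        var = np.maximum(self.sumsq / self.n_eff - mu ** 2, 0.0)
        return np.sqrt(var)


def normalize_output(
    z: np.ndarray,
    stats: RunningStats,
    sigma_floor: float = 1e-6,
) -> np.ndarray:
    """``zhat_i = (z_i - mu_i) / sigma_i`` with the sliding-window statistics.

    Channels whose windowed s.d. falls below ``sigma_floor`` (e.g. a
    constant readout at cold start) are returned as 0.
    """
    mu = stats.mean()
    sd = stats.std()
    zhat = np.zeros_like(mu)
    ok = sd >= sigma_floor
    zhat[ok] = (np.asarray(z, dtype=float)[ok] - mu[ok]) / sd[ok]
    return zhat


def teaching_signal(zhat_partner: np.ndarray, teaching: TeachingParams) -> np.ndarray:
    """Soft winner-take-all FORCE target from the partner's normalized readouts.

    ``f_i = [tanh((zhat_i - gamma * sum_{j != i} zhat_j) / beta)]_+`` with the
    threshold-linear ``[x]_+`` clipping negatives to zero; values lie in
    [0, 1) and the map is equivariant under index permutation.
    """
    zhat = np.asarray(zhat_partner, dtype=float)
    others = zhat.sum() - zhat
    return np.maximum(0.0, np.tanh((zhat - teaching.gamma * others) / teaching.beta))


def output_error(z: np.ndarray, f: np.ndarray) -> np.ndarray:
    """FORCE error ``e = z - f`` (elementwise)."""
    z = np.asarray(z, dtype=float)
    f = np.asarray(f, dtype=float)
    if z.shape != f.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {f.shape}")
    return z - f


def integrated_output(z1: np.ndarray, z2: np.ndarray, delta: float = 0.5) -> np.ndarray:
    """Association-layer output of the original model, ``o = delta (z1 + z2)``."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError(f"shape mismatch: {z1.shape} vs {z2.shape}")
    return delta * (z1 + z2)


def assoc_output_and_hebb(
    z1: np.ndarray,
    z2: np.ndarray,
    assoc_w: Tuple[np.ndarray, np.ndarray],
    dt: float,
    eta: float = 1e-4,
) -> Tuple[np.ndarray, Tuple[np.ndarray, np.ndarray]]:
    """Association output plus one Euler step of the normalized Hebbian rule.

    ``o = w1 z1 + w2 z2`` with current weights; then
    ``dw_ij/dt = o_i z_j - o_i (sum_j z_j) / n`` (Hebb minus mean
    normalization, so every row sum of ``dw`` is zero) integrated at ``dt``
    with rate multiplier ``eta``.  Returns ``o`` and the updated weights.
    """
    w1, w2 = assoc_w
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    o = w1 @ z1 + w2 @ z2
    n = z1.shape[0]
    w1 = w1 + dt * eta * np.outer(o, z1 - z1.sum() / n)
    w2 = w2 + dt * eta * np.outer(o, z2 - z2.sum() / n)
    return o, (w1, w2)


# ---------------------------------------------------------------------------
# model container and construction
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Two coupled modules, the interaction variant and its extra matrices."""

    rc1: ModuleWeights
    rc2: ModuleWeights
    variant: str
    teaching: TeachingParams
    seed: Optional[int] = None
    # variant-specific couplings (present iff the variant demands them)
    W_in_inter_1: Optional[np.ndarray] = None   # a1: module1 <- module2 rates
    W_in_inter_2: Optional[np.ndarray] = None
    W_back_inter_1: Optional[np.ndarray] = None  # a2: module1 <- module2 readouts
    W_back_inter_2: Optional[np.ndarray] = None
    R1: Optional[np.ndarray] = None              # a3: readout-to-readout mixing
    R2: Optional[np.ndarray] = None
    assoc_w1: Optional[np.ndarray] = None        # Hebbian association weights
    assoc_w2: Optional[np.ndarray] = None

    @property
    def O(self) -> int:
        return self.rc1.params.O

    def copy(self) -> "TrainedModel":
        cp = lambda a: None if a is None else a.copy()
        return TrainedModel(
            self.rc1.copy(), self.rc2.copy(), self.variant, self.teaching,
            self.seed, cp(self.W_in_inter_1), cp(self.W_in_inter_2),
            cp(self.W_back_inter_1), cp(self.W_back_inter_2),
            cp(self.R1), cp(self.R2), cp(self.assoc_w1), cp(self.assoc_w2),
        )

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        import dataclasses as dc
        import json

        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["variant"] = self.variant
            f.attrs["teaching"] = json.dumps(dc.asdict(self.teaching))
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            for name, rc in (("rc1", self.rc1), ("rc2", self.rc2)):
                grp = f.create_group(name)
                for key in ("W", "in_index", "in_weight", "W_back", "W_out",
                            "P", "support"):
                    grp.create_dataset(key, data=getattr(rc, key), compression="gzip")
                grp.attrs["params"] = json.dumps(dc.asdict(rc.params))
            for key in ("W_in_inter_1", "W_in_inter_2", "W_back_inter_1",
                        "W_back_inter_2", "R1", "R2", "assoc_w1", "assoc_w2"):
                val = getattr(self, key)
                if val is not None:
                    f.create_dataset(key, data=val)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            rcs = []
            for name in ("rc1", "rc2"):
                grp = f[name]
                params = ModelParams(**json.loads(grp.attrs["params"]))
                rcs.append(ModuleWeights(
                    grp["W"][:], grp["in_index"][:], grp["in_weight"][:],
                    grp["W_back"][:], grp["W_out"][:], grp["P"][:],
                    grp["support"][:], params))
            kwargs = {}
            for key in ("W_in_inter_1", "W_in_inter_2", "W_back_inter_1",
                        "W_back_inter_2", "R1", "R2", "assoc_w1", "assoc_w2"):
                if key in f:
                    kwargs[key] = f[key][:]
            teaching = TeachingParams(**json.loads(f.attrs["teaching"]))
            seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
            return cls(rcs[0], rcs[1], str(f.attrs["variant"]), teaching,
                       seed, **kwargs)


def build_model(
    variant: str,
    params1: ModelParams,
    params2: ModelParams,
    teaching: TeachingParams,
    rng: np.random.Generator,
    inter_p: float = 0.1,
    assoc_init_scale: float = 0.1,
) -> TrainedModel:
    """Construct an untrained model for one interaction architecture.

    ``original`` allocates no cross matrices (the coupling lives in the
    teaching signals).  ``a1`` draws sparse reservoir-to-reservoir input
    matrices (Bernoulli ``inter_p`` pattern, N(0, 1) values, built like the
    input matrix); ``a2`` draws uniform [-1, 1] cross-feedback matrices like
    the within-module feedback; ``a3`` draws dense uniform [-1, 1]
    readout-to-readout mixing matrices.  Variants also get a Hebbian
    association layer with small positive uniform initial weights.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if params1.O != params2.O:
        raise ValueError("both modules must have the same number of readouts")
    rc1 = init_weights(params1, rng)
    rc2 = init_weights(params2, rng)
    model = TrainedModel(rc1, rc2, variant, teaching)
    O = params1.O
    if variant == "a1":
        for tgt, (n_to, n_from) in (("W_in_inter_1", (params1.N, params2.N)),
                                    ("W_in_inter_2", (params2.N, params1.N))):
            vals = rng.normal(0.0, 1.0, (n_to, n_from))
            mask = rng.random((n_to, n_from)) < inter_p
            setattr(model, tgt, np.where(mask, vals, 0.0))
    elif variant == "a2":
        model.W_back_inter_1 = rng.uniform(-1.0, 1.0, (params1.N, O))
        model.W_back_inter_2 = rng.uniform(-1.0, 1.0, (params2.N, O))
    elif variant == "a3":
        model.R1 = rng.uniform(-1.0, 1.0, (O, O))
        model.R2 = rng.uniform(-1.0, 1.0, (O, O))
    if variant != "original":
        model.assoc_w1 = rng.uniform(0.0, assoc_init_scale, (O, O))
        model.assoc_w2 = rng.uniform(0.0, assoc_init_scale, (O, O))
    return model


# ---------------------------------------------------------------------------
# training / inference driver
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Per-step records of one pass over a track.

    ``z1``/``z2`` are the (effective) readouts, ``f1``/``f2`` the teaching
    signals, ``o`` the association output.  ``wout_norm`` samples the
    Frobenius norms of the two readout matrices once per kernel block (at
    the steps in ``wout_norm_t``).  Rate snapshots ``r1``/``r2`` are present
    when ``record_stride > 0``.
    """

    z1: np.ndarray
    z2: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    o: np.ndarray
    wout_norm: np.ndarray          # (n_blocks, 2)
    wout_norm_t: np.ndarray
    r1: Optional[np.ndarray] = None
    r2: Optional[np.ndarray] = None
    record_stride: int = 0


_EMPTY_I = np.zeros(1, dtype=np.int64)
_EMPTY_F = np.zeros(1)
_EMPTY_M = np.zeros((1, 1))


def _csr_or_dummy(mat: Optional[np.ndarray]):
    if mat is None:
        ptr = np.zeros(1, dtype=np.int64)
        return ptr, _EMPTY_I, _EMPTY_F
    from scipy.sparse import csr_matrix

    sp = csr_matrix(mat)
    return (sp.indptr.astype(np.int64), sp.indices.astype(np.int64),
            sp.data.astype(float))


def _run(
    model: TrainedModel,
    track: StimulusTrack,
    rng: np.random.Generator,
    learn: bool,
    record_stride: int = 0,
    block_size: int = 4096,
    stats: Optional[Tuple[RunningStats, RunningStats]] = None,
) -> RunResult:
    p1, p2 = model.rc1.params, model.rc2.params
    if track.modality1.shape[1] != p1.I or track.modality2.shape[1] != p2.I:
        raise ValueError(
            "track widths "
            f"({track.modality1.shape[1]}, {track.modality2.shape[1]}) do not "
            f"match module input dims ({p1.I}, {p2.I})")
    if p1.dt != p2.dt or abs(track.dt - p1.dt) > 1e-12:
        raise ValueError("track and both modules must share the same dt")
    T = track.n_steps
    O = p1.O
    dt = p1.dt
    win = model.teaching.window_steps(dt)

    s1 = init_state(model.rc1, rng)
    s2 = init_state(model.rc2, rng)
    if stats is None:
        stats = (RunningStats(O, win), RunningStats(O, win))
    st1, st2 = stats
    counters = np.zeros(3, dtype=np.int64)
    counters[0] = st1.count
    counters[1] = st1.pos

    z1 = np.empty((T, O)); z2 = np.empty((T, O))
    f1 = np.empty((T, O)); f2 = np.empty((T, O))
    o = np.empty((T, O))
    n_rec = (T + record_stride - 1) // record_stride if record_stride > 0 else 0
    r1_rec = np.empty((n_rec, p1.N)) if n_rec else _EMPTY_M
    r2_rec = np.empty((n_rec, p2.N)) if n_rec else _EMPTY_M

    a1_ptr1, a1_idx1, a1_dat1 = _csr_or_dummy(model.W_in_inter_1)
    a1_ptr2, a1_idx2, a1_dat2 = _csr_or_dummy(model.W_in_inter_2)
    wbi1 = model.W_back_inter_1 if model.W_back_inter_1 is not None else _EMPTY_M
    wbi2 = model.W_back_inter_2 if model.W_back_inter_2 is not None else _EMPTY_M
    R1 = model.R1 if model.R1 is not None else _EMPTY_M
    R2 = model.R2 if model.R2 is not None else _EMPTY_M
    w_a1 = model.assoc_w1 if model.assoc_w1 is not None else _EMPTY_M
    w_a2 = model.assoc_w2 if model.assoc_w2 is not None else _EMPTY_M

    warm_min = getattr(model.teaching, 'warmup_steps', None)
    warm_min = win if warm_min is None else warm_min
    pretrain_zero = bool(getattr(model.teaching, 'pretrain_zero', False))
    norms: List[Tuple[float, float]] = []
    norm_t: List[int] = []
    code = _VARIANT_CODE[model.variant]
    for t0 in range(0, T, block_size):
        t1 = min(t0 + block_size, T)
        sl = slice(t0, t1)
        noise1 = rng.standard_normal((t1 - t0, p1.N))
        noise2 = rng.standard_normal((t1 - t0, p2.N))
        _kernels.run_block(
            s1.x, s1.r, s2.x, s2.r,
            model.rc1.W, model.rc1.in_index, model.rc1.in_weight,
            model.rc1.W_back, model.rc1.W_out, model.rc1.P, model.rc1.support,
            model.rc2.W, model.rc2.in_index, model.rc2.in_weight,
            model.rc2.W_back, model.rc2.W_out, model.rc2.P, model.rc2.support,
            track.modality1[sl], track.modality2[sl], noise1, noise2,
            st1.buf, st1.sum, st1.sumsq, st2.buf, st2.sum, st2.sumsq, counters,
            dt, p1.tau, p2.tau, p1.g, p2.g, p1.k, p2.k,
            model.teaching.beta, model.teaching.gamma,
            model.teaching.sigma_floor, model.teaching.delta,
            model.teaching.hebb_eta,
            code, learn, p1.force_interval, t0, warm_min, pretrain_zero,
            a1_ptr1, a1_idx1, a1_dat1, a1_ptr2, a1_idx2, a1_dat2,
            wbi1, wbi2, R1, R2, w_a1, w_a2,
            z1[sl], z2[sl], f1[sl], f2[sl], o[sl],
            r1_rec, r2_rec, record_stride,
        )
        if not (np.all(np.isfinite(s1.x)) and np.all(np.isfinite(s2.x))):
            raise FloatingPointError(
                f"simulation diverged in steps [{t0}, {t1}) "
                f"(variant={model.variant}, learn={learn})")
        norms.append((np.linalg.norm(model.rc1.W_out),
                      np.linalg.norm(model.rc2.W_out)))
        norm_t.append(t1)
    st1.count = st2.count = int(counters[0])
    st1.pos = st2.pos = int(counters[1])
    return RunResult(
        z1=z1, z2=z2, f1=f1, f2=f2, o=o,
        wout_norm=np.asarray(norms), wout_norm_t=np.asarray(norm_t),
        r1=r1_rec if n_rec else None, r2=r2_rec if n_rec else None,
        record_stride=record_stride,
    )


def train(
    model: TrainedModel,
    track: StimulusTrack,
    seed: int = 0,
    record_stride: int = 0,
    block_size: int = 4096,
) -> Tuple[TrainedModel, RunResult]:
    """FORCE-train both modules jointly on one pass over ``track``.

    Both modules are stepped each ``dt``; sliding statistics warm up for one
    full normalization window before any teaching or weight update, after
    which RLS updates run every ``force_interval`` steps (and for variants
    the Hebbian association layer learns concurrently).  Returns the model
    (modified in place) and the training log.  A zero-length track returns
    the model unchanged.
    """
    if track.n_steps == 0:
        return model, RunResult(
            *(np.zeros((0, model.O)) for _ in range(5)),
            wout_norm=np.zeros((0, 2)), wout_norm_t=np.zeros(0, dtype=int))
    rng = np.random.default_rng(seed)
    model.seed = seed
    log = _run(model, track, rng, learn=True,
               record_stride=record_stride, block_size=block_size)
    return model, log


def run_inference(
    model: TrainedModel,
    track: StimulusTrack,
    seed: int = 1,
    record_stride: int = 0,
    block_size: int = 4096,
) -> RunResult:
    """Forward-only pass with frozen weights (deterministic given ``seed``)."""
    rng = np.random.default_rng(seed)
    frozen = model.copy()
    res = _run(frozen, track, rng, learn=False,
               record_stride=record_stride, block_size=block_size)
    return res
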