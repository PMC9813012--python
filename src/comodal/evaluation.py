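"""Scoring and population-dynamics metrics.

Chunk-detection performance: the association output is smoothed with a
causal Gaussian kernel, min-max normalized per unit, and each annotated
epoch is assigned to the readout with the largest epoch response (or
"no-response" when every unit stays below threshold; no-response is the
correct answer for random separators).  Because learning is unsupervised,
the chunk <-> unit assignment is chosen to maximize the confusion-matrix
diagonal before computing accuracy.

Population dynamics: PCA trajectories of the reservoir rates per chunk,
their trial-averaged centers, deviations and pairwise separation degree
``r_XY`` (smaller = better separated), circular-mean activation phases, and
the effective dimension (inverse participation ratio) of the PCA spectrum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

NO_RESPONSE = "no-response"
RANDOM_LABEL = "random"


# ---------------------------------------------------------------------------
# response scoring
# ---------------------------------------------------------------------------

def smooth_and_normalize(
    o_series: np.ndarray,
    window_sd: float = 20.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Causal Gaussian smoothing then per-unit min-max rescale to [0, 1].

    The kernel has s.d. ``window_sd`` ms, truncated at 3 s.d., and is purely
    causal (each output sample only sees the past).  The min-max rescaling
    uses one common scale across units, so relative response amplitudes
    between units are preserved (a weakly modulated unit stays weak); it
    makes the result invariant to the overall amplitude of the raw output.
    A constant series maps to all-zero.
    """
    o = np.asarray(o_series, dtype=float)
    if o.ndim == 1:
        o = o[:, None]
    if o.shape[0] == 0:
        raise ValueError("empty series")
    sd_steps = window_sd / dt
    half = max(1, int(np.ceil(3 * sd_steps)))
    t = np.arange(half + 1, dtype=float)
    kern = np.exp(-0.5 * (t / sd_steps) ** 2)
    kern /= kern.sum()
    # edge correction: renormalize by the kernel mass actually inside the
    # series so a constant input stays exactly constant
    mass = np.ones(o.shape[0])
    ramp = np.cumsum(kern)
    n = min(len(ramp), o.shape[0])
    mass[:n] = ramp[:n]
    out = np.empty_like(o)
    for j in range(o.shape[1]):
        out[:, j] = np.convolve(o[:, j], kern, mode="full")[: o.shape[0]] / mass
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def score_epochs(
    smoothed: np.ndarray,
    annotations: pd.DataFrame,
    no_response_threshold: float = 0.3,
    dt: float = 1.0,
    statistic: str = "mean",
) -> List[str]:
    """Winner unit per annotated epoch (``"no-response"`` if all below threshold).

    The epoch response of a unit is the mean (or, with
    ``statistic="peak"``, the maximum) of its smoothed normalized trace over
    the epoch; ties go to the lowest unit index.
    """
    if statistic not in ("mean", "peak"):
        raise ValueError("statistic must be 'mean' or 'peak'")
    winners = []
    for row in annotations.itertuples():
        a = int(round(row.onset_ms / dt))
        b = int(round(row.offset_ms / dt))
        seg = smoothed[a:b]
        resp = seg.mean(axis=0) if statistic == "mean" else seg.max(axis=0)
        if np.all(resp < no_response_threshold):
            winners.append(NO_RESPONSE)
        else:
            winners.append(f"unit{int(np.argmax(resp))}")
    return winners


def confusion_matrix(
    winners: Sequence[str],
    labels: Sequence[str],
    chunk_names: Sequence[str],
    n_units: int,
) -> pd.DataFrame:
    """Counts of (presented label) x (winning unit), randoms included.

    Rows are the chunk names plus ``"random"``; columns the readout units
    plus ``"no-response"``.  Entries sum to the number of epochs.
    """
    rows = list(chunk_names) + [RANDOM_LABEL]
    cols = [f"unit{i}" for i in range(n_units)] + [NO_RESPONSE]
    cm = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for lab, win in zip(labels, winners):
        cm.loc[lab, win] += 1
    return cm


def accuracy(cm: pd.DataFrame) -> float:
    """Assignment-maximized diagonal fraction of the confusion matrix.

    Because chunk selectivity is self-organized, units are matched to
    chunks by maximizing the summed diagonal over all chunk <-> unit
    assignments (Hungarian algorithm; equivalent to exhausting the 3!
    permutations for three chunks).  The random <-> no-response cell is
    fixed.  Returns (best diagonal sum) / (total epochs).
    """
    total = int(cm.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    chunk_rows = [r for r in cm.index if r != RANDOM_LABEL]
    unit_cols = [c for c in cm.columns if c != NO_RESPONSE]
    sub = cm.loc[chunk_rows, unit_cols].to_numpy()
    ri, ci = linear_sum_assignment(sub, maximize=True)
    diag = int(sub[ri, ci].sum())
    if RANDOM_LABEL in cm.index and NO_RESPONSE in cm.columns:
        diag += int(cm.loc[RANDOM_LABEL, NO_RESPONSE])
    return diag / total


def evaluate_outputs(
    o_series: np.ndarray,
    annotations: pd.DataFrame,
    chunk_names: Sequence[str],
    window_sd: float = 20.0,
    no_response_threshold: float = 0.3,
    dt: float = 1.0,
    statistic: str = "mean",
) -> Tuple[float, pd.DataFrame]:
    """Smooth, score and summarize one output series: (accuracy, confusion)."""
    sm = smooth_and_normalize(o_series, window_sd=window_sd, dt=dt)
    winners = score_epochs(sm, annotations, no_response_threshold, dt, statistic)
    cm = confusion_matrix(winners, list(annotations["label"]), chunk_names,
                          o_series.shape[1])
    return accuracy(cm), cm


# ---------------------------------------------------------------------------
# reservoir activity analyses
# ---------------------------------------------------------------------------

def activation_phase(r_history: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Circular-mean activation time of each neuron over one epoch of length T.

    Each neuron's rate trace is min-max normalized; the phase is the
    argument of its first Fourier coefficient mapped back to time,
    ``t_i = (T / 2pi) * arg sum_t rhat_i(t) exp(i 2pi t / T)`` (wrapped into
    [0, T)).  Neurons with zero total normalized activity have no defined
    phase and come back as NaN.
    """
    r = np.atleast_2d(np.asarray(r_history, dtype=float))
    Tn = r.shape[0]
    if Tn < 1:
        raise ValueError("empty epoch")
    lo = r.min(axis=0)
    hi = r.max(axis=0)
    span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
    rhat = (r - lo) / span
    t = np.arange(Tn)
    phasor = np.exp(1j * 2 * np.pi * t / Tn)
    num = rhat.T @ phasor
    tot = rhat.sum(axis=0)
    phases = np.full(r.shape[1], np.nan)
    ok = tot > 1e-12
    ang = np.angle(num[ok])
    phases[ok] = (ang % (2 * np.pi)) * (Tn * dt) / (2 * np.pi)
    return phases


def pca_trajectories(
    reservoir_history: np.ndarray,
    annotations: pd.DataFrame,
    dt: float = 1.0,
    record_stride: int = 1,
    n_components: int = 3,
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Project every chunk epoch into the top principal components.

    The PCA basis is fitted on the pooled rate history (chunks and randoms
    alike).  Returns ``(trials, spectrum)`` where ``trials[chunk]`` is an
    array ``(n_trials, T_chunk, n_components)`` of per-presentation
    trajectories (all presentations of a chunk share a duration) and
    ``spectrum`` holds all PCA eigenvalues (explained variances).
    """
    H = np.asarray(reservoir_history, dtype=float)
    if H.shape[0] < 2:
        raise ValueError("need at least two time samples for PCA")
    from sklearn.decomposition import PCA

    pca = PCA()
    proj = pca.fit_transform(H)
    k = min(n_components, proj.shape[1])
    trials: Dict[str, List[np.ndarray]] = {}
    for row in annotations.itertuples():
        if row.label == RANDOM_LABEL:
            continue
        a = int(round(row.onset_ms / dt)) // record_stride
        b = int(round(row.offset_ms / dt)) // record_stride
        seg = proj[a:b, :k]
        trials.setdefault(row.label, []).append(seg)
    out = {}
    for name, segs in trials.items():
        L = min(s.shape[0] for s in segs)
        out[name] = np.stack([s[:L] for s in segs])
    return out, pca.explained_variance_


@dataclass
class TrajectorySummary:
    """Trial-averaged trajectory geometry for every chunk pair."""

    centers: Dict[str, np.ndarray]          # chunk -> (T, 3) center trajectory
    sigma: Dict[str, np.ndarray]            # chunk -> (T,) deviation
    n_trials: Dict[str, int]
    d: Dict[Tuple[str, str], np.ndarray]    # pair -> (W,) distance on the window
    r: Dict[Tuple[str, str], float]         # pair -> separation degree
    window: int


def trajectory_separation(
    trials: Dict[str, np.ndarray],
    window: int = 100,
) -> TrajectorySummary:
    """Centers, deviations and the separation degree ``r_XY`` per chunk pair.

    For chunk X, the center is the trial mean at each time and
    ``sigma_X(t)`` the root summed per-component variance around it.  Chunks
    are aligned at the midpoint of their presentations, and on the
    ``+-window`` steps around it

        r_XY = sum_s (sigma_X(s) + sigma_Y(s)) / d_XY(s),

    where ``d_XY`` is the distance between the two centers.  Smaller r_XY
    means better-separated trajectories; coincident centers (d_XY = 0
    anywhere on the window) yield ``r_XY = inf``.
    """
    centers, sigma, n_trials = {}, {}, {}
    for name, arr in trials.items():
        if arr.shape[0] < 1:
            raise ValueError(f"no trials for chunk {name!r}")
        centers[name] = arr.mean(axis=0)
        var = ((arr - centers[name]) ** 2).mean(axis=0)   # (T, k)
        sigma[name] = np.sqrt(var.sum(axis=1))
        n_trials[name] = arr.shape[0]
    d_out: Dict[Tuple[str, str], np.ndarray] = {}
    r_out: Dict[Tuple[str, str], float] = {}
    names = sorted(trials)
    for X, Y in itertools.combinations(names, 2):
        cX, cY = centers[X], centers[Y]
        sX, sY = sigma[X], sigma[Y]
        iX = _midwindow(cX.shape[0], window)
        iY = _midwindow(cY.shape[0], window)
        dXY = np.linalg.norm(cX[iX] - cY[iY], axis=1)
        with np.errstate(divide="ignore"):
            terms = (sX[iX] + sY[iY]) / dXY
        r = float(np.inf) if np.any(dXY == 0) else float(terms.sum())
        d_out[(X, Y)] = d_out[(Y, X)] = dXY
        r_out[(X, Y)] = r_out[(Y, X)] = r
    return TrajectorySummary(centers, sigma, n_trials, d_out, r_out, window)


def _midwindow(T: int, window: int) -> np.ndarray:
    """Indices of the +-window steps around the presentation midpoint."""
    mid = T // 2
    w = min(window, mid, T - 1 - mid)
    return np.arange(mid - w, mid + w + 1)


# ---------------------------------------------------------------------------
# spectrum summaries
# ---------------------------------------------------------------------------

def effective_dimension(eigenvalues: np.ndarray) -> float:
    """Inverse participation ratio of the normalized eigenvalue spectrum.

    With eigenvalues normalized to unit sum, ``N_eff = 1 / sum_a lambda_a^2``;
    if n components share the variance equally (rest zero), N_eff = n.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    tot = lam.sum()
    if tot == 0:
        raise ValueError("all-zero spectrum has no effective dimension")
    lam = lam / tot
    return 1.0 / float((lam ** 2).sum())


def cumulative_contribution(eigenvalues: np.ndarray) -> np.ndarray:
    """Cumulative explained-variance curve of a descending spectrum."""
    lam = np.asarray(eigenvalues, dtype=float)
    tot = lam.sum()
    if tot == 0:
        raise ValueError("all-zero spectrum")
    return np.cumsum(lam) / tot
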