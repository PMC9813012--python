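"""Synthesis of paired two-modality stimulus streams.

One modality is a "text tone": a sequence of letters, each transiently
activating one of 26 input lines.  The other is an "image": a small RGB
raster decomposed into RGB channels and 10 horizontal sections, scanned left
to right with a mean-pooling window so that each image becomes a
30-dimensional time series whose duration matches the paired letter signal.

A *chunk* is a named, recurring pairing of a letter string and an image
(the demo uses "apple", "grape" and "banana").  Streams interleave chunk
epochs with random separators (random letter strings paired with Gaussian
noise images) and can be manipulated by pair replacement (probability ``m``)
or an inter-modal delay (``d`` ms), the two handles used to probe how much
the model relies on cross-modal co-occurrence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.transform import resize

from .params import ScheduleParams, StimulusParams

RANDOM_LABEL = "random"


@dataclass(frozen=True)
class ChunkSpec:
    """A named chunk: an ordered letter string paired with an image."""

    name: str
    letters: Tuple[str, ...]
    image_id: str

    def __post_init__(self) -> None:
        if len(self.letters) == 0:
            raise ValueError(f"chunk {self.name!r} has no letters")

    @classmethod
    def from_word(cls, word: str, image_id: Optional[str] = None) -> "ChunkSpec":
        return cls(name=word, letters=tuple(word), image_id=image_id or word)


def default_chunks() -> List[ChunkSpec]:
    """The three demonstration chunks."""
    return [ChunkSpec.from_word(w) for w in ("apple", "grape", "banana")]


# ---------------------------------------------------------------------------
# procedural images
# ---------------------------------------------------------------------------

def _disk(size: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy * size) ** 2 + (xx - cx * size) ** 2 <= (radius * size) ** 2


_BACKGROUND = 0.5  # mid-gray, matched to the noise-image mean so that chunk
                   # and separator images have comparable global luminance


def _draw_apple(size: int) -> np.ndarray:
    # distinct colored shapes on a mid-gray background; the background is
    # luminance-matched to the separator noise images so chunk identity,
    # not global brightness, is the discriminating feature
    img = np.full((size, size, 3), _BACKGROUND)
    body = _disk(size, 0.58, 0.5, 0.33)
    img[body] = (0.85, 0.08, 0.05)
    stem = np.zeros((size, size), dtype=bool)
    stem[int(0.12 * size):int(0.3 * size), int(0.47 * size):int(0.53 * size)] = True
    img[stem] = (0.15, 0.55, 0.1)
    return img


def _draw_grape(size: int) -> np.ndarray:
    img = np.full((size, size, 3), _BACKGROUND)
    centers = [(0.35, 0.35), (0.35, 0.65), (0.55, 0.25), (0.55, 0.5),
               (0.55, 0.75), (0.75, 0.38), (0.75, 0.62), (0.9, 0.5)]
    for cy, cx in centers:
        img[_disk(size, cy, cx, 0.13)] = (0.45, 0.1, 0.6)
    return img


def _draw_banana(size: int) -> np.ndarray:
    img = np.full((size, size, 3), _BACKGROUND)
    crescent = _disk(size, 0.45, 0.5, 0.38) & ~_disk(size, 0.3, 0.5, 0.36)
    img[crescent] = (0.9, 0.82, 0.1)
    return img


_IMAGES: Dict[str, Callable[[int], np.ndarray]] = {
    "apple": _draw_apple,
    "grape": _draw_grape,
    "banana": _draw_banana,
}


def synthesize_image(
    image_id: str,
    params: StimulusParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a procedural RGB raster in [0, 1] for ``image_id``.

    ``image_id == "random"`` yields a Gaussian noise raster (the separator
    image).  Per-presentation additive pixel noise is controlled by
    ``params.image_noise_sd``.
    """
    size = params.image_size
    if image_id == RANDOM_LABEL:
        if rng is None:
            raise ValueError("a Generator is required for noise images")
        img = rng.normal(params.noise_image_mean, params.noise_image_sd, (size, size, 3))
    elif image_id in _IMAGES:
        img = _IMAGES[image_id](size)
        if params.image_noise_sd > 0:
            if rng is None:
                raise ValueError("a Generator is required for image presentation noise")
            img = img + rng.normal(0.0, params.image_noise_sd, img.shape)
    else:
        raise KeyError(f"unknown image_id {image_id!r}")
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def encode_text(letters: Sequence[str], params: StimulusParams) -> np.ndarray:
    """Encode a letter sequence as a [time x alphabet] pulse raster.

    Each letter occupies one slot of ``params.slot_steps`` steps; the input
    line of that letter carries a rectangular pulse over the leading
    ``pulse_fraction`` of the slot and every other line stays at zero.
    """
    letters = list(letters)
    if len(letters) == 0:
        raise ValueError("letter sequence is empty")
    alphabet = params.alphabet
    slot = params.slot_steps
    pulse = max(1, int(round(slot * params.pulse_fraction)))
    out = np.zeros((len(letters) * slot, len(alphabet)))
    for i, ch in enumerate(letters):
        col = alphabet.find(ch)
        if col < 0:
            raise ValueError(f"letter {ch!r} is not in the configured alphabet")
        out[i * slot:i * slot + pulse, col] = params.pulse_amplitude
    return out


def encode_image(image: np.ndarray, n_steps: int, params: StimulusParams) -> np.ndarray:
    """Convert an RGB raster into a [n_steps x 3*sections] scanned series.

    The raster is rescaled to the canonical square size, split per RGB
    channel into ``sections`` horizontal bands, and a ``window_cols``-wide
    window is swept left to right in ``n_steps`` positions; each output value
    is the mean of one band of one channel inside the window.  Rows are
    ordered channel-major: R bands top-to-bottom, then G, then B.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB raster (H, W, 3), got shape {image.shape}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    size = params.image_size
    if image.shape[:2] != (size, size):
        image = resize(image, (size, size), anti_aliasing=True, preserve_range=True)
    k = params.sections
    band = size // k
    w = params.window_cols
    # per-band column means -> (sections, width, 3)
    col_means = image.reshape(k, band, size, 3).mean(axis=1)
    cs = np.concatenate(
        [np.zeros((k, 1, 3)), np.cumsum(col_means, axis=1)], axis=1
    )
    starts = np.round(np.linspace(0, size - w, n_steps)).astype(int)
    win = (cs[:, starts + w, :] - cs[:, starts, :]) / w          # (k, n_steps, 3)
    out = win.transpose(1, 2, 0).reshape(n_steps, 3 * k)         # channel-major
    return params.image_gain * out


def chunk_segment(
    chunk: ChunkSpec,
    params: StimulusParams,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Paired (text, image) signal of one chunk presentation."""
    m1 = encode_text(chunk.letters, params)
    img = synthesize_image(chunk.image_id, params, rng)
    m2 = encode_image(img, m1.shape[0], params)
    return m1, m2


def make_random_segment(
    params: StimulusParams,
    rng: np.random.Generator,
    length_range: Tuple[int, int] = (5, 8),
) -> Tuple[np.ndarray, np.ndarray, str]:
    """A random separator: random letters paired with a Gaussian noise image.

    The letter count is uniform on ``length_range`` (inclusive); both sides
    are drawn jointly and duration-matched.
    """
    lo, hi = length_range
    n = int(rng.integers(lo, hi + 1))
    letters = "".join(rng.choice(list(params.alphabet), size=n))
    m1 = encode_text(letters, params)
    img = synthesize_image(RANDOM_LABEL, params, rng)
    m2 = encode_image(img, m1.shape[0], params)
    return m1, m2, letters


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class StimulusTrack:
    """Two concurrent multichannel time series plus ground-truth annotations.

    ``annotations`` is a DataFrame with one row per epoch: ``label`` (a chunk
    name or ``"random"``), ``onset_ms``, ``offset_ms`` and ``co_occurring``
    (False where :func:`apply_missing` replaced one side of the pair).
    The chunk list and stimulus parameters travel with the track so that
    manipulations can re-synthesize replacement signals.
    """

    modality1: np.ndarray
    modality2: np.ndarray
    annotations: pd.DataFrame
    dt: float
    params: StimulusParams
    chunks: List[ChunkSpec]
    applied_delay_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.modality1.shape[0] != self.modality2.shape[0]:
            raise ValueError("modalities must have identical time length")

    @property
    def n_steps(self) -> int:
        return self.modality1.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt

    def epoch_slice(self, row) -> slice:
        a = int(round(row.onset_ms / self.dt))
        b = int(round(row.offset_ms / self.dt))
        return slice(a, b)

    def copy(self) -> "StimulusTrack":
        return StimulusTrack(
            self.modality1.copy(), self.modality2.copy(),
            self.annotations.copy(), self.dt, self.params,
            list(self.chunks), self.applied_delay_ms,
        )

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("modality1", data=self.modality1, compression="gzip")
            f.create_dataset("modality2", data=self.modality2, compression="gzip")
            ann = self.annotations
            f.create_dataset("annotations/label",
                             data=np.array(ann["label"], dtype="S32"))
            for col in ("onset_ms", "offset_ms"):
                f.create_dataset(f"annotations/{col}", data=ann[col].to_numpy(float))
            f.create_dataset("annotations/co_occurring",
                             data=ann["co_occurring"].to_numpy(bool))
            f.attrs["dt"] = self.dt
            f.attrs["applied_delay_ms"] = self.applied_delay_ms
            f.attrs["params"] = json.dumps(dataclasses.asdict(self.params))
            f.attrs["chunks"] = json.dumps(
                [{"name": c.name, "letters": list(c.letters), "image_id": c.image_id}
                 for c in self.chunks])

    @classmethod
    def load(cls, path) -> "StimulusTrack":
        import h5py

        with h5py.File(path, "r") as f:
            ann = pd.DataFrame({
                "label": [s.decode() for s in f["annotations/label"][:]],
                "onset_ms": f["annotations/onset_ms"][:],
                "offset_ms": f["annotations/offset_ms"][:],
                "co_occurring": f["annotations/co_occurring"][:].astype(bool),
            })
            params = StimulusParams(**json.loads(f.attrs["params"]))
            chunks = [ChunkSpec(c["name"], tuple(c["letters"]), c["image_id"])
                      for c in json.loads(f.attrs["chunks"])]
            return cls(f["modality1"][:], f["modality2"][:], ann,
                       float(f.attrs["dt"]), params, chunks,
                       float(f.attrs["applied_delay_ms"]))

    def annotations_csv(self, path) -> None:
        ann = self.annotations.copy()
        ann["applied_delay_ms"] = self.applied_delay_ms
        ann.to_csv(path, index=False)


def build_sequence(
    schedule: ScheduleParams,
    chunks: Sequence[ChunkSpec],
    params: StimulusParams,
    rng: Optional[np.random.Generator] = None,
) -> StimulusTrack:
    """Assemble ``schedule.C`` epochs into one two-modality track.

    With separators on, epochs alternate random separator / chunk (starting
    with a separator, so every chunk is flanked by random material); with
    separators off every epoch is a chunk.  Chunk identities are i.i.d.
    draws from ``schedule.chunk_probabilities``.
    """
    chunks = list(chunks)
    if len(chunks) == 0:
        raise ValueError("need at least one chunk")
    if rng is None:
        rng = np.random.default_rng(schedule.seed)
    probs = np.asarray(schedule.chunk_probabilities, dtype=float)
    if probs.shape[0] != len(chunks):
        raise ValueError("one probability per chunk required")

    seg1, seg2, rows = [], [], []
    t = 0
    for e in range(schedule.C):
        if schedule.use_separators and e % 2 == 0:
            m1, m2, _ = make_random_segment(params, rng)
            label = RANDOM_LABEL
        else:
            idx = int(rng.choice(len(chunks), p=probs))
            m1, m2 = chunk_segment(chunks[idx], params, rng)
            label = chunks[idx].name
        seg1.append(m1)
        seg2.append(m2)
        rows.append({
            "label": label,
            "onset_ms": t * params.dt,
            "offset_ms": (t + m1.shape[0]) * params.dt,
            "co_occurring": True,
        })
        t += m1.shape[0]
    ann = pd.DataFrame(rows)
    return StimulusTrack(np.concatenate(seg1), np.concatenate(seg2), ann,
                         params.dt, params, chunks)


def apply_missing(
    track: StimulusTrack,
    m: float,
    rng: np.random.Generator,
) -> StimulusTrack:
    """Break cross-modal co-occurrence with pair-replacement probability ``m``.

    Independently for each chunk epoch, with probability ``m`` one modality
    (chosen uniformly) is replaced by the corresponding signal of a different
    chunk or of a random separator (source uniform among those
    alternatives); the epoch is then flagged ``co_occurring = False``.
    ``m = 0`` returns an identical copy.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"m must be in [0, 1], got {m}")
    out = track.copy()
    if m == 0.0:
        return out
    params = track.params
    by_name = {c.name: c for c in track.chunks}
    for i, row in out.annotations.iterrows():
        if row.label == RANDOM_LABEL or rng.random() >= m:
            continue
        modality = 1 if rng.random() < 0.5 else 2
        alternatives = [n for n in by_name if n != row.label] + [RANDOM_LABEL]
        source = alternatives[int(rng.integers(len(alternatives)))]
        sl = out.epoch_slice(row)
        n = sl.stop - sl.start
        if modality == 1:
            if source == RANDOM_LABEL:
                letters = rng.choice(list(params.alphabet),
                                     size=-(-n // params.slot_steps))
                sig = encode_text(letters, params)
            else:
                sig = encode_text(by_name[source].letters, params)
            repl = np.zeros((n, out.modality1.shape[1]))
            repl[: min(n, sig.shape[0])] = sig[:n]
            out.modality1[sl] = repl
        else:
            img = synthesize_image(source, params, rng)
            out.modality2[sl] = encode_image(img, n, params)
        out.annotations.loc[i, "co_occurring"] = False
    return out


def apply_delay(
    track: StimulusTrack,
    d: float,
    delayed_modality: int = 2,
) -> StimulusTrack:
    """Shift one modality later by ``d`` ms relative to its partner.

    The whole designated channel is displaced (zeros fill the vacated head,
    the tail is truncated), so every chunk of that modality lags the partner
    by ``d``.  Annotations keep the undelayed boundaries; the applied delay
    is recorded on the track.  ``d = 0`` is the identity.
    """
    if d < 0:
        raise ValueError(f"delay d must be >= 0, got {d}")
    if delayed_modality not in (1, 2):
        raise ValueError("delayed_modality must be 1 or 2")
    out = track.copy()
    steps = int(round(d / track.dt))
    if steps == 0:
        return out
    target = out.modality1 if delayed_modality == 1 else out.modality2
    shifted = np.zeros_like(target)
    if steps < target.shape[0]:
        shifted[steps:] = target[:-steps]
    if delayed_modality == 1:
        out.modality1 = shifted
    else:
        out.modality2 = shifted
    out.applied_delay_ms = float(d)
    return out
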