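"""Training-set expansion: class oversampling and on-the-fly transforms.

Oversampling duplicates whole segments containing under-represented classes
until every class reaches a minimum number of labels per epoch (300 by
default); because segments are multi-label, duplication can raise other
classes' counts too.  On-the-fly augmentation then perturbs each 512x128
log-Mel matrix per epoch with four transforms: time-warp (stretch along time,
clipped/padded back to 512 frames), small circular shifts along time and
frequency, and a contrast adjustment of the spectrogram power.  Since the
matrices are log-power, a power-law contrast exponent acts as a scalar
multiplication of the log values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from botopam.annotations import TARGET_CLASSES


@dataclass
class AugmentPolicy:
    """Augmentation configuration; all magnitudes are deliberately small."""

    min_labels_per_epoch: int = 300
    max_freq_shift_bands: int = 4
    max_time_shift_frames: int = 16
    contrast_exponent_range: tuple[float, float] = (0.8, 1.2)
    time_warp_factor_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_freq_shift_bands < 0 or self.max_time_shift_frames < 0:
            raise ValueError("shift magnitudes must be >= 0")
        if min(self.time_warp_factor_range) <= 0:
            raise ValueError("time-warp factors must be > 0")
        for rng_pair in (self.contrast_exponent_range, self.time_warp_factor_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"range {rng_pair} is not well-ordered")


def class_counts(
    labelsets, classes: tuple[str, ...] = TARGET_CLASSES
) -> dict[str, int]:
    counts = {c: 0 for c in classes}
    for labels in labelsets:
        for c in labels:
            if c in counts:
                counts[c] += 1
    return counts


def oversample(
    labelsets,
    policy: AugmentPolicy,
    classes: tuple[str, ...] = TARGET_CLASSES,
) -> list[int]:
    """Return indices of an expanded training set meeting the label minimum.

    For every class below ``min_labels_per_epoch`` the list of segments
    containing it is duplicated wholesale ``ceil(min/count) - 1`` extra
    times, so a class with 120 labels and a minimum of 300 ends at 360.
    Expansion is deterministic: classes are processed in canonical order and
    duplicates appended cyclically.  A class present in the taxonomy but
    absent from the data cannot be oversampled and raises.
    """
    labelsets = [set(ls) for ls in labelsets]
    indices = list(range(len(labelsets)))
    counts = class_counts(labelsets, classes)
    for c in classes:
        if counts[c] == 0:
            raise ValueError(
                f"class {c!r} has no labels; cannot oversample from nothing"
            )
    for c in classes:
        current = sum(1 for i in indices if c in labelsets[i])
        if current >= policy.min_labels_per_epoch:
            continue
        members = [i for i in indices if c in labelsets[i]]
        extra_rounds = math.ceil(policy.min_labels_per_epoch / current) - 1
        for _ in range(extra_rounds):
            indices.extend(members)
    return indices


def _time_warp(values: np.ndarray, factor: float) -> np.ndarray:
    """Stretch along the time axis by ``factor``; clip or pad back to shape.

    Linear interpolation on the frame index; when the stretched version is
    shorter than the original, the tail is padded with zeros (the median
    level of an equalized matrix).
    """
    n_frames = values.shape[0]
    new_len = max(1, int(round(n_frames * factor)))
    if new_len == n_frames:
        return values
    src = np.linspace(0.0, n_frames - 1.0, new_len)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_frames - 1)
    frac = (src - lo)[:, None]
    stretched = values[lo] * (1.0 - frac) + values[hi] * frac
    if new_len >= n_frames:
        return stretched[:n_frames]
    out = np.zeros_like(values)
    out[:new_len] = stretched
    return out


def transform(
    values: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator
) -> np.ndarray:
    """Apply the four augmentation transforms to one 512x128 matrix.

    Order is fixed: time-warp, then circular time shift, then circular
    frequency shift, then contrast.  Parameters are drawn independently from
    the policy ranges using ``rng``, so per-epoch regeneration with advancing
    generator state yields slightly different matrices from the same base
    segment.  Degenerate policies (zero shifts, unit ranges) reproduce the
    input exactly.
    """
    out = np.asarray(values)
    wlo, whi = policy.time_warp_factor_range
    factor = rng.uniform(wlo, whi) if whi > wlo else wlo
    out = _time_warp(out, factor)
    if policy.max_time_shift_frames > 0:
        shift_t = int(
            rng.integers(-policy.max_time_shift_frames, policy.max_time_shift_frames + 1)
        )
        out = np.roll(out, shift_t, axis=0)
    if policy.max_freq_shift_bands > 0:
        shift_f = int(
            rng.integers(-policy.max_freq_shift_bands, policy.max_freq_shift_bands + 1)
        )
        out = np.roll(out, shift_f, axis=1)
    clo, chi = policy.contrast_exponent_range
    gamma = rng.uniform(clo, chi) if chi > clo else clo
    if gamma != 1.0:
        out = out * gamma
    return out
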