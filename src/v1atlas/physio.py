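"""Fictive-locomotion frequency and limb-kinematics analysis.

Ventral-root recordings (10 kHz) are low-pass filtered with a centered
moving mean of 10,000 points (1 s of data, truncated-edge convention) and
the locomotor frequency is the argmax of the periodogram power spectral
density, excluding the zero-frequency bin.

Joint angles are computed from nine tracked landmarks (forepaw, wrist,
elbow, armpit, hindpaw, ankle, knee, groin, anus) as the interior angle at
the joint vertex between its two arm vectors: ankle (hindpaw, knee), knee
(ankle, groin), wrist (forepaw, elbow), elbow (wrist, armpit).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["smooth_trace", "locomotor_frequency", "JOINT_ARMS",
           "joint_angle", "select_frames", "summarize_angles"]

JOINT_ARMS = {
    "wrist": ("forepaw", "elbow"),
    "elbow": ("wrist", "armpit"),
    "ankle": ("hindpaw", "knee"),
    "knee": ("ankle", "groin"),
}


def smooth_trace(trace, window: int = 10_000) -> np.ndarray:
    """Centered moving mean, valid support only (length n - window + 1)."""
    x = np.asarray(trace, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError(f"window {window} exceeds trace length {x.size}")
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[window:] - c[:-window]) / window


def locomotor_frequency(smoothed, fs: float) -> float:
    """Dominant frequency (Hz) of the smoothed trace by periodogram argmax.

    The trace is mean-subtracted; the zero-frequency bin is excluded; the
    plain (untapered) periodogram is used.  Spectral resolution is fs / n.
    An all-constant trace has no defined frequency and raises.
    """
    x = np.asarray(smoothed, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if np.ptp(x) == 0:
        raise ValueError("constant trace has no dominant frequency")
    freqs, psd = signal.periodogram(x - x.mean(), fs=fs, window="boxcar",
                                    detrend=False)
    # freqs[0] == 0; exclude it
    return float(freqs[1:][np.argmax(psd[1:])])


def _pivot(track: pd.DataFrame, field: str) -> pd.DataFrame:
    return track.pivot_table(index="frame", columns="landmark", values=field,
                             aggfunc="first")


def joint_angle(track: pd.DataFrame, joint: str) -> np.ndarray:
    """Interior angle (degrees, [0, 180]) at the joint vertex per frame.

    ``track`` is long-format with columns frame, landmark, x, y.  Frames
    where the vertex coincides with an arm landmark have no defined angle
    and are returned as NaN.
    """
    if joint not in JOINT_ARMS:
        raise ValueError(f"unknown joint {joint!r}; one of {sorted(JOINT_ARMS)}")
    arm_a, arm_b = JOINT_ARMS[joint]
    xs = _pivot(track, "x")
    ys = _pivot(track, "y")
    for lm in (joint, arm_a, arm_b):
        if lm not in xs.columns:
            raise ValueError(f"landmark {lm!r} missing from track")
    v = np.stack([xs[joint], ys[joint]], axis=1)
    u1 = np.stack([xs[arm_a], ys[arm_a]], axis=1) - v
    u2 = np.stack([xs[arm_b], ys[arm_b]], axis=1) - v
    n1 = np.linalg.norm(u1, axis=1)
    n2 = np.linalg.norm(u2, axis=1)
    bad = (n1 == 0) | (n2 == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (u1 * u2).sum(axis=1) / (n1 * n2)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[bad] = np.nan
    return ang


def select_frames(track: pd.DataFrame, min_confidence: float = 0.9,
                  exclusion_intervals=()) -> np.ndarray:
    """Frame keep-mask: all nine landmarks confident and not excluded.

    ``exclusion_intervals`` is a sequence of (start, end) inclusive frame
    ranges standing in for manual annotation of turning/flipping movements.
    """
    conf = _pivot(track, "confidence")
    keep = (conf >= min_confidence).all(axis=1).to_numpy()
    frames = conf.index.to_numpy()
    for start, end in exclusion_intervals:
        keep &= ~((frames >= start) & (frames <= end))
    return keep


def summarize_angles(angles, animal_ids) -> tuple:
    """Per-animal mean angle, then group mean +/- SEM across animals.

    Frames with NaN angles are ignored; an animal with no valid frame is
    excluded with a warning.  Returns (per_animal Series, mean, sem).
    """
    angles = np.asarray(angles, dtype=float)
    animal_ids = np.asarray(animal_ids)
    means = {}
    for a in pd.unique(animal_ids):
        vals = angles[animal_ids == a]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"animal {a!r} has no valid frames; excluded")
            continue
        means[a] = vals.mean()
    per_animal = pd.Series(means, name="mean_angle")
    group_mean = float(per_animal.mean())
    n = len(per_animal)
    sem = float(per_animal.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return per_animal, group_mean, sem
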