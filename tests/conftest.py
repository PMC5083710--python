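"""Shared fixtures and independent oracles.

The session-scoped fixtures build one small labeled synthetic set and a
trained model reused across classifier and well-analytics tests. The
oracle functions are deliberately naive, literal implementations kept
independent of the package code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from calscreen import (
    TrainingSet,
    features_frame,
    make_training_set,
    train_tree,
)

SMALL_COMPOSITION = (40, 60, 100)


@pytest.fixture(scope="session")
def small_training():
    traces, labels = make_training_set(SMALL_COMPOSITION, seed=7)
    return traces, labels


@pytest.fixture(scope="session")
def small_features(small_training):
    traces, labels = small_training
    return features_frame(traces), labels


@pytest.fixture(scope="session")
def small_ts(small_features) -> TrainingSet:
    feats, labels = small_features
    return TrainingSet.from_frame(feats, labels)


@pytest.fixture(scope="session")
def small_model(small_ts):
    return train_tree(small_ts, seed=7)


# ---------------------------------------------------------------------------
# Oracles


def naive_peak_indices(y, width: int, threshold: float) -> list[int]:
    """Literal enumeration of the peak contract: strict centered-window
    maximum (earliest index on ties) with prominence — height above the
    higher flanking minimum inside the window — at least the threshold.
    """
    y = [float(v) for v in y]
    w = max(3, width if width % 2 == 1 else width + 1)
    half = w // 2
    n = len(y)
    peaks = []
    for i in range(n):
        if i - half < 0 or i + half > n - 1:
            continue  # no centered window at the boundary
        window = y[i - half : i + half + 1]
        m = max(window)
        if y[i] != m:
            continue
        if window.index(m) != half:  # an equal maximum occurs earlier
            continue
        left_min = min(y[i - half : i])
        right_min = min(y[i + 1 : i + half + 1])
        prominence = y[i] - max(left_min, right_min)
        if prominence >= threshold:
            peaks.append(i)
    return peaks


def brute_force_power(y) -> np.ndarray:
    """O(n^2) one-sided DFT power, same scaling as the implementation:
    |X_k|^2 / n^2 with interior-bin doubling, on the mean-subtracted
    signal."""
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    n = y.size
    k = np.arange(n // 2 + 1)
    phases = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    X = phases @ y
    p = np.abs(X) ** 2 / n**2
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    return p


def chord_elongation_oracle(rows, cols, angle_step_deg: float = 1.0) -> float:
    """Independent elongation measure: chords collected by perpendicular
    offset bands around the centroid rather than ray marching. Returns
    max centroid chord over the discretized orientations divided by the
    circle-calibrated mean perpendicular chord."""
    rows = np.asarray(rows, float)
    cols = np.asarray(cols, float)
    cr, cc = rows.mean(), cols.mean()
    dr, dc = rows - cr, cols - cc
    best_len, best_theta = -1.0, 0.0
    for deg in np.arange(0.0, 180.0, angle_step_deg):
        th = np.deg2rad(deg)
        along = dr * np.cos(th) + dc * np.sin(th)
        perp = -dr * np.sin(th) + dc * np.cos(th)
        band = np.abs(perp) <= 0.5
        if not band.any():
            continue
        length = along[band].max() - along[band].min() + 1.0
        if length > best_len:
            best_len, best_theta = length, th
    along = dr * np.cos(best_theta) + dc * np.sin(best_theta)
    perp = -dr * np.sin(best_theta) + dc * np.cos(best_theta)
    bins = np.rint(along).astype(int)
    extents = [
        perp[bins == b].max() - perp[bins == b].min() + 1.0 for b in np.unique(bins)
    ]
    mean_perp = float(np.mean(extents)) / (np.pi / 4.0)
    return best_len / mean_perp
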