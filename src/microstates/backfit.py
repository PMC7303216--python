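"""Backfitting: label every EEG sample with a microstate class.

Competitive fitting compares each instantaneous scalp map with every group
template by spatial correlation (polarity ignored) and assigns the winner.
Because low-GFP periods are noisy, the raw label sequence is then smoothed
with a windowed Besag-style penalty that rewards agreement with neighboring
labels, and optionally rid of one-sample segments.  Temporal statistics per
class — mean segment duration (ms), time coverage (%), occurrence (1/s) —
are the quantities carried into the group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import TemplateSet, _corr_matrix
from .preprocess import EEGRecording

_ZERO_TOL = 1e-12

PARAMETERS = ("mean_duration", "coverage", "occurrence")


@dataclass
class Segmentation:
    """A per-sample microstate label sequence."""

    labels: np.ndarray
    sfreq: float
    k: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class SmoothingConfig:
    """Besag-style temporal smoothing parameters.

    ``window_half_size`` (b) and ``strength`` (lambda) default to the
    values used throughout this pipeline at 128 Hz: b = 5, lambda = 10,
    with rejection of one-sample segments enabled.
    """

    window_half_size: int = 5
    strength: float = 10.0
    reject_single_frames: bool = True
    max_iter: int = 1000

    def __post_init__(self):
        if self.window_half_size < 0:
            raise ValueError("window_half_size must be >= 0")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


def segments_of(labels: np.ndarray) -> list:
    """Maximal constant-label runs as (label, start, length) tuples."""
    labels = np.asarray(labels)
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [labels.size]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _abs_corr_samples(rec: EEGRecording, templates: TemplateSet):
    """(|corr| matrix (T, k), boolean mask of zero-variance samples)."""
    x = rec.data.T
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms < _ZERO_TOL * max(1.0, norms.max(initial=0.0))
    corr = np.abs(_corr_matrix(x, templates.maps))
    return corr, degenerate


def competitive_fit(rec: EEGRecording, templates: TemplateSet) -> Segmentation:
    """Label each sample by the template with the largest |spatial correlation|.

    Polarity is ignored; ties go to the lowest class index.  Zero-variance
    samples inherit the preceding sample's label (the first sample falls
    back to class 0) and are counted in ``Segmentation.diagnostics``.
    """
    if rec.reference != "average":
        raise ValueError("competitive fitting requires average-referenced data")
    if rec.n_channels != templates.n_electrodes:
        raise ValueError("electrode count mismatch between recording and templates")
    corr, degenerate = _abs_corr_samples(rec, templates)
    labels = np.argmax(corr, axis=1)
    if degenerate.any():
        for t in np.flatnonzero(degenerate):
            labels[t] = labels[t - 1] if t > 0 else 0
    return Segmentation(
        labels=labels,
        sfreq=rec.sfreq,
        k=templates.k,
        diagnostics={"n_zero_variance": int(degenerate.sum())},
    )


def _reject_single_frames(labels: np.ndarray, abs_corr: np.ndarray) -> np.ndarray:
    """Merge every 1-sample segment into its better-fitting temporal neighbor.

    The neighbor whose template correlates more strongly (in absolute
    value) with the map at the offending sample wins; ties and boundary
    cases go to the earlier neighbor.  Repeats until no 1-sample segment
    remains.  Operates on a run-length list, so the cost is linear in the
    number of runs.
    """
    runs = segments_of(labels)
    i = 0
    while i < len(runs):
        lab, start, length = runs[i]
        if length != 1 or len(runs) == 1:
            i += 1
            continue
        prev_lab = runs[i - 1][0] if i > 0 else None
        next_lab = runs[i + 1][0] if i < len(runs) - 1 else None
        if prev_lab is None:
            new_lab = next_lab
        elif next_lab is None:
            new_lab = prev_lab
        else:
            new_lab = next_lab if abs_corr[start, next_lab] > abs_corr[start, prev_lab] else prev_lab
        runs[i] = (new_lab, start, 1)
        # coalesce with equal-label neighbors
        j = i
        if j > 0 and runs[j - 1][0] == new_lab:
            pl, ps, pn = runs[j - 1]
            runs[j - 1 : j + 1] = [(pl, ps, pn + 1)]
            j -= 1
        if j < len(runs) - 1 and runs[j + 1][0] == new_lab:
            cl, cs, cn = runs[j]
            nl, ns, nn = runs[j + 1]
            runs[j : j + 2] = [(cl, cs, cn + nn)]
        i = max(j - 1, 0)  # a merge can shorten the previous run's neighbor context
    out = np.empty_like(labels)
    for lab, start, length in runs:
        out[start : start + length] = lab
    return out


def smooth_labels(
    seg: Segmentation,
    rec: EEGRecording,
    templates: TemplateSet,
    cfg: SmoothingConfig | None = None,
) -> Segmentation:
    """Besag-penalty temporal smoothing of a label sequence.

    Iteratively relabels each sample t by maximizing

        corr(t, class)^2 + strength * N_b(t, class)

    where N_b counts same-class labels among the 2b surrounding samples
    (windows truncated at the boundaries) under the current labeling.
    Sweeps are synchronous (all labels updated from the previous iterate)
    and repeat until a fixed point or ``max_iter``.  Afterwards, if
    configured, one-sample segments are merged into their better-fitting
    neighbor until none remain.
    """
    cfg = cfg or SmoothingConfig()
    if seg.n_samples != rec.n_samples:
        raise ValueError("segmentation and recording lengths differ")
    abs_corr, _ = _abs_corr_samples(rec, templates)
    fit = abs_corr**2
    labels = seg.labels.copy()
    k = templates.k
    b = cfg.window_half_size
    kernel = np.ones(2 * b + 1)
    kernel[b] = 0.0  # neighbors only, not the sample itself
    converged = True
    if cfg.strength > 0 and b > 0:
        converged = False
        previous = None
        for _ in range(cfg.max_iter):
            onehot = np.zeros((k, labels.size))
            onehot[labels, np.arange(labels.size)] = 1.0
            counts = np.stack(
                [np.convolve(onehot[c], kernel, mode="same") for c in range(k)]
            )
            value = fit + cfg.strength * counts.T
            new = np.argmax(value, axis=1)
            if np.array_equal(new, labels):
                converged = True
                break
            if previous is not None and np.array_equal(new, previous):
                break  # synchronous sweeps entered a 2-cycle; keep the last iterate
            previous = labels
            labels = new
        if not converged:
            warnings.warn("label smoothing did not reach a fixed point")
    if cfg.reject_single_frames:
        labels = _reject_single_frames(labels, abs_corr)
    diag = dict(seg.diagnostics)
    diag["smoothing_converged"] = converged
    return Segmentation(labels=labels, sfreq=seg.sfreq, k=seg.k, diagnostics=diag)


def microstate_parameters(seg: Segmentation) -> pd.DataFrame:
    """Per-class temporal parameters of a segmentation.

    Segments are maximal constant-label runs, including the (possibly
    truncated) first and last runs.  Returns a DataFrame indexed by class
    with columns ``mean_duration`` (ms), ``coverage`` (%), ``occurrence``
    (segments per second) and ``n_segments``; classes absent from the
    sequence get zeros.  ``total_time`` (s) is stored in ``attrs``.

    The definitions are linked: occurrence x mean_duration / 1000 equals
    coverage / 100 for every class, identically.
    """
    runs = segments_of(seg.labels)
    total_samples = seg.n_samples
    total_s = total_samples / seg.sfreq
    out = pd.DataFrame(
        0.0,
        index=pd.RangeIndex(seg.k, name="class"),
        columns=["mean_duration", "coverage", "occurrence", "n_segments"],
    )
    for c in range(seg.k):
        lengths = np.array([n for lab, _, n in runs if lab == c], dtype=float)
        if lengths.size == 0:
            continue
        out.loc[c, "mean_duration"] = lengths.mean() * 1000.0 / seg.sfreq
        out.loc[c, "coverage"] = lengths.sum() / total_samples * 100.0
        out.loc[c, "occurrence"] = lengths.size / total_s
        out.loc[c, "n_segments"] = float(lengths.size)
    out.attrs["total_time"] = total_s
    return out
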