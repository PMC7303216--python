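"""Signal conditioning and global field power machinery.

The microstate pipeline operates on average-referenced multichannel EEG.
Everything downstream (clustering, backfitting) is anchored on the global
field power (GFP), the per-timepoint population standard deviation of the
potential across electrodes: a reference-offset-independent measure of
momentary field strength.  Topographies at local GFP maxima have the best
signal-to-noise ratio and are the ones submitted to clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass
class EEGRecording:
    """A multichannel EEG epoch.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels, one per row of ``data``.
    reference : {"raw", "average"}
        Referencing state.  Average-referenced data sum to zero across
        channels at every sample.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list = field(default_factory=list)
    reference: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.ch_names:
            self.ch_names = [f"E{i + 1}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("one channel label per data row required")
        if self.reference not in ("raw", "average"):
            raise ValueError("reference must be 'raw' or 'average'")
        if self.reference == "average":
            scale = np.abs(self.data).max(initial=1.0)
            if np.abs(self.data.sum(axis=0)).max(initial=0.0) > 1e-9 * max(scale, 1.0):
                raise ValueError("reference='average' but samples do not sum to 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class GFPSeries:
    """Global field power per sample, with its sampling rate."""

    values: np.ndarray
    sfreq: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("GFP series must be 1-D")
        if (self.values < 0).any():
            raise ValueError("GFP values must be nonnegative")


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average (idempotent)."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="average")


def preprocess_recording(
    rec: EEGRecording,
    band: tuple = (1.0, 40.0),
    target_rate: float = 128.0,
) -> EEGRecording:
    """Band-pass, downsample and average-reference a recording.

    The resampler applies its own anti-alias low-pass; the band-pass is a
    zero-phase FIR (applied forward and backward) at the target rate, so no
    group delay distorts the topographies.  Output length is
    ``floor(n_samples * target_rate / sfreq)``.

    Parameters
    ----------
    band : (low, high)
        Pass band in Hz; requires ``0 < low < high < target_rate / 2``.
    target_rate : float
        Output sampling rate in Hz; must not exceed the input rate.
    """
    low, high = band
    if not (0 < low < high):
        raise ValueError("band must satisfy 0 < low < high")
    if high >= target_rate / 2:
        raise ValueError("band upper edge must be below the target Nyquist")
    if target_rate > rec.sfreq:
        raise ValueError("target_rate must not exceed the input rate")

    n_out = int(np.floor(rec.n_samples * target_rate / rec.sfreq))
    data = rec.data
    if target_rate != rec.sfreq:
        ratio = Fraction(target_rate / rec.sfreq).limit_denominator(10000)
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
        data = data[:, :n_out]

    # zero-phase FIR band-pass; transition width ~= the lower edge, which
    # keeps the filter short while still killing DC
    trans = min(low, 2.0)
    numtaps = int(np.ceil(3.3 * target_rate / trans)) | 1
    numtaps = min(numtaps, max(3, 2 * (data.shape[1] // 3) - 1) | 1)
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=target_rate)
    padlen = min(3 * numtaps, data.shape[1] - 1)
    data = signal.filtfilt(taps, 1.0, data, axis=1, padlen=padlen)

    out = replace(rec, data=data, sfreq=float(target_rate), reference="raw")
    return average_reference(out)


def global_field_power(rec: EEGRecording) -> GFPSeries:
    """GFP: population (1/N) standard deviation across electrodes per sample.

    Requires average-referenced input; for such data the GFP equals the
    Euclidean norm of each column divided by sqrt(n_channels).
    """
    if rec.reference != "average":
        raise ValueError("GFP requires an average-referenced recording")
    values = rec.data.std(axis=0, ddof=0)
    return GFPSeries(values=values, sfreq=rec.sfreq)


def gfp_peaks(gfp: GFPSeries) -> np.ndarray:
    """Indices of strict local maxima of the GFP series.

    A peak is a sample strictly greater than the nearest differing values on
    both sides; a plateau of equal values flanked by smaller values yields
    its first index.  The endpoints are never peaks.
    """
    v = gfp.values
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 samples to find peaks")
    peaks = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            # scan past a potential plateau starting at i
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j + 1 < n and v[j + 1] < v[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(peaks, dtype=int)
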