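"""Surrogate resting-state EEG with planted microstate dynamics.

The generator emulates the data regime the pipeline is designed for:
64-channel recordings at 128 Hz, a few minutes long, in which four
quasi-stable scalp topographies alternate with mean dwell times of
60-120 ms.  Class dynamics follow a semi-Markov chain: the sequence of
classes is Markovian (zero self-transition), and each visit's dwell time is
drawn from a geometric law (minimum one sample) whose mean matches the
class's requested mean duration.  The instantaneous signal is the active
class's template scaled by a GFP amplitude profile — sinusoidal by default,
so that GFP peaks exist for the clustering stage — plus spatially white
Gaussian sensor noise projected onto the average-reference subspace and
scaled to a requested GFP signal-to-noise ratio.

This module also ships small tabular fixtures (demographic contingency
tables and an uncorrected p-value grid) used by the statistics layer's
worked examples and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import TemplateSet, _corr_matrix, map_gfp, normalize_maps
from .preprocess import EEGRecording

#: default per-class mean dwell times (ms), spanning the quasi-stable range
DEFAULT_MEAN_DURATIONS = (60.0, 80.0, 100.0, 120.0)


def uniform_offdiagonal_transitions(k: int) -> np.ndarray:
    """k x k transition matrix: uniform over the other classes, zero diagonal."""
    if k < 2:
        raise ValueError("need at least 2 classes for switching dynamics")
    t = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(t, 0.0)
    return t


def make_templates(
    n_electrodes: int,
    k: int = 4,
    min_separation: float = 0.5,
    seed: int | None = None,
    max_attempts: int = 2000,
) -> TemplateSet:
    """Draw k well-separated random topographies.

    Maps are average-referenced, unit-GFP, and every pair satisfies
    |spatial correlation| <= ``min_separation``.  Rejection sampling adds
    maps one at a time; raises after ``max_attempts`` failed draws.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_electrodes < max(k, 2):
        raise ValueError("need n_electrodes >= max(k, 2)")
    if not (0 <= min_separation < 1):
        raise ValueError("min_separation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    accepted: list = []
    attempts = 0
    while len(accepted) < k:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {k} maps with pairwise |corr| <= {min_separation} "
                f"in {max_attempts} attempts"
            )
        attempts += 1
        cand = normalize_maps(rng.standard_normal(n_electrodes)[None, :])[0]
        if accepted:
            corr = _corr_matrix(cand[None, :], np.vstack(accepted))
            if np.abs(corr).max() > min_separation:
                continue
        accepted.append(cand)
    return TemplateSet(maps=np.vstack(accepted), labels=list(range(k)))


@dataclass
class SimulationSpec:
    """Everything that defines one surrogate recording.

    ``snr`` is the ratio of the time-averaged GFP of the noiseless signal
    to the time-averaged GFP of the noise (the whole pipeline is GFP-based,
    so the SNR is too); ``np.inf`` disables noise.  ``amplitude_profile``
    is ``("constant",)`` or ``("sinusoidal", period_in_samples)``; the
    default is sinusoidal with a period of ~100 ms so the GFP has peaks.
    """

    n_electrodes: int = 64
    sampling_rate: float = 128.0
    duration: float = 300.0
    templates: TemplateSet | None = None
    mean_durations: tuple = DEFAULT_MEAN_DURATIONS
    transition_matrix: np.ndarray | None = None
    snr: float = 2.0
    amplitude_profile: tuple = ()
    amplitude_depth: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        k = len(self.mean_durations)
        if self.templates is None:
            self.templates = make_templates(self.n_electrodes, k, seed=self.seed)
        if self.templates.k != k:
            raise ValueError("one mean duration per template required")
        if self.transition_matrix is None:
            self.transition_matrix = uniform_offdiagonal_transitions(k)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        t = self.transition_matrix
        if t.shape != (k, k):
            raise ValueError("transition matrix must be k x k")
        if np.abs(np.diag(t)).max() > 0:
            raise ValueError("transition matrix diagonal must be zero")
        if np.abs(t.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("transition matrix rows must sum to 1")
        if (t < 0).any():
            raise ValueError("transition probabilities must be nonnegative")
        if min(self.mean_durations) <= 0:
            raise ValueError("mean durations must be strictly positive")
        if min(self.mean_durations) < 1000.0 / self.sampling_rate:
            raise ValueError("mean durations must be at least one sample period")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not self.amplitude_profile:
            period = max(2, int(round(0.1 * self.sampling_rate)))
            self.amplitude_profile = ("sinusoidal", period)
        if self.amplitude_profile[0] not in ("constant", "sinusoidal"):
            raise ValueError("amplitude profile must be constant or sinusoidal")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def k(self) -> int:
        return len(self.mean_durations)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """Planted label sequence plus its run-length segment table."""

    labels: np.ndarray
    segment_table: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.segment_table is None:
            from .backfit import segments_of

            runs = segments_of(self.labels)
            self.segment_table = pd.DataFrame(
                runs, columns=["class", "start_sample", "length"]
            )

    def reconstruct_labels(self) -> np.ndarray:
        out = np.empty(int(self.segment_table["length"].sum()), dtype=int)
        for _, row in self.segment_table.iterrows():
            s = int(row["start_sample"])
            out[s : s + int(row["length"])] = int(row["class"])
        return out


def stationary_coverage(transition_matrix: np.ndarray, mean_durations) -> np.ndarray:
    """Long-run fractional coverage of each class of the semi-Markov chain.

    The embedded class chain has stationary distribution nu (left
    eigenvector of the transition matrix); time-share is nu weighted by the
    mean dwell times: pi_j = nu_j m_j / sum_i nu_i m_i.
    """
    t = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(t.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    nu = np.real(vecs[:, idx])
    nu = nu / nu.sum()
    m = np.asarray(mean_durations, dtype=float)
    pi = nu * m
    return pi / pi.sum()


def _amplitude(spec: SimulationSpec, n: int) -> np.ndarray:
    if spec.amplitude_profile[0] == "constant":
        return np.ones(n)
    period = float(spec.amplitude_profile[1])
    t = np.arange(n)
    return 1.0 + spec.amplitude_depth * np.sin(2 * np.pi * t / period)


def simulate_microstate_eeg(spec: SimulationSpec) -> tuple:
    """Generate one surrogate recording and its ground truth.

    Returns ``(EEGRecording, GroundTruth)``.  Identical specs (including
    the seed) yield bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    n = spec.n_samples
    mean_samples = np.asarray(spec.mean_durations) * spec.sampling_rate / 1000.0

    # semi-Markov label sequence: embedded Markov class chain + geometric
    # dwell times (support {1, 2, ...}, mean = planted mean in samples)
    nu = stationary_coverage(spec.transition_matrix, np.ones(k))
    state = int(rng.choice(k, p=nu))
    labels = np.empty(n, dtype=int)
    pos = 0
    while pos < n:
        length = int(rng.geometric(1.0 / mean_samples[state]))
        end = min(pos + length, n)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(k, p=spec.transition_matrix[state]))
    truth = GroundTruth(labels=labels)

    amp = _amplitude(spec, n)
    signal = spec.templates.maps[labels].T * amp[None, :]

    if np.isfinite(spec.snr):
        noise = rng.standard_normal((spec.n_electrodes, n))
        noise -= noise.mean(axis=0, keepdims=True)  # average-reference subspace
        gfp_signal = signal.std(axis=0, ddof=0).mean()
        gfp_noise = noise.std(axis=0, ddof=0).mean()
        data = signal + noise * (gfp_signal / (spec.snr * gfp_noise))
    else:
        data = signal

    rec = EEGRecording(
        data=data,
        sfreq=spec.sampling_rate,
        ch_names=[f"E{i + 1}" for i in range(spec.n_electrodes)],
        reference="average",
    )
    return rec, truth


# --------------------------------------------------------------------------
# Tabular fixtures: demographic counts and an uncorrected p-value grid from
# a published three-group schizophrenia/siblings/controls resting-EEG study,
# used as worked-example inputs for the statistics layer.

GENDER_FM = {
    "patients": (11, 90),
    "siblings": (21, 22),
    "controls": (39, 36),
    "patients_32": (4, 28),
    "siblings_32": (14, 18),
    "fep": (12, 10),
    "patients_22": (8, 14),
}

HANDEDNESS_LR = {
    "patients": (6, 95),
    "siblings": (2, 41),
    "controls": (4, 71),
    "patients_32": (3, 29),
    "siblings_32": (2, 30),
    "fep": (1, 21),
    "patients_22": (1, 21),
}

#: uncorrected post hoc p-values, patients vs controls, one per
#: microstate parameter x class cell
UNCORRECTED_P = pd.DataFrame(
    {
        "A": [0.054, 0.449, 0.882],
        "B": [0.003, 0.074, 0.112],
        "C": [1.315e-4, 1.452e-7, 1.170e-4],
        "D": [3.010e-6, 3.445e-6, 1.620e-4],
    },
    index=pd.Index(["mean_duration", "coverage", "occurrence"], name="parameter"),
)


def _two_group_table(counts: dict, g1: str, g2: str, columns) -> pd.DataFrame:
    return pd.DataFrame(
        [counts[g1], counts[g2]], index=pd.Index([g1, g2], name="group"), columns=columns
    )


def gender_table(g1: str, g2: str) -> pd.DataFrame:
    """2x2 gender (F/M) contingency table for two named groups."""
    return _two_group_table(GENDER_FM, g1, g2, ["F", "M"])


def handedness_table(g1: str, g2: str) -> pd.DataFrame:
    """2x2 handedness (L/R) contingency table for two named groups."""
    return _two_group_table(HANDEDNESS_LR, g1, g2, ["L", "R"])


def demographics_fixtures() -> dict:
    """All packaged tabular fixtures in one dictionary."""
    return {
        "gender_fm": GENDER_FM.copy(),
        "handedness_lr": HANDEDNESS_LR.copy(),
        "uncorrected_p": UNCORRECTED_P.copy(),
    }
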