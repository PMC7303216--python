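"""Polarity-invariant topographic clustering.

Microstate analysis treats a scalp map and its negation as the same brain
state (the generators are the same; only the instantaneous polarity
differs).  The modified k-means implemented here is therefore invariant to
the sign of every input map: assignment uses squared spatial correlation,
and the template update extracts the dominant spatial pattern (first
principal axis) of the maps assigned to a cluster, which is sign-blind by
construction.

Cluster quality is scored by the global explained variance (GEV)

    GEV = sum_t (GFP_t * corr_t)^2 / sum_t GFP_t^2

where corr_t is the spatial correlation between map t and its assigned
template: the fraction of GFP-weighted topographic variance the template
set accounts for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

_ZERO_TOL = 1e-12


@dataclass
class TemplateSet:
    """A set of k average-referenced topographic maps with class labels.

    ``maps`` has shape (k, n_electrodes); maps are stored at unit GFP.
    ``level`` records whether the set came from a single subject or from
    the group-level (second-stage) clustering.
    """

    maps: np.ndarray
    labels: list
    level: str = "individual"

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per map required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.level not in ("individual", "group"):
            raise ValueError("level must be 'individual' or 'group'")
        scale = np.abs(self.maps).max(initial=1.0)
        if np.abs(self.maps.sum(axis=1)).max(initial=0.0) > 1e-8 * max(scale, 1.0):
            raise ValueError("template maps must be average-referenced")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.maps.shape[1]


@dataclass
class ClusterFit:
    """Result of a modified k-means run."""

    templates: TemplateSet
    assignments: np.ndarray
    polarities: np.ndarray
    gev: float
    gev_trace: list = field(default_factory=list)
    converged: bool = True


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two maps across electrodes.

    Sign-aware: polarity handling (taking absolute values) is the caller's
    concern.  Rejects maps with zero spatial variance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("maps must have equal electrode counts")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _ZERO_TOL or nb < _ZERO_TOL:
        raise ValueError("zero-variance map")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Row-wise spatial correlations: (n_maps, k).  Zero-variance rows -> 0."""
    x = maps - maps.mean(axis=1, keepdims=True)
    t = templates - templates.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(x, axis=1)
    nt = np.linalg.norm(t, axis=1)
    nx = np.where(nx < _ZERO_TOL, np.inf, nx)
    nt = np.where(nt < _ZERO_TOL, np.inf, nt)
    return np.clip((x / nx[:, None]) @ (t / nt[:, None]).T, -1.0, 1.0)


def map_gfp(maps: np.ndarray) -> np.ndarray:
    """Per-map GFP (population SD across electrodes)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    return maps.std(axis=1, ddof=0)


def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference each map and rescale it to unit GFP."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    maps = maps - maps.mean(axis=1, keepdims=True)
    g = map_gfp(maps)
    if (g < _ZERO_TOL).any():
        raise ValueError("cannot normalize a zero-variance map")
    return maps / g[:, None]


def global_explained_variance(
    maps: np.ndarray,
    templates: TemplateSet | np.ndarray,
    assignments: np.ndarray,
    gfp: np.ndarray | None = None,
) -> float:
    """GEV of an assignment of maps to templates.

    ``gfp`` supplies per-map weights; by default the maps' own GFP is used
    (pass the original GFP when the maps were normalized beforehand).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    tmaps = templates.maps if isinstance(templates, TemplateSet) else np.atleast_2d(templates)
    assignments = np.asarray(assignments, dtype=int)
    if assignments.size != maps.shape[0]:
        raise ValueError("one assignment per map required")
    if gfp is None:
        gfp = map_gfp(maps)
    gfp = np.asarray(gfp, dtype=float)
    corr = _corr_matrix(maps, tmaps)[np.arange(maps.shape[0]), assignments]
    denom = float(np.sum(gfp**2))
    if denom == 0.0:
        return 0.0
    return float(np.sum((gfp * corr) ** 2) / denom)


def _dominant_pattern(maps: np.ndarray) -> np.ndarray:
    """First principal axis of a set of maps (unit GFP, average-referenced).

    Eigenvector of X^T X with the largest eigenvalue; sign-blind, hence
    polarity-invariant.
    """
    x = maps - maps.mean(axis=1, keepdims=True)
    s = x.T @ x
    vals, vecs = np.linalg.eigh(s)
    v = vecs[:, -1]
    v = v - v.mean()
    g = v.std(ddof=0)
    if g < _ZERO_TOL:
        raise ValueError("degenerate cluster: zero-variance dominant pattern")
    return v / g


def modified_kmeans(
    maps: np.ndarray,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
    gfp: np.ndarray | None = None,
    level: str = "individual",
) -> ClusterFit:
    """Polarity-invariant modified k-means on topographic maps.

    Each restart seeds templates from k randomly chosen input maps, then
    alternates (1) assigning every map to the template with the largest
    squared spatial correlation (ties to the lowest class index) and (2)
    recomputing each template as the dominant spatial pattern of its
    assigned maps.  Both steps increase the GEV, which is tracked per
    iteration; the best restart by final GEV is returned.

    Empty clusters are repaired by re-seeding the empty template from the
    currently worst-represented map.  A restart that fails to converge
    within ``max_iter`` contributes its best iterate and the returned fit
    carries ``converged=False`` if the winning restart did not converge.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n = maps.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} maps, got {n}")
    if gfp is None:
        gfp = map_gfp(maps)
    gfp = np.asarray(gfp, dtype=float)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        idx = rng.choice(n, size=k, replace=False)
        templates = normalize_maps(maps[idx])
        prev_gev = -np.inf
        trace = []
        converged = False
        assign = np.zeros(n, dtype=int)
        for _it in range(max_iter):
            corr = _corr_matrix(maps, templates)
            assign = np.argmax(corr**2, axis=1)
            # repair empty clusters from the worst-represented map
            for c in range(k):
                if not (assign == c).any():
                    worst = int(np.argmin(np.max(corr**2, axis=1)))
                    templates[c] = normalize_maps(maps[worst][None, :])[0]
                    assign[worst] = c
                    corr = _corr_matrix(maps, templates)
            for c in range(k):
                members = maps[assign == c]
                new_t = _dominant_pattern(members)
                # fix the (arbitrary) eigenvector sign for determinism
                if new_t @ templates[c] < 0:
                    new_t = -new_t
                templates[c] = new_t
            gev = global_explained_variance(maps, templates, assign, gfp=gfp)
            trace.append(gev)
            if gev - prev_gev <= tol * max(prev_gev, _ZERO_TOL) and _it > 0:
                converged = True
                break
            prev_gev = gev
        corr = _corr_matrix(maps, templates)
        assign = np.argmax(corr**2, axis=1)
        gev = global_explained_variance(maps, templates, assign, gfp=gfp)
        if best is None or gev > best.gev:
            pol = np.where(corr[np.arange(n), assign] >= 0, 1, -1)
            ts = TemplateSet(maps=templates.copy(), labels=list(range(k)), level=level)
            best = ClusterFit(
                templates=ts,
                assignments=assign,
                polarities=pol,
                gev=gev,
                gev_trace=trace,
                converged=converged,
            )
    if not best.converged:
        warnings.warn("modified k-means did not converge; returning best iterate")
    return best


def _rank_by_gev_contribution(fit: ClusterFit, maps: np.ndarray, gfp: np.ndarray) -> np.ndarray:
    """Order of a fit's classes by their contribution to the GEV (descending)."""
    corr = _corr_matrix(maps, fit.templates.maps)
    contrib = np.zeros(fit.templates.k)
    rows = np.arange(maps.shape[0])
    picked = (gfp * corr[rows, fit.assignments]) ** 2
    for c in range(fit.templates.k):
        contrib[c] = picked[fit.assignments == c].sum()
    return np.argsort(-contrib, kind="stable")


def two_level_clustering(
    subject_maps: list,
    k: int = 4,
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
    normalize: bool = True,
):
    """Individual-then-group microstate clustering.

    Stage 1 runs modified k-means per subject on that subject's GFP-peak
    maps (normalized to unit GFP by default, weighted by their original
    GFP).  Stage 2 pools each subject's k templates — every participant
    contributes exactly k unit-GFP maps, ordered by per-class GEV
    contribution, so subjects contribute equally — and clusters the pool
    again with modified k-means to yield the group template set.

    Returns ``(group_fit, individual_fits)``; per-subject seeds are spawned
    deterministically from ``seed`` via ``np.random.SeedSequence``.
    """
    if len(subject_maps) < 1:
        raise ValueError("need at least one subject")
    children = np.random.SeedSequence(seed).spawn(len(subject_maps) + 1)
    fits = []
    pooled = []
    for s, maps in enumerate(subject_maps):
        maps = np.atleast_2d(np.asarray(maps, dtype=float))
        if maps.shape[0] < k:
            raise ValueError(f"subject {s}: fewer than k={k} peak maps")
        gfp = map_gfp(maps)
        x = normalize_maps(maps) if normalize else maps
        try:
            fit = modified_kmeans(
                x, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                seed=children[s].generate_state(1)[0], gfp=gfp,
            )
        except Exception as err:  # noqa: BLE001 - annotate with subject id
            raise RuntimeError(f"individual clustering failed for subject {s}") from err
        fits.append(fit)
        order = _rank_by_gev_contribution(fit, x, gfp)
        pooled.append(fit.templates.maps[order])
    pooled = np.vstack(pooled)
    group_fit = modified_kmeans(
        pooled, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
        seed=children[-1].generate_state(1)[0], level="group",
    )
    return group_fit, fits


def align_templates(candidate: TemplateSet, reference: TemplateSet):
    """Match a candidate template set to a reference set.

    Finds the one-to-one class assignment maximizing the summed absolute
    spatial correlation (optimal over all permutations), re-orders the
    candidate maps accordingly, flips signs so every map correlates
    positively with its reference partner, and adopts the reference labels.

    Returns ``(aligned, mapping, abs_corrs)`` where ``mapping[i]`` is the
    candidate index matched to reference class i.
    """
    if candidate.k != reference.k:
        raise ValueError("template sets must have equal k")
    if candidate.n_electrodes != reference.n_electrodes:
        raise ValueError("template sets must have equal electrode counts")
    corr = _corr_matrix(reference.maps, candidate.maps)
    ref_idx, cand_idx = linear_sum_assignment(-np.abs(corr))
    mapping = cand_idx[np.argsort(ref_idx)]
    picked = corr[np.arange(reference.k), mapping]
    signs = np.where(picked >= 0, 1.0, -1.0)
    maps = candidate.maps[mapping] * signs[:, None]
    aligned = TemplateSet(maps=maps, labels=list(reference.labels), level=candidate.level)
    return aligned, mapping, np.abs(picked)


def canonical_templates(montage: str = "biosemi64") -> TemplateSet:
    """Synthetic stand-ins for the four canonical microstate topographies.

    Built from a standard electrode layout (2-D projected positions): two
    maps with diagonal axis orientations (classes A and B), one with an
    anterior-posterior orientation (class C), and one with a fronto-central
    extreme (class D).  These are idealized geometric fields, not empirical
    group maps; they exist so that group templates can be given the
    conventional A-D labels via :func:`align_templates`.
    """
    import mne

    mont = mne.channels.make_standard_montage(montage)
    pos = np.array([mont.get_positions()["ch_pos"][ch] for ch in mont.ch_names])
    x, y = pos[:, 0], pos[:, 1]
    x = x / np.abs(x).max()
    y = y / np.abs(y).max()
    a = (x + y) / np.sqrt(2)            # right-frontal vs left-posterior diagonal
    b = (-x + y) / np.sqrt(2)           # left-frontal vs right-posterior diagonal
    c = y                               # anterior-posterior axis
    d = np.exp(-((x**2 + (y - 0.35) ** 2) / 0.35))  # fronto-central extreme
    maps = normalize_maps(np.vstack([a, b, c, d]))
    return TemplateSet(maps=maps, labels=["A", "B", "C", "D"], level="group")
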