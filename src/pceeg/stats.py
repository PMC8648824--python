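"""Repeated-measures linear-trend statistics and cluster-based permutation tests.

Per sample (channel, frequency, time) the nine condition cells are collapsed
to the three level means of the tested factor, an ordinary-least-squares
slope over the level codes is fit per subject, and the group statistic is
``F = t^2`` with ``t`` the one-sample t of the subject slopes - a single-df
linear trend test with df = (1, n_subjects - 1).

Samples exceeding the cluster-forming threshold are split by the sign of the
group-mean slope, pruned by the spatial-neighbor rule (a sample survives only
if at least one neighboring channel is also supra-threshold at the same
frequency and time), and grouped into connected components under orthogonal
adjacency: +-1 frequency step, +-1 time step, or a neighboring channel.  A
cluster's value is the sum of its member F values.  Monte-Carlo permutation
of the per-subject assignment of level means to level codes yields the
distribution of the maximum same-sign cluster value, from which each observed
cluster's p-value is the plain proportion of permutation maxima reaching it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from . import design
from .synth import Montage

__all__ = [
    "StatMap",
    "Cluster",
    "PostHocTable",
    "PermutationResult",
    "DegenerateContrastError",
    "FACTOR_LEVEL_CODES",
    "factor_level_means",
    "linear_trend_F",
    "compute_stat_map",
    "f_critical",
    "spatial_neighbor_filter",
    "form_clusters",
    "permutation_test",
    "posthoc_pairwise",
    "ratings_tests",
]


class DegenerateContrastError(ValueError):
    """Raised when a contrast has no between-subject variability to test against."""


#: ascending level codes per factor
FACTOR_LEVEL_CODES = {"INT": (-1, 0, 1), "EXP": (-1, 0, 1), "PE": (0, 1, 2)}


def _cell_codes(factor: str) -> np.ndarray:
    cells = design.build_condition_grid()
    return np.array(
        [getattr(c, {"INT": "int_code", "EXP": "exp_code", "PE": "pe_code"}[factor])
         for c in cells]
    )


def factor_level_means(values: np.ndarray, factor: str) -> tuple[np.ndarray, np.ndarray]:
    """Collapse subject x 9-cell values to subject x 3 factor-level means.

    ``values`` has the 9 canonical cells on axis 1 and arbitrary trailing
    sample axes.  Cells sharing a level are averaged with equal weight
    (3 cells per INT/EXP level; 3, 4 and 2 cells for PE levels 0, 1, 2).
    Returns (means, level codes).
    """
    if factor not in FACTOR_LEVEL_CODES:
        raise ValueError(f"unknown factor {factor!r}")
    values = np.asarray(values, dtype=float)
    if values.ndim < 2 or values.shape[1] != 9:
        raise ValueError("values must be subjects x 9 cells (x samples)")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing or non-finite cell values")
    codes = _cell_codes(factor)
    levels = np.asarray(FACTOR_LEVEL_CODES[factor])
    means = np.stack([values[:, codes == lv].mean(axis=1) for lv in levels], axis=1)
    return means, levels


def _trend_weights(codes: np.ndarray) -> np.ndarray:
    """OLS slope weights: b = sum_l w_l * y_l for regression of y on codes."""
    c = np.asarray(codes, dtype=float)
    cc = c - c.mean()
    denom = (cc ** 2).sum()
    if denom == 0:
        raise ValueError("level codes must not all be equal")
    return cc / denom


def linear_trend_F(
    level_means: np.ndarray, codes
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Single-df repeated-measures linear trend test.

    Per subject the OLS slope of the level means over the level codes is
    computed; ``t = mean(b) / (SD(b)/sqrt(n))`` and ``F = t^2`` with
    df = (1, n-1).  Works elementwise over trailing sample axes.

    Returns ``(F, slope_mean, df)``.  A slope standard deviation of exactly
    zero anywhere raises :class:`DegenerateContrastError`.
    """
    y = np.asarray(level_means, dtype=float)
    if y.ndim < 2 or y.shape[1] != 3:
        raise ValueError("level_means must be subjects x 3 (x samples)")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    w = _trend_weights(codes)
    slopes = np.tensordot(y, w, axes=([1], [0]))  # (n, samples...)
    mean_b = slopes.mean(axis=0)
    sd_b = slopes.std(axis=0, ddof=1)
    if np.any(sd_b == 0):
        raise DegenerateContrastError(
            "zero between-subject slope variability; trend F undefined"
        )
    t = mean_b / (sd_b / np.sqrt(n))
    return t ** 2, mean_b, (1, n - 1)


@dataclass
class StatMap:
    """Per-sample F values and group-mean slopes for one factor.

    ``F`` and ``slope`` are channel x frequency x time; ``F = t^2`` with
    df = (1, n_subjects - 1).
    """

    F: np.ndarray
    slope: np.ndarray
    df: tuple[int, int]
    factor: str


def compute_stat_map(cell_values: np.ndarray, factor: str) -> StatMap:
    """Mass-univariate trend statistics over a subject x 9 x ch x F x T array."""
    means, levels = factor_level_means(cell_values, factor)
    F, slope, df = linear_trend_F(means, levels)
    return StatMap(F=F, slope=slope, df=df, factor=factor)


def f_critical(df1: int, df2: int, alpha: float) -> float:
    """Upper-alpha quantile of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return float(scipy.stats.f.isf(alpha, df1, df2))


# ---------------------------------------------------------------------------
# cluster formation

def spatial_neighbor_filter(mask: np.ndarray, montage: Montage) -> np.ndarray:
    """Keep supra-threshold samples with a supra-threshold spatial neighbor.

    A sample (channel, frequency, time) survives only if at least one
    neighboring channel is also in the mask at the same (frequency, time).
    Channels with an empty neighbor set lose all their samples.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != montage.n_channels:
        raise ValueError("mask channel axis does not match montage")
    adj = montage.adjacency_matrix()
    flat = mask.reshape(mask.shape[0], -1)
    has_nb = adj @ flat  # counts of supra neighbors per (channel, sample)
    return mask & (has_nb > 0).reshape(mask.shape)


@dataclass
class Cluster:
    """A sign-pure connected set of supra-threshold samples."""

    members: np.ndarray  # (n_members, 3) int: channel, freq, time indices
    value: float         # sum of member F values
    sign: str            # "positive" or "negative"
    p: float | None = None


_FT_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _component_labels(mask: np.ndarray, edges: list[tuple[int, int]]) -> tuple[np.ndarray, int]:
    """Connected-component labels under orthogonal (f, t) + channel-graph adjacency.

    Labels each channel's (frequency, time) plane with 4-connectivity, then
    merges labels across montage edges wherever both channels are in the mask
    at the same (frequency, time).  Returns (label array with -1 background,
    number of components).
    """
    n_ch = mask.shape[0]
    labels = np.full(mask.shape, -1, dtype=np.int64)
    offset = 0
    for c in range(n_ch):
        lab, n = scipy.ndimage.label(mask[c], structure=_FT_STRUCTURE)
        plane = lab.astype(np.int64) - 1
        plane[plane >= 0] += offset
        labels[c] = plane
        offset += n
    if offset == 0:
        return labels, 0

    parent = np.arange(offset)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        common = mask[a] & mask[b]
        if not common.any():
            continue
        pairs = np.unique(
            np.stack([labels[a][common], labels[b][common]], axis=1), axis=0
        )
        for la, lb in pairs:
            ra, rb = find(la), find(lb)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    roots = np.array([find(i) for i in range(offset)])
    remap = {r: i for i, r in enumerate(np.unique(roots))}
    flat_roots = np.array([remap[r] for r in roots], dtype=np.int64)
    out = labels.copy()
    sel = labels >= 0
    out[sel] = flat_roots[labels[sel]]
    return out, len(remap)


def _sign_masks(stat: StatMap, threshold: float) -> dict[str, np.ndarray]:
    supra = stat.F > threshold
    return {
        "positive": supra & (stat.slope > 0),
        "negative": supra & (stat.slope < 0),
    }


def form_clusters(stat: StatMap, threshold: float, montage: Montage) -> list[Cluster]:
    """Sign-pure clusters of supra-threshold samples, largest value first.

    Supra-threshold samples (``F > threshold``, strict) are split by slope
    sign; each sign's mask passes the spatial-neighbor filter before
    connected components are extracted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    edges = montage.edges()
    clusters: list[Cluster] = []
    for sign, mask in _sign_masks(stat, threshold).items():
        fmask = spatial_neighbor_filter(mask, montage)
        labels, n = _component_labels(fmask, edges)
        if n == 0:
            continue
        sel = labels >= 0
        sums = np.bincount(labels[sel], weights=stat.F[sel], minlength=n)
        coords = np.argwhere(sel)
        lab_of = labels[sel]
        for k in range(n):
            clusters.append(
                Cluster(members=coords[lab_of == k], value=float(sums[k]), sign=sign)
            )
    clusters.sort(key=lambda c: -c.value)
    return clusters


def _max_cluster_values(F: np.ndarray, slope: np.ndarray, threshold: float,
                        montage_adj: np.ndarray, edges: list[tuple[int, int]]) -> dict[str, float]:
    """Maximum cluster value per sign (0.0 when no cluster forms)."""
    out = {}
    supra = F > threshold
    flat_adj = montage_adj
    for sign, smask in (("positive", supra & (slope > 0)), ("negative", supra & (slope < 0))):
        if not smask.any():
            out[sign] = 0.0
            continue
        flat = smask.reshape(smask.shape[0], -1)
        fmask = smask & ((flat_adj @ flat) > 0).reshape(smask.shape)
        labels, n = _component_labels(fmask, edges)
        if n == 0:
            out[sign] = 0.0
            continue
        sel = labels >= 0
        out[sign] = float(np.bincount(labels[sel], weights=F[sel], minlength=n).max())
    return out


# ---------------------------------------------------------------------------
# permutation inference

@dataclass
class PermutationResult:
    """Observed clusters with permutation p-values and the null maxima."""

    factor: str
    clusters: list[Cluster]
    stat: StatMap
    threshold: float
    alpha: float
    n_perm: int
    seed: int
    add_one: bool
    tail_mode: str = "split"
    max_null: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def alpha_per_tail(self) -> float:
        """Per-tail significance level implied by the overall two-sided alpha.

        In ``split`` mode the two sign tails share the overall alpha
        (alpha/2 each), controlling the two-sided family-wise error at the
        nominal level; ``per_tail`` evaluates each tail at the full alpha.
        """
        return self.alpha / 2.0 if self.tail_mode == "split" else self.alpha

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p < self.alpha_per_tail]


def permutation_test(
    cell_values: np.ndarray,
    factor: str,
    montage: Montage,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    threshold: float | None = None,
    add_one: bool = False,
    tail_mode: str = "split",
) -> PermutationResult:
    """Cluster-based Monte-Carlo permutation test of one factor.

    ``cell_values`` is subjects x 9 cells x channels x freqs x times.  Each
    permutation independently re-assigns, per subject, the three factor-level
    means to the level codes (a uniform draw from the six label
    permutations), recomputes the trend-F map, and applies the identical
    threshold, spatial-neighbor filter and clustering; the maximum same-sign
    cluster value is recorded.  A cluster's p-value is the proportion of
    same-sign permutation maxima at or above its value (``(b+1)/(n+1)`` with
    ``add_one=True``).

    The test is two-sided over positive and negative clusters; with the
    default ``tail_mode="split"`` each tail is judged at ``alpha/2`` so the
    overall two-sided error rate is ``alpha`` (``"per_tail"`` evaluates each
    tail at the full alpha).  The cluster-forming threshold itself defaults
    to the upper-``alpha`` F quantile regardless of tail mode.
    """
    if tail_mode not in ("split", "per_tail"):
        raise ValueError("tail_mode must be 'split' or 'per_tail'")
    cell_values = np.asarray(cell_values, dtype=float)
    if cell_values.ndim != 5:
        raise ValueError("cell_values must be subjects x 9 x channels x freqs x times")
    n_subj = cell_values.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    level_means, levels = factor_level_means(cell_values, factor)
    F, slope, df = linear_trend_F(level_means, levels)
    if threshold is None:
        threshold = f_critical(df[0], df[1], alpha)
    stat = StatMap(F=F, slope=slope, df=df, factor=factor)
    clusters = form_clusters(stat, threshold, montage)

    adj = montage.adjacency_matrix()
    edges = montage.edges()
    w = _trend_weights(levels)
    rng = np.random.default_rng(seed)
    sqrt_n = np.sqrt(n_subj)

    shape = level_means.shape  # (n_subj, 3, ch, F, T)
    lm = level_means.reshape(n_subj, 3, -1)
    max_pos = np.empty(n_perm)
    max_neg = np.empty(n_perm)
    subj_idx = np.arange(n_subj)[:, None]
    for i in range(n_perm):
        perm = rng.permuted(np.broadcast_to(np.arange(3), (n_subj, 3)), axis=1)
        permuted = lm[subj_idx, perm, :]
        slopes = np.einsum("l,nls->ns", w, permuted)
        mean_b = slopes.mean(axis=0)
        sd_b = slopes.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd_b > 0, mean_b / (sd_b / sqrt_n), 0.0)
        Fp = (t ** 2).reshape(shape[2:])
        sp = mean_b.reshape(shape[2:])
        maxima = _max_cluster_values(Fp, sp, threshold, adj, edges)
        max_pos[i] = maxima["positive"]
        max_neg[i] = maxima["negative"]

    null = {"positive": max_pos, "negative": max_neg}
    for c in clusters:
        b = int((null[c.sign] >= c.value).sum())
        c.p = (b + 1) / (n_perm + 1) if add_one else b / n_perm

    return PermutationResult(
        factor=factor, clusters=clusters, stat=stat, threshold=float(threshold),
        alpha=alpha, n_perm=n_perm, seed=seed, add_one=add_one,
        tail_mode=tail_mode, max_null=null,
    )


# ---------------------------------------------------------------------------
# post-hoc tests and ratings

@dataclass
class PostHocTable:
    """Bonferroni-corrected pairwise comparisons of the three factor levels.

    ``pairs`` has one row per level pair with the mean difference, paired t,
    raw and adjusted p; ``levels`` has the group mean (M) and SD of the
    subject-level values per factor level.
    """

    pairs: pd.DataFrame
    levels: pd.DataFrame


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise DegenerateContrastError(
            "paired differences are a nonzero constant; t undefined"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def _posthoc_from_levels(level_values: np.ndarray, levels: np.ndarray) -> PostHocTable:
    """Pairwise Bonferroni-corrected paired t-tests on subject x 3 level values."""
    rows = []
    pairs = [(0, 1), (1, 2), (0, 2)]
    for i, j in pairs:
        t, p = _paired_t(level_values[:, j], level_values[:, i])
        rows.append(
            {
                "level_a": int(levels[i]),
                "level_b": int(levels[j]),
                "mean_diff": float(level_values[:, j].mean() - level_values[:, i].mean()),
                "t": t,
                "p_raw": p,
                "p_bonferroni": min(1.0, 3.0 * p),
            }
        )
    level_rows = [
        {"level": int(levels[k]), "M": float(level_values[:, k].mean()),
         "SD": float(level_values[:, k].std(ddof=1))}
        for k in range(3)
    ]
    return PostHocTable(pairs=pd.DataFrame(rows), levels=pd.DataFrame(level_rows))


def posthoc_pairwise(cluster: Cluster, cell_values: np.ndarray, factor: str) -> PostHocTable:
    """Post-hoc level comparisons on the cluster-averaged values.

    Per subject and condition cell the values are averaged over all
    (channel, frequency, time) members of the cluster, collapsed to factor
    level means, and the three level pairs are compared with paired t-tests
    under Bonferroni correction (x3).
    """
    if len(cluster.members) == 0:
        raise ValueError("cluster has no members")
    cell_values = np.asarray(cell_values, dtype=float)
    ch, fr, ti = cluster.members.T
    cluster_mean = cell_values[:, :, ch, fr, ti].mean(axis=2)  # (n_subj, 9)
    level_values, levels = factor_level_means(cluster_mean, factor)
    return _posthoc_from_levels(level_values, levels)


@dataclass
class RatingsFactorResult:
    F: float
    p: float
    df: tuple[int, int]
    slope_mean: float
    posthoc: PostHocTable


def ratings_tests(ratings_cells: np.ndarray) -> dict[str, RatingsFactorResult]:
    """Linear-trend tests of the three factors on subject x 9 mean ratings.

    For each factor the nine cell means collapse to three level means, the
    single-df trend F with df (1, n-1) is computed, and Bonferroni-corrected
    post-hoc paired tests compare the levels.
    """
    ratings_cells = np.asarray(ratings_cells, dtype=float)
    if ratings_cells.ndim != 2 or ratings_cells.shape[1] != 9:
        raise ValueError("ratings must be subjects x 9 cell means")
    out = {}
    for factor in design.FACTORS:
        level_values, levels = factor_level_means(ratings_cells, factor)
        F, slope, df = linear_trend_F(level_values, levels)
        p = float(scipy.stats.f.sf(F, df[0], df[1]))
        out[factor] = RatingsFactorResult(
            F=float(F), p=p, df=df, slope_mean=float(slope),
            posthoc=_posthoc_from_levels(level_values, levels),
        )
    return out
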