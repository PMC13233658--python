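"""Cohort-level statistics on vertex-wise mechanomarker fields.

Node-wise two-group comparisons use Welch's unequal-variance t-test with
Benjamini-Hochberg false-discovery-rate control across vertices at
alpha = 0.05. Hemispheric symmetry is assessed by reflecting the mesh across
a midsagittal plane, pairing each vertex with its nearest mirror partner,
and testing left-right marker differences. Cohort homogeneity of a marker is
summarised by its per-vertex variance field (after per-subject min-max
normalisation) and variance fields of two markers are compared with a
histogram-based Kullback-Leibler divergence. Burden-bin effects use one-way
ANOVA with eta-squared effect sizes and BH-corrected post-hoc Welch tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .mesh_core import SurfaceMesh
from .wmh import BurdenBin

__all__ = [
    "CohortFieldStack",
    "TestResultField",
    "HemisphericPairing",
    "welch_t",
    "nodewise_test",
    "hemispheric_map",
    "hemispheric_difference_test",
    "variance_field",
    "kl_divergence",
    "anova_eta2",
    "pearson",
    "burden_bin_summary",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CohortFieldStack:
    """Subjects x vertices matrix of one marker plus group labels."""
    values: np.ndarray            # (n_subjects, n_vertices)
    groups: np.ndarray            # (n_subjects,) labels, e.g. 'F'/'M'
    marker: str = "marker"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        g = np.asarray(self.groups)
        if v.ndim != 2:
            raise ValueError("values must be (subjects, vertices)")
        if len(g) != v.shape[0]:
            raise ValueError("group labels must match subject count")
        if any(x is None or (isinstance(x, float) and np.isnan(x)) for x in g.tolist()):
            raise ValueError("missing group labels")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "groups", g)


@dataclass(frozen=True)
class TestResultField:
    """Per-vertex test statistics with BH-adjusted p-values."""
    statistic: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> np.ndarray:
        return self.p_adjusted < self.alpha


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Zero-variance convention: when both groups are constant, t = 0 and p = 1
    if the constants agree; p = 0 with an infinite statistic if they differ.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def nodewise_test(stack: CohortFieldStack, grouping=None,
                  alpha: float = ALPHA) -> TestResultField:
    """Welch t-test at every vertex with BH FDR correction across vertices.

    Vertices where both groups have zero variance are reported with t = 0,
    p = 1 (no evidence) so downstream maps stay total.
    """
    groups = stack.groups if grouping is None else np.asarray(grouping)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.tolist()}")
    a = stack.values[groups == labels[0]]
    b = stack.values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 at zero-variance vertices
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return TestResultField(statistic=t, p_raw=p, p_adjusted=p_adj, alpha=alpha,
                           extra={"groups": labels.tolist()})


# ---------------------------------------------------------------------------
# hemispheric symmetry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HemisphericPairing:
    """Nearest-mirror-vertex pairing across a midsagittal plane."""
    partner: np.ndarray     # partner vertex index per vertex
    distance: np.ndarray    # mm, reflection-to-partner distance
    side: np.ndarray        # +1 / -1 / 0 signed side of the plane
    plane_point: np.ndarray
    plane_normal: np.ndarray


def hemispheric_map(mesh: SurfaceMesh, plane_point=None,
                    plane_normal=(1.0, 0.0, 0.0)) -> HemisphericPairing:
    """Pair each vertex with the vertex nearest to its mirror image.

    The default plane is the sagittal plane (normal +x in RAS) through the
    mesh centroid. Pairing distances localise asymmetries: they are ~0 for a
    mirror-symmetric mesh and grow where the two sides disagree.
    """
    normal = np.asarray(plane_normal, dtype=np.float64)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("degenerate plane normal")
    normal = normal / nn
    point = (mesh.vertices.mean(axis=0) if plane_point is None
             else np.asarray(plane_point, dtype=np.float64))
    signed = (mesh.vertices - point) @ normal
    reflected = mesh.vertices - 2.0 * signed[:, None] * normal
    dist, partner = cKDTree(mesh.vertices).query(reflected)
    return HemisphericPairing(
        partner=partner, distance=dist, side=np.sign(signed),
        plane_point=point, plane_normal=normal,
    )


def hemispheric_difference_test(stack: CohortFieldStack,
                                pairing: HemisphericPairing,
                                alpha: float = ALPHA) -> TestResultField:
    """Welch test of left-vs-right marker values at each paired vertex.

    For every vertex on the positive side of the plane, the subjects' values
    there form one sample and the values at its mirror partner the other.
    Also returns the relative difference field (L - R) / mean in ``extra``.
    Vertices without a usable partner (partner on the same side) are skipped
    and reported.
    """
    left = np.nonzero(pairing.side > 0)[0]
    usable = left[pairing.side[pairing.partner[left]] <= 0]
    skipped = np.setdiff1d(left, usable)
    if len(usable) == 0:
        raise ValueError("no usable hemisphere pairs")
    lvals = stack.values[:, usable]
    rvals = stack.values[:, pairing.partner[usable]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(lvals, rvals, axis=0, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    mean = 0.5 * (lvals.mean(axis=0) + rvals.mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean != 0, (lvals.mean(axis=0) - rvals.mean(axis=0)) / mean, 0.0)
    return TestResultField(
        statistic=t, p_raw=p, p_adjusted=p_adj, alpha=alpha,
        extra={"vertices": usable, "partners": pairing.partner[usable],
               "relative_difference": rel, "skipped": skipped},
    )


# ---------------------------------------------------------------------------
# variance homogeneity and KL divergence
# ---------------------------------------------------------------------------

def variance_field(stack: CohortFieldStack) -> np.ndarray:
    """Per-vertex sample variance after per-subject min-max normalisation.

    Each subject's field is rescaled to [0, 1] before the vertex-wise
    variance is taken, so subjects with larger overall deformations do not
    dominate. Subjects with a constant field cannot be normalised and are
    skipped with a warning.
    """
    rows = []
    for i, row in enumerate(stack.values):
        rng = row.max() - row.min()
        if rng == 0.0:
            warnings.warn(f"subject {i} has a constant field; skipped")
            continue
        rows.append((row - row.min()) / rng)
    if len(rows) < 2:
        raise ValueError("need at least 2 normalisable subjects")
    return np.var(np.asarray(rows), axis=0, ddof=1)


def kl_divergence(sample_a, sample_b, bins: int = 50,
                  epsilon: float = 1e-10) -> float:
    """KL divergence D(a || b) in nats between two empirical distributions.

    Both samples are histogrammed on shared equal-width bins spanning their
    pooled range; counts get additive epsilon smoothing, are renormalised,
    and D = sum p log(p/q). Nonnegative; zero iff the histograms agree;
    not symmetric in its arguments.
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1.0  # all mass in one bin either way
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    p = pa.astype(np.float64) + epsilon
    q = pb.astype(np.float64) + epsilon
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


# ---------------------------------------------------------------------------
# ANOVA, correlation, bin summaries
# ---------------------------------------------------------------------------

def anova_eta2(groups: list) -> dict:
    """One-way ANOVA with eta-squared effect size and BH post-hoc Welch tests.

    eta^2 = SS_between / SS_total. Post-hoc pairwise comparisons are run
    only when the omnibus F is significant at ALPHA.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(groups)
    if len(pooled) - len(groups) < 1:
        raise ValueError("insufficient degrees of freedom")
    grand = pooled.mean()
    ss_total = float(np.sum((pooled - grand) ** 2))
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    if ss_total == 0.0:
        return {"F": 0.0, "p": 1.0, "eta2": 0.0, "posthoc": None}
    F, p = stats.f_oneway(*groups)
    eta2 = ss_between / ss_total
    posthoc = None
    if p < ALPHA:
        pairs, praw = [], []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                t_ij, p_ij = welch_t(groups[i], groups[j])
                pairs.append((i, j, t_ij))
                praw.append(p_ij)
        _, p_adj, _, _ = multipletests(praw, alpha=ALPHA, method="fdr_bh")
        posthoc = [
            {"pair": (i, j), "t": t_ij, "p_raw": pr, "p_adjusted": pa}
            for (i, j, t_ij), pr, pa in zip(pairs, praw, p_adj)
        ]
    return {"F": float(F), "p": float(p), "eta2": float(eta2), "posthoc": posthoc}


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.var() == 0.0 or y.var() == 0.0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


_BIN_ORDER = [BurdenBin.NO_WMH, BurdenBin.LOW, BurdenBin.INTERMEDIATE, BurdenBin.HIGH]


def burden_bin_summary(stack: CohortFieldStack, bins: np.ndarray) -> dict:
    """Average a marker per subject within each WMH burden bin.

    Returns a table of per-subject bin means, the cohort mean +- SD per bin,
    and the one-way ANOVA across bins with eta-squared. Empty bins are
    reported as missing and excluded from the ANOVA.
    """
    bins = np.asarray(bins, dtype=object)
    if len(bins) != stack.values.shape[1]:
        raise ValueError("bin labels do not match vertex count")
    per_subject = {}
    for cat in _BIN_ORDER:
        idx = np.nonzero([b == cat for b in bins])[0]
        per_subject[cat.value] = (stack.values[:, idx].mean(axis=1)
                                  if len(idx) else None)
    present = {k: v for k, v in per_subject.items() if v is not None}
    missing = [k for k, v in per_subject.items() if v is None]
    if missing:
        warnings.warn(f"empty burden bins excluded from ANOVA: {missing}")
    table = pd.DataFrame({
        k: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for k, v in present.items()
    }).T
    anova = anova_eta2(list(present.values())) if len(present) >= 2 else None
    return {
        "per_subject": {k: np.asarray(v) for k, v in present.items()},
        "summary": table,
        "missing_bins": missing,
        "anova": anova,
    }
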