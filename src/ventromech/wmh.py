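"""White matter hyperintensity (WMH) mapping on the ventricular surface.

Periventricular WMHs appear as bright FLAIR regions hugging the ventricular
wall. Each subject's surface mesh is interpolated onto their co-registered
FLAIR images; a vertex is flagged as WMH when its baseline intensity exceeds
the subject's 90th-percentile baseline intensity, and longitudinal emergence
is read off by applying the *same* baseline-derived threshold to follow-up
intensities. Across subjects the binary indicators average into per-vertex
occurrence probabilities P_i = (1/N) sum_s W_i^(s), their longitudinal
change dP_i = P_i^fu - P_i^bl, burden bins, and peak-load likelihood maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .mesh_core import SurfaceMesh, triangle_areas
from .imagefield import ScalarVolume, sample
from .mechanomarkers import MarkerSet

__all__ = [
    "BurdenBin",
    "WMHIndicator",
    "sample_intensity",
    "wmh_indicator",
    "probability_map",
    "probability_change",
    "bin_burden",
    "peak_load_likelihood",
    "wall_fraction",
]

DEFAULT_PERCENTILE = 90.0


class BurdenBin(str, Enum):
    """WMH probability burden category per vertex."""
    NO_WMH = "noWMH"          # P = 0
    LOW = "low"               # 0 < P < 1/3
    INTERMEDIATE = "intermediate"  # 1/3 <= P <= 2/3
    HIGH = "high"             # P > 2/3
    EXCLUDED = "excluded"     # adjacent to deep grey matter, dropped


@dataclass(frozen=True)
class WMHIndicator:
    """Binary WMH indicators for one subject at both time points."""
    baseline: np.ndarray   # bool per vertex
    followup: np.ndarray   # bool per vertex, same baseline-derived threshold
    threshold: float       # intensity units
    percentile: float


def sample_intensity(volume: ScalarVolume, mesh: SurfaceMesh,
                     out_of_bounds: str = "raise") -> np.ndarray:
    """Trilinear image intensity at each mesh vertex."""
    return sample(volume, mesh.vertices, out_of_bounds=out_of_bounds)


def wmh_indicator(baseline_intensity: np.ndarray,
                  followup_intensity: np.ndarray | None = None,
                  q: float = DEFAULT_PERCENTILE) -> WMHIndicator:
    """Threshold vertex intensities at the q-th percentile of baseline.

    The percentile uses linear interpolation between order statistics. The
    comparison is strict (> threshold), so all-equal intensities flag no
    vertex; values within a 1e-9 relative tolerance of the threshold count
    as ties, not exceedances, so floating-point dust from interpolating
    near-constant image regions cannot flag vertices. Follow-up uses the
    same baseline-derived threshold so that newly emerged hyperintensities
    are detected.
    """
    bl = np.asarray(baseline_intensity, dtype=np.float64)
    if bl.size == 0:
        raise ValueError("empty intensity field")
    thr = float(np.percentile(bl, q))
    cut = thr + 1e-9 * max(1.0, abs(thr))
    w_bl = bl > cut
    if followup_intensity is None:
        w_fu = w_bl.copy()
    else:
        fu = np.asarray(followup_intensity, dtype=np.float64)
        if fu.shape != bl.shape:
            raise ValueError("baseline and follow-up fields differ in length")
        w_fu = fu > cut
    return WMHIndicator(baseline=w_bl, followup=w_fu, threshold=thr, percentile=q)


def probability_map(indicators: Sequence[np.ndarray]) -> np.ndarray:
    """Per-vertex fraction of subjects exhibiting WMH: P_i = (1/N) sum W_i."""
    if len(indicators) == 0:
        raise ValueError("need at least one subject")
    mat = np.asarray([np.asarray(w, dtype=np.float64) for w in indicators])
    if mat.ndim != 2:
        raise ValueError("indicator fields differ in length")
    if not np.all((mat == 0) | (mat == 1)):
        raise ValueError("indicators must be binary")
    return mat.mean(axis=0)


def probability_change(p_baseline: np.ndarray, p_followup: np.ndarray) -> np.ndarray:
    """Node-wise probability change dP = P_fu - P_bl, in [-1, 1]."""
    pb = np.asarray(p_baseline, dtype=np.float64)
    pf = np.asarray(p_followup, dtype=np.float64)
    if pb.shape != pf.shape:
        raise ValueError("probability fields differ in length")
    return pf - pb


def bin_burden(p: np.ndarray, exclusion: Iterable[int] = ()) -> np.ndarray:
    """Assign each vertex a WMH burden bin from its occurrence probability.

    noWMH: P = 0; low: 0 < P < 1/3; intermediate: 1/3 <= P <= 2/3;
    high: P > 2/3. Boundary probabilities go to the intermediate bin.
    Excluded vertices (e.g. adjacent to deep grey matter) are dropped from
    every bin.
    """
    p = np.asarray(p, dtype=np.float64)
    out = np.empty(len(p), dtype=object)
    out[p == 0] = BurdenBin.NO_WMH
    out[(p > 0) & (p < 1.0 / 3.0)] = BurdenBin.LOW
    out[(p >= 1.0 / 3.0) & (p <= 2.0 / 3.0)] = BurdenBin.INTERMEDIATE
    out[p > 2.0 / 3.0] = BurdenBin.HIGH
    excl = np.asarray(sorted(set(int(i) for i in exclusion)), dtype=np.int64)
    if excl.size:
        out[excl] = BurdenBin.EXCLUDED
    return out


def peak_load_likelihood(subjects: Sequence[MarkerSet],
                         q_high: float = 90.0,
                         q_low: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex likelihood of peak mechanical loading across a cohort.

    For each subject, a vertex satisfies the *expansion* criterion when its
    area stretch is > 1 and its maximum principal wall strain lies above that
    subject's 90th strain percentile; the *shrinking* criterion when area
    stretch is < 1 and strain lies below the subject's 10th percentile. The
    returned maps are the fractions of subjects satisfying each criterion.

    The strict area-stretch inequalities carry a 1e-12 tolerance so exactly
    strain-free deformations (lambda_A = 1 up to round-off) satisfy neither.
    """
    if len(subjects) == 0:
        raise ValueError("empty cohort")
    n_vert = subjects[0].mesh.n_vertices
    expand = np.zeros(n_vert)
    shrink = np.zeros(n_vert)
    for ms in subjects:
        if ms.mesh.n_vertices != n_vert:
            raise ValueError("subjects do not share mesh topology")
        strain = ms.max_principal_strain
        hi = np.percentile(strain, q_high)
        lo = np.percentile(strain, q_low)
        expand += (ms.area_stretch > 1.0 + 1e-12) & (strain > hi)
        shrink += (ms.area_stretch < 1.0 - 1e-12) & (strain < lo)
    n = float(len(subjects))
    return expand / n, shrink / n


def wall_fraction(marker_set: MarkerSet, criterion: np.ndarray) -> float:
    """Area-weighted percentage of the wall whose vertices satisfy a criterion.

    Vertex weights are one third of the summed incident triangle areas, so
    the weights add up to the total surface area.
    """
    criterion = np.asarray(criterion, dtype=bool)
    mesh = marker_set.mesh
    if len(criterion) != mesh.n_vertices:
        raise ValueError("criterion length does not match mesh")
    areas = triangle_areas(mesh)
    w = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(w, mesh.triangles[:, k], areas / 3.0)
    return 100.0 * float(w[criterion].sum() / w.sum())
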