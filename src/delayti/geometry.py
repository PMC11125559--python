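"""Population-geometry indices and encoding analysis.

All indices operate on per-condition activity states referenced to the
cross-condition mean (XCM) and, in the standard pipeline, reduced to the top
PCs of delay-period activity. Item groups (for odd n_items):

- S       : all items
- S_outer : all items except the middle one
- S_high  : items ranked above the middle
- S_low   : items ranked below the middle
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .synthdata import random_activity_like


@dataclass(frozen=True)
class ItemGroups:
    """Index groups over ranks (0-based indices into the condition axis)."""

    n_items: int = 7

    def __post_init__(self) -> None:
        if self.n_items % 2 == 0:
            raise ValueError("item groups are defined for odd n_items only")

    @property
    def all_items(self) -> list[int]:
        return list(range(self.n_items))

    @property
    def middle(self) -> int:
        return self.n_items // 2

    @property
    def outer(self) -> list[int]:
        return [i for i in range(self.n_items) if i != self.middle]

    @property
    def high(self) -> list[int]:
        return list(range(self.middle))

    @property
    def low(self) -> list[int]:
        return list(range(self.middle + 1, self.n_items))


def _xcm_referenced(states: np.ndarray, xcm: np.ndarray | None) -> np.ndarray:
    if xcm is None:
        xcm = states.mean(axis=0)
    return states - xcm


def _unit_rows(v: np.ndarray, context: str) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1)
    bad = norms < 1e-12
    if bad.any():
        warnings.warn(f"{context}: excluding {bad.sum()} zero-norm vector(s)")
    return v, norms, ~bad


def collinearity_index(
    states: np.ndarray,
    xcm: np.ndarray | None = None,
    groups: ItemGroups | None = None,
) -> float:
    """Mean |cos| over unordered pairs of XCM-referenced outer-item states.

    1 for perfectly collinear arrangements; approximately 0.28 for i.i.d.
    Gaussian states in 10 dimensions.
    """
    groups = groups or ItemGroups(states.shape[0])
    v = _xcm_referenced(states, xcm)[groups.outer]
    v, norms, ok = _unit_rows(v, "collinearity_index")
    idx = np.flatnonzero(ok)
    if len(idx) < 2:
        return np.nan
    u = v[idx] / norms[idx, None]
    cos = np.abs(u @ u.T)
    iu = np.triu_indices(len(idx), k=1)
    return float(cos[iu].mean())


def ordered_collinearity_index(
    states: np.ndarray,
    xcm: np.ndarray | None = None,
    groups: ItemGroups | None = None,
) -> float:
    """-(mean cos) over high x low item pairs; +1 when the high and low
    groups point in opposite directions from the XCM (rank-ordered line)."""
    groups = groups or ItemGroups(states.shape[0])
    v = _xcm_referenced(states, xcm)
    v, norms, ok = _unit_rows(v, "ordered_collinearity_index")
    hi = [i for i in groups.high if ok[i]]
    lo = [i for i in groups.low if ok[i]]
    if not hi or not lo:
        return np.nan
    uh = v[hi] / norms[hi, None]
    ul = v[lo] / norms[lo, None]
    return float(-(uh @ ul.T).mean())


def mean_angle_change(
    states_early: np.ndarray,
    states_late: np.ndarray,
    xcm_early: np.ndarray | None = None,
    xcm_late: np.ndarray | None = None,
) -> float:
    """Mean over all unordered item pairs of cos(late) - cos(early)."""
    ve = _xcm_referenced(states_early, xcm_early)
    vl = _xcm_referenced(states_late, xcm_late)
    ue = ve / np.linalg.norm(ve, axis=1, keepdims=True)
    ul = vl / np.linalg.norm(vl, axis=1, keepdims=True)
    iu = np.triu_indices(states_early.shape[0], k=1)
    return float(((ul @ ul.T) - (ue @ ue.T))[iu].mean())


def mean_distance_change(
    states_early: np.ndarray, states_late: np.ndarray
) -> float:
    """Mean over all unordered item pairs of the change in pairwise
    Euclidean distance (late minus early); raw states, no XCM reference."""
    def pdist(x):
        d = x[:, None, :] - x[None, :, :]
        return np.linalg.norm(d, axis=-1)

    iu = np.triu_indices(states_early.shape[0], k=1)
    return float((pdist(states_late) - pdist(states_early))[iu].mean())


def random_index_baseline(
    index_fn,
    shape: tuple[int, int],
    n_draws: int = 1000,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Distribution of an index over i.i.d. standard-normal configurations."""
    rng = np.random.default_rng(seed)
    template = np.empty(shape)
    return np.array(
        [index_fn(random_activity_like(template, rng), **kwargs)
         for _ in range(n_draws)]
    )


# ---------------------------------------------------------------------------
# Axis angles
# ---------------------------------------------------------------------------

def axis_axis_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """|dot| between two unit axes."""
    return float(abs(np.dot(a, b)))


def axis_plane_cosine(axis: np.ndarray, plane: np.ndarray) -> float:
    """Mean |dot| of an axis with the two orthonormal plane vectors."""
    return float(np.abs(plane @ axis).mean())


def axis_angle_table(
    choice_axis: np.ndarray,
    xcm_axis: np.ndarray,
    readout_axis: np.ndarray,
    plane: np.ndarray | None = None,
    n_random: int = 1000,
    seed: int = 0,
) -> dict:
    """The four angular relationships plus random-unit-vector references.

    Axes must already live in a common (PC) space of dimension k. The plane
    is a (2, k) orthonormal pair (the comparison-oscillation plane); plane
    entries are NaN when no oscillatory mode exists.
    """
    k = len(choice_axis)
    rng = np.random.default_rng(seed)

    def rand_unit(n):
        v = rng.standard_normal((n, k))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def rand_plane():
        v = rng.standard_normal((2, k))
        q, _ = np.linalg.qr(v.T)
        return q.T[:2]

    table = dict(
        xcm_vs_choice=axis_axis_cosine(xcm_axis, choice_axis),
        choice_vs_readout=axis_axis_cosine(choice_axis, readout_axis),
    )
    ref = dict(
        xcm_vs_choice=np.abs(
            (rand_unit(n_random) * rand_unit(n_random)).sum(axis=1)
        ),
        choice_vs_readout=np.abs(
            (rand_unit(n_random) * rand_unit(n_random)).sum(axis=1)
        ),
    )
    if plane is not None:
        table["choice_vs_plane"] = axis_plane_cosine(choice_axis, plane)
        table["xcm_vs_plane"] = axis_plane_cosine(xcm_axis, plane)
        ref["choice_vs_plane"] = np.array(
            [axis_plane_cosine(rand_unit(1)[0], rand_plane())
             for _ in range(n_random)]
        )
        ref["xcm_vs_plane"] = np.array(
            [axis_plane_cosine(rand_unit(1)[0], rand_plane())
             for _ in range(n_random)]
        )
    return dict(angles=table, random_reference=ref)


# ---------------------------------------------------------------------------
# Geometry report over a delay-activity block
# ---------------------------------------------------------------------------

@dataclass
class GeometryReport:
    collinearity_early: float
    collinearity_late: float
    collinearity_change: float
    ordered_collinearity_early: float
    ordered_collinearity_late: float
    ordered_collinearity_change: float
    mean_angle_change: float
    mean_distance_change: float
    n_pcs: int
    random_baseline: dict[str, float] = field(default_factory=dict)


def geometry_report(
    delay_activity: np.ndarray,
    n_pcs: int = 10,
    groups: ItemGroups | None = None,
    n_random: int = 200,
    seed: int = 0,
) -> GeometryReport:
    """Full collinearity-family report from delay-period activity.

    Parameters
    ----------
    delay_activity : (n_items, n_delay_steps, N) noise-free activity of the
        item-1 conditions across the delay window.
    n_pcs : PCA dimension; PCs are computed from the pooled delay activity.
    """
    from .dynamics import pca_project  # local import to avoid a cycle

    n_items, n_steps, _ = delay_activity.shape
    groups = groups or ItemGroups(n_items)
    proj, _ = pca_project(delay_activity.reshape(n_items * n_steps, -1), n_pcs)
    proj = proj.reshape(n_items, n_steps, n_pcs)

    early, late = proj[:, 0, :], proj[:, -1, :]
    ce = collinearity_index(early, groups=groups)
    cl = collinearity_index(late, groups=groups)
    oe = ordered_collinearity_index(early, groups=groups)
    ol = ordered_collinearity_index(late, groups=groups)

    rng = np.random.default_rng(seed)
    rand = dict(collinearity=[], ordered_collinearity=[])
    for _ in range(n_random):
        r = rng.standard_normal((n_items, n_pcs))
        rand["collinearity"].append(collinearity_index(r, groups=groups))
        rand["ordered_collinearity"].append(
            ordered_collinearity_index(r, groups=groups)
        )
    baseline = {k: float(np.mean(v)) for k, v in rand.items() if v}

    return GeometryReport(
        collinearity_early=ce,
        collinearity_late=cl,
        collinearity_change=cl - ce,
        ordered_collinearity_early=oe,
        ordered_collinearity_late=ol,
        ordered_collinearity_change=ol - oe,
        mean_angle_change=mean_angle_change(early, late),
        mean_distance_change=mean_distance_change(early, late),
        n_pcs=n_pcs,
        random_baseline=baseline,
    )


# ---------------------------------------------------------------------------
# Encoding analysis
# ---------------------------------------------------------------------------

@dataclass
class EncodingReport:
    """End-item encoding gain across the delay along one activity axis."""

    projections: np.ndarray  # (n_items, n_delay_steps) axis projections
    gain_per_end_item: dict[int, float]  # rank -> log2 |end| / |start|
    encoding_index: float  # mean over end items; >0 first-dominant
    axis_name: str


def encoding_index(
    delay_activity: np.ndarray,
    axis: np.ndarray,
    axis_name: str = "readout",
    xcm: np.ndarray | None = None,
) -> EncodingReport:
    """log2 magnitude gain of end-item encodings over the delay.

    Projects XCM-referenced delay activity onto ``axis`` and compares the
    magnitude of the end items' projections at the last vs first delay step.
    Positive index: the item-1 encoding grows during the delay
    (first-dominant); negative: it shrinks (second-dominant).
    """
    n_items = delay_activity.shape[0]
    if xcm is None:
        xcm = delay_activity.mean(axis=0)
    proj = (delay_activity - xcm) @ axis  # (n_items, n_steps)
    gains = {}
    for rank in (1, n_items):
        start = abs(proj[rank - 1, 0])
        end = abs(proj[rank - 1, -1])
        if start < 1e-12:
            warnings.warn(f"zero-magnitude start projection for rank {rank}")
            gains[rank] = np.nan
        else:
            gains[rank] = float(np.log2(end / start))
    vals = [g for g in gains.values() if np.isfinite(g)]
    return EncodingReport(
        projections=proj,
        gain_per_end_item=gains,
        encoding_index=float(np.mean(vals)) if vals else np.nan,
        axis_name=axis_name,
    )
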