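"""Concentric-bin clustering index, compartments, and the AZ-associated pool.

The clustering index asks whether recycled (PC+) vesicles are locally
enriched around one another beyond the synapse-wide baseline.  Around each
focal PC+ vesicle, expanding concentric circular bins (20 nm radial steps)
collect the local recycled fraction among neighboring vesicles (focal
excluded); per-radius values are averaged over focal vesicles and divided by
the focal-excluded whole-cluster fraction (N_R - 1)/(N - 1), so the index
converges to exactly 1 at the radius enclosing the whole cluster.  Index 1
means no local structure; > 1 means local PC+ clustering.

Compartments partition vesicles by nearest-AZ distance (active zone
0-35 nm, front 35-100 nm, middle 100-300 nm, rear/side 300-800 nm); the
AZ-associated pool is the first line of vesicles with membrane within 20 nm
of the release site and an unobstructed line of sight to it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points

from .model import RECYCLED, SynapseSection
from .pool_metrics import CorrelationResult, TestResult, spearman_correlation

DEFAULT_STEP_NM = 20.0
PEAK_WINDOW_NM = (40.0, 240.0)
AZ_POOL_GAP_NM = 20.0

#: Compartment bands as [lower, upper) nm of center-to-nearest-AZ distance;
#: the final band is closed at 800 nm and distances beyond are clamped into it.
COMPARTMENT_BANDS: Tuple[Tuple[str, float, float], ...] = (
    ("active_zone", 0.0, 35.0),
    ("front", 35.0, 100.0),
    ("middle", 100.0, 300.0),
    ("rear_side", 300.0, 800.0),
)
COMPARTMENT_NAMES = tuple(name for name, _, _ in COMPARTMENT_BANDS)


@dataclass(frozen=True)
class ClusterProfile:
    """Per-radius absolute recycled fraction and normalized clustering index."""

    section_id: str
    radii: np.ndarray            # nm, multiples of the step
    absolute_fraction: np.ndarray
    clustering_index: np.ndarray  # NaN when the reference fraction is 0
    n_contributing: np.ndarray    # focal vesicles with non-empty neighborhoods
    reference_fraction: float     # (N_R - 1) / (N - 1)

    @property
    def r_max(self) -> float:
        return float(self.radii[-1])

    def index_at(self, radius: float) -> float:
        """Clustering index at ``radius``; constant 1 beyond the profile end."""
        i = np.searchsorted(self.radii, radius)
        if i >= self.radii.size:
            return 1.0
        return float(self.clustering_index[i])


@dataclass(frozen=True)
class AZPoolResult:
    section_id: str
    member_ids: Tuple[str, ...]
    recycled_fraction_az: Optional[float]  # None when the pool is empty


@dataclass(frozen=True)
class PeakClusterAmplitude:
    section_id: str
    amplitude: float
    truncated: bool  # profile ended before the nominal window


# ---------------------------------------------------------------------------
# clustering profiles


def _profile_from_arrays(
    section_id: str,
    centers: np.ndarray,
    recycled: np.ndarray,
    step: float,
    r_max: Optional[float],
) -> ClusterProfile:
    n = centers.shape[0]
    if n < 2:
        raise ValueError(f"section {section_id!r}: clustering needs >= 2 vesicles")
    n_rec = int(recycled.sum())
    if n_rec < 1:
        raise ValueError(f"section {section_id!r}: no recycled vesicle")
    dist = cdist(centers, centers)
    if r_max is None:
        r_max = step * math.ceil(dist.max() / step)
        r_max = max(r_max, step)
    radii = np.arange(step, r_max + step / 2, step)
    focal = np.flatnonzero(recycled)
    d_focal = dist[focal]  # (n_focal, n)
    self_mask = np.zeros_like(d_focal, dtype=bool)
    self_mask[np.arange(focal.size), focal] = True
    # neighbor membership per radius: (n_focal, n, n_radii)
    within = (d_focal[:, :, None] <= radii[None, None, :]) & ~self_mask[:, :, None]
    n_all = within.sum(axis=1).astype(float)           # (n_focal, n_radii)
    n_rec_nb = within[:, recycled, :].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.where(n_all > 0, n_rec_nb / np.maximum(n_all, 1), np.nan)
    contributing = (n_all > 0).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        absolute = np.nanmean(local, axis=0)
    reference = (n_rec - 1) / (n - 1)
    # when a radius encloses the whole cluster every focal fraction equals the
    # reference; write it directly so the terminal index is exactly 1 and not
    # off by a summation ulp
    complete = (n_all == n - 1).all(axis=0)
    absolute[complete] = reference
    with np.errstate(invalid="ignore", divide="ignore"):
        index = absolute / reference if reference > 0 else np.full_like(absolute, np.nan)
    return ClusterProfile(
        section_id=section_id,
        radii=radii,
        absolute_fraction=absolute,
        clustering_index=index,
        n_contributing=contributing.astype(int),
        reference_fraction=reference,
    )


def clustering_profile(
    section: SynapseSection,
    step: float = DEFAULT_STEP_NM,
    r_max: Optional[float] = None,
) -> ClusterProfile:
    """Concentric-bin clustering profile of one section.

    Bins are cumulative: the value at radius r covers all neighbors within r
    of the focal vesicle.  Focal vesicles with empty neighborhoods at a
    radius are skipped at that radius (``n_contributing`` records how many
    contributed).  When the section has a single recycled vesicle the
    reference fraction is 0 and the normalized index is NaN; the absolute
    fractions remain defined.
    """
    return _profile_from_arrays(
        section.id, section.centers(), section.recycled_mask(), step, r_max
    )


def population_cluster_test(
    profiles: Sequence[ClusterProfile],
    radii: Optional[np.ndarray] = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-sample t tests of per-synapse clustering indices against 1.

    Profiles are aligned on a common radius grid; a profile evaluated beyond
    its own maximal radius contributes its limiting value 1 (all vesicles
    enclosed).  NaN indices (undefined normalization) are skipped.  Radii
    with fewer than two contributing synapses are reported untestable
    (NaN statistic).

    Returns a DataFrame with columns
    ``radius_nm, n, mean_index, t, p_value, significant``.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    if radii is None:
        step = float(profiles[0].radii[0])
        top = max(p.r_max for p in profiles)
        radii = np.arange(step, top + step / 2, step)
    rows = []
    for r in radii:
        vals = np.array([p.index_at(r) for p in profiles], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2 or np.ptp(vals) == 0:
            # untestable (too few synapses, or a degenerate constant sample)
            mean = float(vals.mean()) if vals.size else np.nan
            rows.append((r, vals.size, mean, np.nan, np.nan, False))
            continue
        t, p = stats.ttest_1samp(vals, 1.0)
        rows.append((r, vals.size, float(vals.mean()), float(t), float(p), bool(p < alpha)))
    return pd.DataFrame(
        rows, columns=["radius_nm", "n", "mean_index", "t", "p_value", "significant"]
    )


def peak_amplitude(
    profile: ClusterProfile, window: Tuple[float, float] = PEAK_WINDOW_NM
) -> PeakClusterAmplitude:
    """Mean clustering index over the peak-cluster window (40-240 nm).

    A profile ending before the window does is averaged over the radii it
    covers and flagged truncated.
    """
    lo, hi = window
    sel = (profile.radii >= lo - 1e-9) & (profile.radii <= hi + 1e-9)
    truncated = profile.r_max < hi
    vals = profile.clustering_index[sel]
    if vals.size == 0 or np.all(np.isnan(vals)):
        return PeakClusterAmplitude(profile.section_id, float("nan"), truncated)
    return PeakClusterAmplitude(
        profile.section_id, float(np.nanmean(vals)), truncated
    )


# ---------------------------------------------------------------------------
# compartments


def assign_compartments(section: SynapseSection) -> Dict[str, str]:
    """Map vesicle id -> compartment name by nearest-AZ distance bands.

    Bands are half-open ``[lower, upper)``; the rear/side band is closed at
    800 nm and vesicles beyond 800 nm are clamped into it with a warning.
    """
    if len(section.active_zones) != 1:
        raise ValueError(f"section {section.id!r}: compartments require a single AZ")
    line = section.active_zones[0].line
    out: Dict[str, str] = {}
    for v in section.vesicles:
        d = Point(v.x, v.y).distance(line)
        name = None
        for cname, lo, hi in COMPARTMENT_BANDS:
            if lo <= d < hi:
                name = cname
                break
        if name is None:
            if d <= COMPARTMENT_BANDS[-1][2]:  # exactly 800
                name = COMPARTMENT_BANDS[-1][0]
            else:
                warnings.warn(
                    f"section {section.id!r}: vesicle {v.id!r} at {d:.1f} nm "
                    "exceeds the 800 nm rear/side band; clamped"
                )
                name = COMPARTMENT_BANDS[-1][0]
        out[v.id] = name
    return out


def compartment_fractions(sections: Sequence[SynapseSection]) -> pd.DataFrame:
    """Per-synapse recycled fractions per compartment plus an ``all`` row.

    Compartments with no vesicles in a synapse contribute no row.  Columns:
    ``section_id, condition, compartment, n, n_recycled, fraction``.
    """
    rows = []
    for s in sections:
        comp = assign_compartments(s)
        groups: Dict[str, List] = {name: [] for name in COMPARTMENT_NAMES}
        for v in s.vesicles:
            groups[comp[v.id]].append(v)
        groups["all"] = list(s.vesicles)
        for name in COMPARTMENT_NAMES + ("all",):
            members = groups[name]
            if not members:
                continue
            n_rec = sum(v.is_recycled for v in members)
            rows.append(
                {
                    "section_id": s.id,
                    "condition": s.condition,
                    "compartment": name,
                    "n": len(members),
                    "n_recycled": n_rec,
                    "fraction": n_rec / len(members),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["section_id", "condition", "compartment", "n", "n_recycled", "fraction"],
    )


def compartment_cluster_profiles(
    section: SynapseSection,
    step: float = DEFAULT_STEP_NM,
) -> Dict[str, ClusterProfile]:
    """Clustering profiles recomputed within each compartment.

    Focal vesicles and neighbors are both restricted to compartment members.
    Compartments with fewer than two vesicles, no recycled vesicle, or an
    undefined normalization (a single recycled member) are omitted.
    """
    comp = assign_compartments(section)
    centers = section.centers()
    recycled = section.recycled_mask()
    ids = [v.id for v in section.vesicles]
    out: Dict[str, ClusterProfile] = {}
    for name in COMPARTMENT_NAMES:
        sel = np.array([comp[i] == name for i in ids], dtype=bool)
        if sel.sum() < 2 or recycled[sel].sum() < 2:
            continue
        out[name] = _profile_from_arrays(
            section.id, centers[sel], recycled[sel], step, None
        )
    return out


def compartment_tests(values: pd.DataFrame, value_col: str = "fraction") -> dict:
    """Condition x compartment comparisons of per-synapse compartment values.

    ``values`` is long-format with columns ``condition``, ``compartment``
    and ``value_col`` (one row per synapse x compartment).  Returns:

    * ``anova`` — two-way ANOVA (type II) table rows as TestResults for the
      condition and compartment main effects and the interaction;
    * ``posthoc`` — per-compartment unpaired t tests between the two
      conditions with Sidak- and Bonferroni-adjusted p values;
    * ``kruskal`` — per-condition one-way Kruskal-Wallis across compartments.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = values.rename(columns={value_col: "value"})[
        ["condition", "compartment", "value"]
    ].dropna()
    conditions = sorted(df["condition"].unique())
    compartments = sorted(df["compartment"].unique())
    if len(conditions) < 2 or len(compartments) < 2:
        raise ValueError(
            f"two-way ANOVA needs >= 2 conditions and >= 2 compartments; "
            f"got conditions={conditions}, compartments={compartments}"
        )
    cell_sizes = df.groupby(["condition", "compartment"]).size()
    for c in conditions:
        for k in compartments:
            if cell_sizes.get((c, k), 0) < 2:
                raise ValueError(
                    f"cell (condition={c!r}, compartment={k!r}) has "
                    f"{cell_sizes.get((c, k), 0)} observations; two-way ANOVA "
                    "requires >= 2 per cell"
                )
    model = smf.ols("value ~ C(condition) * C(compartment)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    anova = {}
    resid_df = float(table.loc["Residual", "df"])
    for key, row_name in (
        ("condition", "C(condition)"),
        ("compartment", "C(compartment)"),
        ("interaction", "C(condition):C(compartment)"),
    ):
        row = table.loc[row_name]
        anova[key] = TestResult(
            test_name=f"anova_{key}",
            statistic=float(row["F"]),
            p_value=float(row["PR(>F)"]),
            dof=(float(row["df"]), resid_df),
        )

    posthoc = {}
    if len(conditions) == 2:
        m = len(compartments)
        a_name, b_name = conditions
        for k in compartments:
            in_k = df["compartment"] == k
            a = df.loc[in_k & (df["condition"] == a_name), "value"]
            b = df.loc[in_k & (df["condition"] == b_name), "value"]
            t, p = stats.ttest_ind(a, b)
            posthoc[k] = {
                "t": float(t),
                "p_raw": float(p),
                "p_sidak": float(min(1.0, -math.expm1(m * math.log1p(-min(p, 1.0 - 1e-16))))),
                "p_bonferroni": float(min(1.0, p * m)),
            }

    kruskal = {}
    for c in conditions:
        in_c = df["condition"] == c
        samples = [
            df.loc[in_c & (df["compartment"] == k), "value"].to_numpy()
            for k in compartments
        ]
        samples = [s for s in samples if s.size > 0]
        if len(samples) >= 2:
            h, p = stats.kruskal(*samples)
            kruskal[c] = TestResult(
                "kruskal_wallis", float(h), float(p), (float(len(samples) - 1),)
            )
    return {"anova": anova, "posthoc": posthoc, "kruskal": kruskal}


# ---------------------------------------------------------------------------
# AZ-associated pool


def az_pool(section: SynapseSection, gap: float = AZ_POOL_GAP_NM) -> AZPoolResult:
    """The AZ-associated pool: first line of vesicles with access to the AZ.

    A vesicle is a member iff its membrane comes within ``gap`` nm of the
    release-site membrane (nearest-AZ center distance minus its radius) and
    the straight segment from its center to its nearest AZ point passes
    through no other vesicle's disc interior (tangency does not occlude).
    """
    if len(section.active_zones) != 1:
        raise ValueError(f"section {section.id!r}: AZ pool requires a single AZ")
    line = section.active_zones[0].line
    vesicles = section.vesicles
    members = []
    for v in vesicles:
        p = Point(v.x, v.y)
        d = p.distance(line)
        if d - v.radius > gap:
            continue
        target = nearest_points(p, line)[1]
        seg = LineString([(v.x, v.y), (target.x, target.y)])
        occluded = False
        for other in vesicles:
            if other.id == v.id:
                continue
            if seg.distance(Point(other.x, other.y)) < other.radius:
                occluded = True
                break
        if not occluded:
            members.append(v)
    if not members:
        return AZPoolResult(section.id, (), None)
    n_rec = sum(v.is_recycled for v in members)
    return AZPoolResult(
        section_id=section.id,
        member_ids=tuple(v.id for v in members),
        recycled_fraction_az=n_rec / len(members),
    )


def az_pool_correlation(sections: Sequence[SynapseSection], gap: float = AZ_POOL_GAP_NM) -> CorrelationResult:
    """Spearman correlation of AZ-pool recycled fraction vs whole-synapse fraction."""
    az_fracs, whole_fracs = [], []
    for s in sections:
        result = az_pool(s, gap=gap)
        if result.recycled_fraction_az is None:
            continue
        az_fracs.append(result.recycled_fraction_az)
        whole_fracs.append(s.n_recycled / s.n_vesicles)
    if len(az_fracs) < 3:
        raise ValueError("need >= 3 sections with a defined AZ-pool fraction")
    return spearman_correlation(az_fracs, whole_fracs)
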