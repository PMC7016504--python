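"""Synthetic synapse-section generator with known ground truth.

Generates 2D cross-sections that emulate the statistical structure of
photoconversion EM data: a vesicle cluster confined to a flattened-ellipse
boundary sitting on a horizontal active zone, hard-core vesicle packing
(random sequential adsorption), a per-synapse recycled fraction drawn from a
Beta law parameterized by (mean, SD), an optional exponential bias of
recycled labels toward the active zone, and optional label contagion
(seed vesicles recruit their k nearest neighbors) to plant local clustering.

Default condition configurations mirror the study groups:

* control — 56 synapses, fraction mean 0.16 / SD 0.10, no AZ bias;
* LTP — 72 synapses, fraction mean 0.30 / SD 0.21, AZ bias lambda 150 nm;
* forskolin — 64 synapses, fraction mean 0.22 / SD 0.14, AZ bias lambda 150 nm.

Everything is reproducible bit-identically from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .model import (
    RECYCLED,
    RESTING,
    ActiveZoneTrace,
    SynapseSection,
    VesicleAnnotation,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic synapse model.

    ``vesicle_count`` and ``fraction`` are (law name, parameter dict) pairs.
    Count laws: ``fixed`` (n), ``uniform`` (low, high), ``lognormal``
    (median, sigma), ``poisson`` (lam); counts are clipped to [10, 100].
    Fraction laws: ``beta_ms`` (mean, sd) or ``fixed`` (p).
    ``az_bias_lambda`` is the exponential decay length (nm) of the recycled
    label bias toward the AZ (``inf`` = unbiased); ``contagion_k`` > 0 turns
    on nearest-neighbor label contagion.
    """

    condition: str = "control"
    n_synapses: int = 56
    vesicle_count: Tuple[str, Dict[str, float]] = (
        "lognormal",
        None,  # filled in __post_init__
    )
    vesicle_radius: float = 20.0
    hard_core_diameter: Optional[float] = None  # default 2 * radius
    boundary_semi_axes: Tuple[float, float] = (400.0, 300.0)
    az_length: float = 200.0
    fraction: Tuple[str, Dict[str, float]] = ("beta_ms", None)
    az_bias_lambda: float = math.inf
    contagion_k: int = 0

    def __post_init__(self) -> None:
        if self.vesicle_count[1] is None:
            object.__setattr__(
                self, "vesicle_count", ("lognormal", {"median": 45.0, "sigma": 0.35})
            )
        if self.fraction[1] is None:
            object.__setattr__(self, "fraction", ("beta_ms", {"mean": 0.16, "sd": 0.10}))
        if self.hard_core_diameter is None:
            object.__setattr__(self, "hard_core_diameter", 2.0 * self.vesicle_radius)
        a, b = self.boundary_semi_axes
        if not (a > 0 and b > 0 and self.az_length > 0 and self.vesicle_radius > 0):
            raise ValueError("all lengths must be > 0")
        if not self.az_bias_lambda > 0:
            raise ValueError("az_bias_lambda must be > 0 (inf = unbiased)")


def control_config(**overrides) -> GeneratorConfig:
    return replace(
        GeneratorConfig(
            condition="control",
            n_synapses=56,
            fraction=("beta_ms", {"mean": 0.16, "sd": 0.10}),
            az_bias_lambda=math.inf,
        ),
        **overrides,
    )


def ltp_config(**overrides) -> GeneratorConfig:
    return replace(
        GeneratorConfig(
            condition="LTP",
            n_synapses=72,
            fraction=("beta_ms", {"mean": 0.30, "sd": 0.21}),
            az_bias_lambda=150.0,
        ),
        **overrides,
    )


def forskolin_config(**overrides) -> GeneratorConfig:
    return replace(
        GeneratorConfig(
            condition="forskolin",
            n_synapses=64,
            fraction=("beta_ms", {"mean": 0.22, "sd": 0.14}),
            az_bias_lambda=150.0,
        ),
        **overrides,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Realized latent values of one generated section."""

    section_id: str
    p: float                 # drawn per-synapse recycled probability
    n_vesicles: int
    n_recycled: int
    az_bias_lambda: float
    contagion_k: int
    seed: int


# ---------------------------------------------------------------------------
# draws


def _draw_count(rng: np.random.Generator, law: str, params: Dict[str, float]) -> int:
    if law == "fixed":
        n = params["n"]
    elif law == "uniform":
        n = rng.integers(int(params["low"]), int(params["high"]) + 1)
    elif law == "lognormal":
        n = round(math.exp(rng.normal(math.log(params["median"]), params["sigma"])))
    elif law == "poisson":
        n = rng.poisson(params["lam"])
    else:
        raise ValueError(f"unknown vesicle count law {law!r}")
    return int(np.clip(n, 10, 100))


def _beta_params(mean: float, sd: float) -> Tuple[float, float]:
    if not 0 < mean < 1:
        raise ValueError("fraction mean must be in (0, 1)")
    v = mean * (1 - mean) / sd**2 - 1.0
    if v <= 0:
        raise ValueError(f"SD {sd} too large for a Beta law with mean {mean}")
    return mean * v, (1 - mean) * v


def _draw_fraction(rng: np.random.Generator, law: str, params: Dict[str, float]) -> float:
    if law == "fixed":
        p = float(params["p"])
    elif law == "beta_ms":
        a, b = _beta_params(params["mean"], params["sd"])
        p = float(rng.beta(a, b))
    else:
        raise ValueError(f"unknown fraction law {law!r}")
    if not 0 <= p <= 1:
        raise ValueError("fraction draw outside [0, 1]")
    return p


# ---------------------------------------------------------------------------
# geometry


def make_boundary(config: GeneratorConfig, n_arc: int = 64) -> Tuple[Tuple[float, float], ...]:
    """Flattened-ellipse cluster boundary polygon resting on the AZ line.

    The ellipse (semi-axes a, b) is centered at (0, 0.6 b) and cut at y = 0,
    so its lower arc is replaced by the flat chord along which the active
    zone lies.
    """
    a, b = config.boundary_semi_axes
    cy = 0.6 * b
    # ellipse: x^2/a^2 + (y-cy)^2/b^2 = 1, keep y >= 0
    t0 = math.asin(-cy / b)  # parameter where the arc crosses y = 0
    ts = np.linspace(t0, math.pi - t0, n_arc)
    xs = a * np.cos(ts)
    ys = cy + b * np.sin(ts)
    pts = list(zip(xs.tolist(), ys.tolist()))
    # close along the flat bottom (polygon closes itself back to the start)
    return tuple(pts)


def _rsa_positions(
    rng: np.random.Generator,
    polygon: Polygon,
    count: int,
    min_sep: float,
) -> np.ndarray:
    """Random sequential adsorption of ``count`` hard cores inside ``polygon``."""
    import shapely

    minx, miny, maxx, maxy = polygon.bounds
    placed = np.empty((0, 2))
    attempts = 0
    max_attempts = 10_000 * count
    batch = max(4 * count, 64)
    while placed.shape[0] < count and attempts < max_attempts:
        m = min(batch, max_attempts - attempts)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        attempts += m
        inside = shapely.intersects_xy(polygon, cand[:, 0], cand[:, 1])
        for c in cand[inside]:
            if placed.shape[0] >= count:
                break
            if placed.shape[0] and (np.hypot(*(placed - c).T) < min_sep).any():
                continue
            placed = np.vstack([placed, c])
    if placed.shape[0] < count:
        if placed.shape[0] < 0.9 * count:
            area = polygon.area
            density = count * math.pi * (min_sep / 2) ** 2 / area
            raise ValueError(
                f"hard-core packing infeasible: placed {placed.shape[0]} of "
                f"{count} vesicles (requested core-area density {density:.2f}; "
                "reduce the count or enlarge the boundary)"
            )
    return placed


def _biased_labels(
    rng: np.random.Generator,
    d_az: np.ndarray,
    p: float,
    lam: float,
) -> np.ndarray:
    """Independent labels with AZ-proximity bias and expected fraction p.

    Per-vesicle recycled probabilities are proportional to exp(-d/lambda),
    rescaled so their mean is p; probabilities capped at 1 with the excess
    redistributed over uncapped vesicles (approximation documented in the
    methods note).
    """
    n = d_az.size
    if math.isinf(lam):
        w = np.ones(n)
    else:
        w = np.exp(-d_az / lam)
    q = p * n * w / w.sum()
    for _ in range(100):
        over = q > 1.0
        if not over.any():
            break
        excess = (q[over] - 1.0).sum()
        q[over] = 1.0
        free = ~over
        if not free.any() or w[free].sum() == 0:
            break
        q[free] += excess * w[free] / w[free].sum()
    q = np.clip(q, 0.0, 1.0)
    return rng.random(n) < q


def _contagion_labels(
    rng: np.random.Generator,
    centers: np.ndarray,
    m: int,
    k: int,
) -> np.ndarray:
    """Exactly ``m`` recycled labels grown as seed + k-nearest-neighbor patches."""
    n = centers.shape[0]
    recycled = np.zeros(n, dtype=bool)
    from scipy.spatial.distance import cdist

    dist = cdist(centers, centers)
    while recycled.sum() < m:
        resting_idx = np.flatnonzero(~recycled)
        seed = int(rng.choice(resting_idx))
        need = m - int(recycled.sum())
        order = np.argsort(dist[seed, resting_idx], kind="stable")
        patch = resting_idx[order[: min(k + 1, need)]]
        recycled[patch] = True
    return recycled


# ---------------------------------------------------------------------------
# section and study generation


def generate_section(
    config: GeneratorConfig, seed: int, section_id: Optional[str] = None
) -> Tuple[SynapseSection, GroundTruth]:
    """Generate one synthetic section and its ground truth."""
    rng = np.random.default_rng(seed)
    if section_id is None:
        section_id = f"{config.condition}-{seed}"
    boundary = make_boundary(config)
    polygon = Polygon(boundary)
    count = _draw_count(rng, *config.vesicle_count)
    p = _draw_fraction(rng, *config.fraction)
    centers = _rsa_positions(rng, polygon, count, config.hard_core_diameter)
    n = centers.shape[0]

    az = ActiveZoneTrace(
        points=((-config.az_length / 2.0, 0.0), (config.az_length / 2.0, 0.0)),
        center=(0.0, 0.0),
    )
    import shapely

    d_az = shapely.distance(shapely.points(centers), az.line)

    if config.contagion_k > 0:
        m = int(rng.binomial(n, p))
        recycled = _contagion_labels(rng, centers, m, config.contagion_k)
    else:
        recycled = _biased_labels(rng, d_az, p, config.az_bias_lambda)

    vesicles = tuple(
        VesicleAnnotation(
            id=f"{section_id}:v{i}",
            x=float(centers[i, 0]),
            y=float(centers[i, 1]),
            label=RECYCLED if recycled[i] else RESTING,
            radius=config.vesicle_radius,
        )
        for i in range(n)
    )
    section = SynapseSection(
        id=section_id,
        condition=config.condition,
        vesicles=vesicles,
        active_zones=(az,),
        boundary=boundary,
        metadata={"pixel_size_nm": 1.0},
    )
    truth = GroundTruth(
        section_id=section_id,
        p=p,
        n_vesicles=n,
        n_recycled=int(recycled.sum()),
        az_bias_lambda=config.az_bias_lambda,
        contagion_k=config.contagion_k,
        seed=seed,
    )
    return section, truth


def generate_group(
    config: GeneratorConfig, master_seed: int, prefix: Optional[str] = None
) -> Tuple[List[SynapseSection], List[GroundTruth]]:
    """Generate ``config.n_synapses`` sections with child seeds from ``master_seed``."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.generate_state(config.n_synapses, dtype=np.uint32)
    prefix = prefix or config.condition
    sections, truths = [], []
    for i, child in enumerate(children):
        sec, gt = generate_section(config, int(child), section_id=f"{prefix}-{i:03d}")
        sections.append(sec)
        truths.append(gt)
    return sections, truths


def generate_study(
    control_config_: GeneratorConfig,
    test_config: GeneratorConfig,
    master_seed: int,
    n_per_group: Optional[Tuple[int, int]] = None,
) -> Tuple[List[SynapseSection], List[SynapseSection], pd.DataFrame]:
    """Generate a two-group study; returns (control, test, ground-truth table)."""
    if n_per_group is not None:
        control_config_ = replace(control_config_, n_synapses=n_per_group[0])
        test_config = replace(test_config, n_synapses=n_per_group[1])
    ss = np.random.SeedSequence(master_seed)
    seed_a, seed_b = (int(s) for s in ss.generate_state(2, dtype=np.uint32))
    control, gt_a = generate_group(control_config_, seed_a)
    test, gt_b = generate_group(test_config, seed_b)
    truth = pd.DataFrame(
        [
            {
                "section_id": g.section_id,
                "condition": c,
                "p": g.p,
                "n_vesicles": g.n_vesicles,
                "n_recycled": g.n_recycled,
                "az_bias_lambda": g.az_bias_lambda,
                "contagion_k": g.contagion_k,
                "seed": g.seed,
            }
            for g, c in [(g, control_config_.condition) for g in gt_a]
            + [(g, test_config.condition) for g in gt_b]
        ]
    )
    return control, test, truth
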