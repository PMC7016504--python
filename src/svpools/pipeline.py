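"""Orchestration: simulate -> filter -> analyze -> compare -> report.

Each stage reads and writes the plain-text formats defined in :mod:`svpools.io`
(CSV tables + JSON sidecars) and records a manifest with versions, seed,
config hash, and per-stage row counts so runs are fully reproducible: two
runs with equal manifests produce equal outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .model import RECYCLED, RESTING, FilterReason, SynapseSection
from .io import (
    MAX_VESICLES_PER_SECTION,
    MIN_POOL_FRACTION,
    apply_inclusion_filters,
    read_sections,
    write_sections,
)
from .pool_metrics import (
    GroupSummary,
    classify_potentiated,
    compare_groups,
    corrected_fraction_correlation,
    group_summary,
    high_fraction_matched_subset,
    potentiated_threshold,
    quartile_bin_means,
    recycled_fraction,
    spearman_correlation,
    top_fraction_subset,
)
from .spatial import (
    compare_distances,
    distance_records,
    mean_density_map,
    orient_section,
)
from .clustering import (
    AZ_POOL_GAP_NM,
    DEFAULT_STEP_NM,
    PEAK_WINDOW_NM,
    az_pool,
    az_pool_correlation,
    clustering_profile,
    compartment_fractions,
    compartment_tests,
    peak_amplitude,
    population_cluster_test,
)
from .synthetic import (
    GeneratorConfig,
    control_config,
    forskolin_config,
    generate_group,
    ltp_config,
)

CONDITION_CONFIGS = {
    "control": control_config,
    "LTP": ltp_config,
    "forskolin": forskolin_config,
}


@dataclass(frozen=True)
class RunConfig:
    """Resolved analysis parameters; defaults follow the study conventions."""

    min_fraction: float = MIN_POOL_FRACTION
    max_vesicles: int = MAX_VESICLES_PER_SECTION
    require_single_az: bool = True
    step_nm: float = DEFAULT_STEP_NM
    az_gap_nm: float = AZ_POOL_GAP_NM
    peak_window_nm: Tuple[float, float] = PEAK_WINDOW_NM
    smooth_sigma: float = 1.0
    alpha_cluster: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(out_dir: Path, config: RunConfig, counts: Dict[str, int], warnings_: Sequence[str] = ()) -> dict:
    manifest = {
        "svpools_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.hash,
        "row_counts": counts,
        "warnings": list(warnings_),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)
    return manifest


# ---------------------------------------------------------------------------
# simulate


def simulate(condition: str, out_dir, seed: int, n_synapses: Optional[int] = None,
             config: Optional[GeneratorConfig] = None) -> List[SynapseSection]:
    """Generate a synthetic dataset for one condition and write it to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        if condition not in CONDITION_CONFIGS:
            raise ValueError(
                f"unknown condition {condition!r}; choose from {sorted(CONDITION_CONFIGS)}"
            )
        config = CONDITION_CONFIGS[condition]()
    if n_synapses is not None:
        config = dataclasses.replace(config, n_synapses=n_synapses)
    sections, truths = generate_group(config, seed)
    write_sections(sections, out_dir / "vesicles.csv", out_dir / "sections.json")
    pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(
        out_dir / "ground_truth.csv", index=False
    )
    run = RunConfig(seed=seed)
    write_manifest(out_dir, run, {"sections": len(sections),
                                  "vesicles": sum(s.n_vesicles for s in sections)})
    return sections


# ---------------------------------------------------------------------------
# analyze


def analyze_sections(sections: Sequence[SynapseSection], config: RunConfig) -> dict:
    """Full per-synapse analysis of one dataset.

    Applies the inclusion filters, orients the surviving sections, and
    computes fractions, nearest-AZ distances, clustering profiles, peak
    amplitudes, compartment fractions, AZ-pool composition, and mean density
    maps.  Returns a dict of DataFrames / arrays.
    """
    report = apply_inclusion_filters(
        sections,
        min_fraction=config.min_fraction,
        max_vesicles=config.max_vesicles,
        require_single_az=config.require_single_az,
    )
    keep = set(report.included)
    kept = [s for s in sections if s.id in keep]
    if not kept:
        raise ValueError("inclusion filters eliminated every section")
    oriented = [orient_section(s).section for s in kept]

    reasons = {sid: reason.value for sid, reason in report.excluded}
    fractions = pd.DataFrame(
        [
            {
                "section_id": s.id,
                "condition": s.condition,
                "n_vesicles": s.n_vesicles,
                "n_recycled": s.n_recycled,
                "fraction": (s.n_recycled / s.n_vesicles) if s.n_vesicles else np.nan,
                "included": s.id in keep,
                "exclusion_reason": reasons.get(s.id, ""),
            }
            for s in sections
        ]
    )

    distances = distance_records(oriented)

    profile_rows = []
    amp_rows = []
    profiles = []
    for s in oriented:
        prof = clustering_profile(s, step=config.step_nm)
        profiles.append(prof)
        for r, a, c, nc in zip(
            prof.radii, prof.absolute_fraction, prof.clustering_index, prof.n_contributing
        ):
            profile_rows.append(
                {
                    "section_id": s.id,
                    "radius_nm": float(r),
                    "absolute_fraction": float(a),
                    "clustering_index": float(c),
                    "n_contributing": int(nc),
                }
            )
        amp = peak_amplitude(prof, window=config.peak_window_nm)
        amp_rows.append(
            {
                "section_id": s.id,
                "condition": s.condition,
                "peak_amplitude": amp.amplitude,
                "truncated": amp.truncated,
            }
        )
    profiles_df = pd.DataFrame(
        profile_rows,
        columns=["section_id", "radius_nm", "absolute_fraction",
                 "clustering_index", "n_contributing"],
    )
    amplitudes = pd.DataFrame(
        amp_rows, columns=["section_id", "condition", "peak_amplitude", "truncated"]
    )

    compartments = compartment_fractions(oriented)

    az_rows = []
    for s in oriented:
        res = az_pool(s, gap=config.az_gap_nm)
        az_rows.append(
            {
                "section_id": s.id,
                "condition": s.condition,
                "n_members": len(res.member_ids),
                "fraction_az": res.recycled_fraction_az
                if res.recycled_fraction_az is not None
                else np.nan,
            }
        )
    az_df = pd.DataFrame(az_rows, columns=["section_id", "condition", "n_members", "fraction_az"])

    density = {}
    for pool in (RECYCLED, RESTING):
        try:
            density[pool] = mean_density_map(oriented, pool, config.smooth_sigma).grid
        except ValueError:
            density[pool] = None

    return {
        "filter_report": report,
        "sections": kept,
        "oriented": oriented,
        "fractions": fractions,
        "distances": distances,
        "profiles": profiles,
        "profiles_df": profiles_df,
        "amplitudes": amplitudes,
        "compartments": compartments,
        "az_pool": az_df,
        "density": density,
    }


def analyze(dataset_dir, out_dir, config: Optional[RunConfig] = None) -> dict:
    """Read a dataset directory, analyze it, and write the result tables."""
    dataset_dir = Path(dataset_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    sections = read_sections(dataset_dir / "vesicles.csv", dataset_dir / "sections.json")
    result = analyze_sections(sections, config)
    result["fractions"].to_csv(out_dir / "fractions.csv", index=False)
    result["distances"].to_csv(out_dir / "distances.csv", index=False)
    result["profiles_df"].to_csv(out_dir / "profiles.csv", index=False)
    result["amplitudes"].to_csv(out_dir / "amplitudes.csv", index=False)
    result["compartments"].to_csv(out_dir / "compartments.csv", index=False)
    result["az_pool"].to_csv(out_dir / "az_pool.csv", index=False)
    for pool, grid in result["density"].items():
        if grid is not None:
            np.savetxt(out_dir / f"density_{pool}.csv", grid, delimiter=",")
    counts = {
        "sections_in": len(sections),
        "sections_included": len(result["sections"]),
        "vesicles": int(result["distances"].shape[0]),
    }
    write_manifest(out_dir, config, counts)
    return result


# ---------------------------------------------------------------------------
# compare


def _load_analyzed(analyzed_dir: Path) -> dict:
    analyzed_dir = Path(analyzed_dir)
    out = {}
    for name in ("fractions", "distances", "profiles", "amplitudes", "compartments", "az_pool"):
        path = analyzed_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"{path} missing: run the analyze stage before compare"
            )
        out[name] = pd.read_csv(path)
    return out


def compare_analyzed(a: dict, b: dict, config: Optional[RunConfig] = None) -> dict:
    """All group-level statistics between two analyzed datasets.

    ``a`` is treated as the reference (control-like) group: the potentiated
    threshold and the trend line of the size-corrected correlation are
    derived from it.
    """
    config = config or RunConfig()
    fa = a["fractions"].query("included")
    fb = b["fractions"].query("included")
    fr_a = fa["fraction"].to_numpy()
    fr_b = fb["fraction"].to_numpy()
    sum_a = group_summary(fr_a)
    sum_b = group_summary(fr_b)
    threshold = potentiated_threshold(sum_a)
    _, prop_b = classify_potentiated(fr_b, threshold)

    tests = compare_groups(fr_a, fr_b)

    corr = {}
    for name, f in (("a", fa), ("b", fb)):
        corr[f"size_vs_count_{name}"] = spearman_correlation(
            f["n_vesicles"], f["n_recycled"]
        )
        corr[f"fraction_vs_count_{name}"] = spearman_correlation(
            f["n_vesicles"], f["fraction"]
        )
    # residual correlation for group b after removing group a's size trend
    slope, intercept = np.polyfit(fa["n_vesicles"], fa["fraction"], 1)
    resid = fb["fraction"] - (slope * fb["n_vesicles"] + intercept)
    corr["fraction_vs_count_b_corrected"] = spearman_correlation(fb["n_vesicles"], resid)

    quart = {
        "a": quartile_bin_means(fr_a),
        "b": quartile_bin_means(fr_b),
        "top25_a": top_fraction_subset(fr_a),
        "top25_b": top_fraction_subset(fr_b),
    }
    matched_idx, matched_summary = high_fraction_matched_subset(fr_a, float(np.mean(fr_b)))

    dist = {}
    for name, d in (("a", a["distances"]), ("b", b["distances"])):
        groups = {
            label: d.loc[d["label"] == label, "d_az_nm"].to_numpy()
            for label in (RECYCLED, RESTING)
        }
        if all(v.size >= 2 for v in groups.values()):
            dist[name] = compare_distances(groups)[(RECYCLED, RESTING)]

    prof_tests = {}
    for name, src in (
        ("a", a.get("profiles_df", a["profiles"])),
        ("b", b.get("profiles_df", b["profiles"])),
    ):
        prof_tests[name] = _population_test_from_long(src, alpha=config.alpha_cluster)

    amp_a = a["amplitudes"]["peak_amplitude"].dropna().to_numpy()
    amp_b = b["amplitudes"]["peak_amplitude"].dropna().to_numpy()
    amp_test = compare_groups(amp_a, amp_b)["t_test"] if (
        amp_a.size >= 2 and amp_b.size >= 2
    ) else None

    comp = pd.concat([a["compartments"], b["compartments"]], ignore_index=True)
    comp = comp[comp["compartment"] != "all"]
    try:
        comp_tests = compartment_tests(comp, value_col="fraction")
    except ValueError as exc:
        comp_tests = {"error": str(exc)}

    azp = {}
    for name, src in (("a", a["az_pool"]), ("b", b["az_pool"])):
        vals = src["fraction_az"].dropna().to_numpy()
        if vals.size >= 2:
            azp[f"summary_{name}"] = group_summary(vals)
    az_a = a["az_pool"]["fraction_az"].dropna().to_numpy()
    az_b = b["az_pool"]["fraction_az"].dropna().to_numpy()
    if az_a.size >= 2 and az_b.size >= 2:
        azp["t_test"] = compare_groups(az_a, az_b)["t_test"]
    for name, src, f in (("a", a["az_pool"], a["fractions"]), ("b", b["az_pool"], b["fractions"])):
        merged = src.merge(f[["section_id", "fraction"]], on="section_id").dropna(
            subset=["fraction_az"]
        )
        if merged.shape[0] >= 3:
            try:
                azp[f"correlation_{name}"] = spearman_correlation(
                    merged["fraction_az"], merged["fraction"]
                )
            except ValueError:
                pass

    return {
        "group_summaries": {"a": sum_a, "b": sum_b},
        "potentiated": {"threshold": threshold, "proportion_b_above": prop_b},
        "fraction_tests": tests,
        "correlations": corr,
        "quartiles": quart,
        "matched_subset": {"k": int(matched_idx.size), "summary": matched_summary},
        "distance_tests": dist,
        "cluster_tests": {k: v.to_dict(orient="records") for k, v in prof_tests.items()},
        "amplitude_test": amp_test,
        "compartment_tests": comp_tests,
        "az_pool": azp,
    }


def _population_test_from_long(profiles_long: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Rebuild ClusterProfiles from the long table and run the per-radius test."""
    from .clustering import ClusterProfile

    profs = []
    for sid, g in profiles_long.groupby("section_id"):
        g = g.sort_values("radius_nm")
        profs.append(
            ClusterProfile(
                section_id=str(sid),
                radii=g["radius_nm"].to_numpy(),
                absolute_fraction=g["absolute_fraction"].to_numpy(),
                clustering_index=g["clustering_index"].to_numpy(),
                n_contributing=g["n_contributing"].to_numpy(),
                reference_fraction=np.nan,
            )
        )
    return population_cluster_test(profs, alpha=alpha)


def compare(analyzed_dir_a, analyzed_dir_b, out_dir, config: Optional[RunConfig] = None) -> dict:
    """Compare two analyzed dataset directories and write compare.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    a = _load_analyzed(analyzed_dir_a)
    b = _load_analyzed(analyzed_dir_b)
    result = compare_analyzed(a, b, config)
    with open(out_dir / "compare.json", "w") as fh:
        json.dump(result, fh, indent=1, default=_json_default)
    write_manifest(out_dir, config, {"groups": 2})
    return result


# ---------------------------------------------------------------------------
# report


def report(compare_dir, out_dir) -> str:
    """Render a plain-text summary (plus CSV extracts) of a compare run."""
    compare_dir = Path(compare_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(compare_dir / "compare.json") as fh:
        cmp_ = json.load(fh)
    lines = ["svpools comparison report", "=" * 30]
    for grp in ("a", "b"):
        s = cmp_["group_summaries"][grp]
        lines.append(
            f"group {grp}: n={s['n']}  fraction mean={s['mean']:.3f} "
            f"+/- {s['sem']:.3f} (SEM), SD={s['sd']:.3f}"
        )
    pot = cmp_["potentiated"]
    lines.append(
        f"potentiated threshold (mean_a + 2 SD_a) = {pot['threshold']:.3f}; "
        f"proportion of group b above = {pot['proportion_b_above']:.3f}"
    )
    t = cmp_["fraction_tests"]["t_test"]
    f = cmp_["fraction_tests"]["f_test"]
    lines.append(f"fraction t test: t={t['statistic']:.3f}, p={t['p_value']:.4g}")
    lines.append(f"variance F test: F={f['statistic']:.3f}, p={f['p_value']:.4g}")
    for key, c in cmp_["correlations"].items():
        lines.append(f"Spearman {key}: rho={c['rho']:.3f}, p={c['p_value']:.4g}, n={c['n']}")
    if cmp_.get("amplitude_test"):
        at = cmp_["amplitude_test"]
        lines.append(
            f"peak cluster amplitude t test: t={at['statistic']:.3f}, p={at['p_value']:.4g}"
        )
    az = cmp_.get("az_pool", {})
    for grp in ("a", "b"):
        key = f"summary_{grp}"
        if key in az:
            s = az[key]
            lines.append(
                f"AZ pool fraction, group {grp}: {s['mean']:.3f} +/- {s['sem']:.3f} (n={s['n']})"
            )
    text = "\n".join(lines) + "\n"
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(text)
    rows = []
    for grp in ("a", "b"):
        for i, b_ in enumerate(cmp_["quartiles"][grp]["bins"]):
            rows.append({"group": grp, "bin": i + 1, **b_})
    pd.DataFrame(rows).to_csv(out_dir / "quartile_bins.csv", index=False)
    return text
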