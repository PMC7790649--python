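"""End-to-end pipeline: data in, pattern/release/stand tables out.

Runs the full reconstruction in the order the method prescribes: build
20-segment profiles, cluster and name growth patterns, compute %GC release
chronologies and their peaks, classify canopy layers, summarize stands, and
test pattern-layer association.  Everything is a pure function of
(inputs, config, seed); outputs are CSV tables plus a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import attribute_group_test, pattern_association_test
from .clustering import LabelThresholds, name_patterns, select_pattern_count
from .releases import (
    ReleaseThresholds,
    detect_release_peaks,
    loess_smooth,
    pattern_section_frequencies,
    percent_growth_change,
    site_change_chronology,
)
from .ringio import (
    PlotInventory,
    RingSeries,
    read_inventory_csv,
    read_rings_csv,
    read_rwl,
    read_saplings_csv,
    write_rings_csv,
)
from .segmentation import (
    growth_attributes,
    profiles_to_frame,
    segment_series,
    standardize_segment_matrix,
)
from .stand_structure import assign_cohorts, assign_layers, dominant_height, stand_summary
from .synthetic_data import SimulationConfig, build_outbreak_schedule, simulate_dataset

log = logging.getLogger("dendropatterns")

__all__ = ["PipelineConfig", "run_pipeline"]


def _write_figures(out, sel, matrix, part, chron_tables, cfg):
    """SSI curve, pattern centers and site release chronologies as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(sel.curve["k"], sel.curve["ssi"], "o-", ms=4)
    best = sel.curve.loc[sel.curve["k"] == sel.k_best]
    ax.plot(best["k"], best["ssi"], "ro", ms=7)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("SSI")
    fig.tight_layout()
    fig.savefig(out / "ssi_curve.png", dpi=150)
    plt.close(fig)

    centers_mm = matrix.destandardize_centers(part.centers)
    ncol = 3
    nrow = -(-part.k // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), sharex=True)
    for c, ax in zip(range(part.k), axes.ravel()):
        ax.plot(range(1, centers_mm.shape[1] + 1), centers_mm[c], "-o", ms=3)
        ax.set_title(part.label_name(c), fontsize=9)
    for ax in axes.ravel()[part.k :]:
        ax.set_visible(False)
    fig.supxlabel("segment")
    fig.supylabel("mean ring width (mm)")
    fig.tight_layout()
    fig.savefig(out / "pattern_centers.png", dpi=150)
    plt.close(fig)

    chron = pd.concat(chron_tables, ignore_index=True)
    sites = chron["site_id"].unique()
    fig, axes = plt.subplots(len(sites), 1, figsize=(7, 1.8 * len(sites)),
                             sharex=True, squeeze=False)
    for site, ax in zip(sites, axes.ravel()):
        sub = chron[chron["site_id"] == site]
        years = sub["year"].to_numpy(dtype=float)
        for col, color in (("pct_all_releases", "tab:blue"),
                           ("pct_all_suppressions", "tab:red")):
            y = sub[col].to_numpy()
            ax.plot(years, y, ".", color=color, ms=2, alpha=0.4)
            if years.size >= 4:
                ax.plot(years, loess_smooth(years, y, span=cfg.span), "-", color=color)
        ax.set_ylabel(site, fontsize=8)
    axes.ravel()[-1].set_xlabel("year")
    fig.tight_layout()
    fig.savefig(out / "chronologies.png", dpi=150)
    plt.close(fig)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run."""

    out_dir: str = "dendropatterns_out"
    # inputs: either paths ...
    rings_path: str | None = None  # .rwl or long-form .csv
    inventory_path: str | None = None
    saplings_path: str | None = None
    # ... or simulation
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_plots: int = 8
    outbreak_periods: list[tuple[int, int]] | None = None

    n_segments: int = 20
    k_min: int = 2
    k_max: int = 12
    n_restarts: int = 1000
    thresholds: ReleaseThresholds = field(default_factory=ReleaseThresholds)
    span: float = 0.5
    peak_min_height: float = 5.0
    peak_min_separation: int = 15
    peak_span: float = 0.15
    label_thresholds: LabelThresholds = field(default_factory=LabelThresholds)
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int | None = None
    make_plots: bool = False


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[list[PlotInventory], list[RingSeries], pd.DataFrame | None]:
    if cfg.simulate:
        schedule = build_outbreak_schedule(cfg.outbreak_periods)
        return simulate_dataset(cfg.sim, schedule, seed=cfg.seed, n_plots=cfg.n_plots)
    if cfg.rings_path is None or cfg.inventory_path is None:
        raise FileNotFoundError("rings_path and inventory_path required unless simulating")
    for p in (cfg.rings_path, cfg.inventory_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    rings = (
        read_rwl(cfg.rings_path)
        if str(cfg.rings_path).endswith(".rwl")
        else read_rings_csv(cfg.rings_path)
    )
    saplings = read_saplings_csv(cfg.saplings_path) if cfg.saplings_path else None
    plots = read_inventory_csv(cfg.inventory_path, saplings)
    return plots, rings, None


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write tables under ``cfg.out_dir``; returns it."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage: load inputs")
    plots, rings, truth = _load_inputs(cfg)
    if cfg.simulate:
        write_rings_csv(rings, out / "rings.csv")
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)

    log.info("stage: segmentation")
    usable = [s for s in rings if len(s) >= cfg.n_segments]
    skipped = len(rings) - len(usable)
    if skipped:
        warnings.warn(f"{skipped} series shorter than {cfg.n_segments} rings skipped")
    profiles = [segment_series(s, cfg.n_segments) for s in usable]
    profiles_to_frame(profiles).to_csv(out / "segment_profiles.csv", index=False)
    matrix = standardize_segment_matrix(profiles)

    log.info("stage: clustering")
    sel = select_pattern_count(
        matrix,
        range(cfg.k_min, cfg.k_max + 1),
        n_restarts=cfg.n_restarts,
        seed=cfg.seed,
    )
    sel.curve.to_csv(out / "ssi_curve.csv", index=False)
    part = name_patterns(sel.best, matrix, cfg.label_thresholds)
    part.to_frame().to_csv(out / "pattern_assignments.csv", index=False)
    centers = pd.DataFrame(
        matrix.destandardize_centers(part.centers),
        columns=[f"segment_{i + 1}" for i in range(matrix.n_segments)],
    )
    centers.insert(0, "cluster", range(part.k))
    centers.insert(1, "pattern", [part.label_name(c) for c in range(part.k)])
    centers.to_csv(out / "pattern_centers.csv", index=False)

    log.info("stage: growth change")
    w2 = 2 * cfg.thresholds.window
    gc_series = [percent_growth_change(s, cfg.thresholds) for s in usable if len(s) >= w2]
    pd.concat([g.to_frame() for g in gc_series], ignore_index=True).to_csv(
        out / "growth_change.csv", index=False
    )

    log.info("stage: chronologies and peaks")
    by_site: dict[str, list] = {}
    site_of = {s.tree_id: (s.site_id or "all") for s in usable}
    for g in gc_series:
        by_site.setdefault(site_of[g.tree_id], []).append(g)
    chron_tables, peak_rows = [], []
    for site, trees in sorted(by_site.items()):
        chron = site_change_chronology(trees, site_id=site, span=cfg.span)
        tab = chron.table.copy()
        tab.insert(0, "site_id", site)
        chron_tables.append(tab)
        for pk in detect_release_peaks(
            chron,
            min_height=cfg.peak_min_height,
            min_separation=cfg.peak_min_separation,
            span=cfg.peak_span,
        ):
            peak_rows.append(
                {
                    "site_id": site,
                    "peak_year": pk.year,
                    "start_year": pk.start_year,
                    "end_year": pk.end_year,
                    "height_pct": pk.height,
                }
            )
    pd.concat(chron_tables, ignore_index=True).to_csv(out / "chronologies.csv", index=False)
    pd.DataFrame(peak_rows).to_csv(out / "release_peaks.csv", index=False)

    log.info("stage: pattern x section frequencies")
    gc_ids = {g.tree_id for g in gc_series}
    pattern_section_frequencies(
        gc_series, [p for p in profiles if p.tree_id in gc_ids], part
    ).to_csv(out / "pattern_section_frequencies.csv", index=False)

    log.info("stage: stand structure")
    ages = {s.tree_id: len(s) for s in usable}
    break_age = cfg.sim.end_year - cfg.sim.primary_disturbance_year + 1
    layer_tables, summary_frames = [], []
    for plot in plots:
        dh = dominant_height(plot)
        layers = assign_layers(plot, dh)
        layers.insert(0, "plot_id", plot.plot_id)
        layer_tables.append(layers)
        plot_ages = {t: ages[t] for t in layers["tree_id"] if t in ages}
        cohorts = assign_cohorts(plot_ages, [break_age]) if plot_ages else None
        # trees without ring data fall in the youngest cohort for CBAP
        if cohorts is not None:
            for t in plot.living["tree_id"]:
                cohorts.setdefault(t, 2)
        summary_frames.append(
            stand_summary(plot, ages=plot_ages or None, cohorts=cohorts).to_frame()
        )
    layer_table = pd.concat(layer_tables, ignore_index=True)
    layer_table.to_csv(out / "canopy_layers.csv", index=False)
    pd.concat(summary_frames, ignore_index=True).to_csv(
        out / "stand_summaries.csv", index=False
    )

    log.info("stage: association tests")
    patterns = part.pattern_of()
    layer_of = dict(zip(layer_table["tree_id"], layer_table["canopy_layer"]))
    shared = [t for t in patterns if t in layer_of]
    stats_out: dict[str, object] = {}
    if shared:
        tab = pd.crosstab(
            pd.Series([patterns[t] for t in shared], name="pattern"),
            pd.Series([layer_of[t] for t in shared], name="layer"),
        )
        tab.to_csv(out / "pattern_layer_table.csv")
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            res = pattern_association_test(
                tab, n_permutations=cfg.n_permutations, seed=cfg.seed
            )
            stats_out["pattern_layer"] = {
                "chi2": res.statistic,
                "p_value": res.p_value,
                "dof": res.dof,
                "n_permutations": res.n_permutations,
            }
    attrs = pd.DataFrame(
        [dataclasses.asdict(growth_attributes(s)) for s in usable if len(s) >= 2]
    )
    attrs["pattern"] = attrs["tree_id"].map(patterns)
    attrs["site_id"] = attrs["tree_id"].map(site_of)
    attrs.to_csv(out / "growth_attributes.csv", index=False)
    for col in ("age", "mean_rw"):
        try:
            res = attribute_group_test(
                attrs[col],
                attrs["pattern"],
                strata=attrs["site_id"],
                n_permutations=min(cfg.n_permutations, 499),
                seed=cfg.seed,
                alpha=cfg.alpha,
            )
            stats_out[f"attribute_{col}"] = {
                "F": None if np.isnan(res.statistic) else res.statistic,
                "p_value": res.p_value,
                "letters": res.letters,
            }
        except ValueError as exc:
            stats_out[f"attribute_{col}"] = {"error": str(exc)}
    (out / "association_tests.json").write_text(
        json.dumps(stats_out, indent=2, sort_keys=True) + "\n"
    )

    if cfg.make_plots:
        log.info("stage: figures")
        _write_figures(out, sel, matrix, part, chron_tables, cfg)

    manifest = {
        "package": "dendropatterns",
        "version": __version__,
        "seed": cfg.seed,
        "k_selected": sel.k_best,
        "k_selection_low_confidence": sel.low_confidence,
        "n_trees": len(usable),
        "n_plots": len(plots),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %s", out)
    return out
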