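"""One-command per-site analysis orchestration.

Reproduces the full per-site analysis suite on any stem map (measured or
synthetic): large-scale homogeneity screen (L and g of established trees
against CSR) that selects homogeneous vs inhomogeneous PCFs, univariate
size-class PCFs against their Poisson null, bivariate size-class
independence (toroidal shifts, both directions) and live/snag random
labelling, crown assignment, patch/single/gap delineation with attribute
tables, patch typology (PCA + Ward + per-variable ANOVA), and optional
composite fire-return-interval statistics.

Every stage draws from a named random stream derived from the master
seed, all numeric output is written at fixed precision, and a manifest
records the configuration, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fire as fire_mod
from .allometry import CrownModel, SiteGeography, assign_crowns
from .core import SizeClassScheme, StemMap, read_firescars, read_stemmap
from .groupstats import (cluster_patch_types, compare_groups_anova,
                         patch_features, pca_patch_structure)
from .mosaic import (delineate_gaps, delineate_patches, summarize_gaps,
                     summarize_mosaic)
from .pointpattern import RGrid, envelope, estimate_intensity
from .synthetic import stream

log = logging.getLogger("icomosaic")

__all__ = ["AnalysisConfig", "run_site_analysis"]

FLOAT_FMT = "%.8g"


@dataclass
class AnalysisConfig:
    """Everything a site analysis needs besides the stem map itself."""

    geography: SiteGeography | None = None
    size_classes: SizeClassScheme = field(default_factory=SizeClassScheme)
    r_max: float = 50.0
    r_step: float = 0.5
    n_sim: int = 199
    rank: int = 5
    gap_threshold: float = 2.0
    spur_threshold: float = 12.0
    gap_cell: float = 0.25
    edge_gap_mode: str = "perimeter"
    edge_gap_limit: float = 0.10
    cluster_k: int | None = None  # None = automatic 3..6
    pcf_mode: str = "auto"  # auto | homogeneous | inhomogeneous
    screen_alpha: float = 0.05
    fixed_n_envelopes: bool = False
    fri_periods: tuple[tuple[int, int], ...] = ()
    fri_fraction_inclusive: bool = False
    seed: int = 0

    def grid(self) -> RGrid:
        return RGrid(np.arange(self.r_step, self.r_max + 1e-9, self.r_step))


def _env_frame(env) -> pd.DataFrame:
    return pd.DataFrame({
        "r": env.grid.r, "ghat": env.observed, "lo": env.lo, "hi": env.hi,
    })


def _plot_env(env, title: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(env.grid.r, env.lo, env.hi, color="0.8",
                    label="null envelope")
    ax.plot(env.grid.r, env.observed, "k-", label="observed")
    ref = 1.0 if env.statistic == "pcf" else None
    if env.statistic == "pcf":
        ax.axhline(1.0, color="0.5", lw=0.5)
        ax.set_ylabel("g(r)")
    else:
        ax.plot(env.grid.r, env.grid.r, color="0.5", lw=0.5)
        ax.set_ylabel("L(r)")
    ax.set_xlabel("r (m)")
    ax.set_title(f"{title}  (GoF p = {env.gof.p:.3f})", fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_site_analysis(
    stemmap: StemMap | str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "icomosaic_run",
    crown_model: CrownModel | None = None,
    firescars: str | Path | None = None,
    plots: bool = True,
) -> dict:
    """Execute the full analysis suite; returns the report bundle dict.

    Artifacts (tidy CSVs per envelope analysis, attribute tables, a JSON
    manifest with seeds and GoF results, diagnostic plots) are written
    under ``out_dir``.  Stage failures raise with the stage name; partial
    outputs written so far are retained.
    """
    config = config or AnalysisConfig()
    if not isinstance(stemmap, StemMap):
        stemmap = read_stemmap(stemmap)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    window = stemmap.window
    bundle: dict = {"site": stemmap.site_label, "n_trees": len(stemmap)}
    manifest: dict = {
        "site": stemmap.site_label,
        "config": {
            k: (v if isinstance(v, (int, float, str, bool, type(None), tuple, list))
                else str(v))
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    def _stage(name: str):
        t0 = time.time()
        log.info("stage %s: start", name)

        def _done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 3), **info}
            log.info("stage %s: done (%.1fs)", name, time.time() - t0)

        return _done

    live = stemmap.live()

    # -- stage 1: homogeneity screen on established trees (DBH > 25 cm) ----
    done = _stage("homogeneity_screen")
    try:
        est = live.subset([t.dbh > 25.0 for t in live.trees])
        screen = {}
        if len(est) >= 10:
            for statistic in ("l", "pcf"):
                env = envelope(
                    est, window, "csr", statistic=statistic, grid=grid,
                    n_sim=config.n_sim, rank=config.rank,
                    fixed_n=config.fixed_n_envelopes,
                    seed=stream(config.seed, f"screen_{statistic}"),
                )
                screen[statistic] = env
                _env_frame(env).to_csv(out / f"screen_{statistic}.csv",
                                       index=False, float_format=FLOAT_FMT)
                if plots:
                    _plot_env(env, f"homogeneity screen ({statistic})",
                              out / f"screen_{statistic}.png")
            # L (cumulative) is the sensitive statistic for large-scale
            # trend; reject homogeneity if either test does
            heterogeneous = min(v.gof.p for v in screen.values()) \
                < config.screen_alpha
        else:
            heterogeneous = False
        if config.pcf_mode == "auto":
            mode = "inhomogeneous" if heterogeneous else "homogeneous"
        else:
            mode = config.pcf_mode
        bundle["screen"] = screen
        bundle["pcf_mode"] = mode
        done(mode=mode,
             gof_p={k: v.gof.p for k, v in screen.items()})
    except Exception as exc:
        raise RuntimeError(f"stage homogeneity_screen failed: {exc}") from exc

    null_uni = "inhom_poisson" if mode == "inhomogeneous" else "csr"

    # -- stage 2: univariate PCFs by size class ----------------------------
    done = _stage("univariate_pcf")
    try:
        classes = config.size_classes.classify([t.dbh for t in live.trees]) \
            if len(live) else np.array([], dtype=object)
        uni = {}
        for label in config.size_classes.labels:
            sub = live.subset(classes == label)
            if len(sub) < 10:
                log.info("size class %s: only %d trees, skipped", label, len(sub))
                continue
            env = envelope(
                sub, window, null_uni, statistic="pcf", grid=grid,
                n_sim=config.n_sim, rank=config.rank,
                fixed_n=config.fixed_n_envelopes,
                seed=stream(config.seed, f"uni_{label}"),
            )
            uni[label] = env
            _env_frame(env).to_csv(out / f"pcf_uni_{label}.csv", index=False,
                                   float_format=FLOAT_FMT)
            if plots:
                _plot_env(env, f"univariate PCF, {label}",
                          out / f"pcf_uni_{label}.png")
        bundle["univariate"] = uni
        done(gof_p={k: v.gof.p for k, v in uni.items()})
    except Exception as exc:
        raise RuntimeError(f"stage univariate_pcf failed: {exc}") from exc

    # -- stage 3: bivariate size-class independence (toroidal shifts) ------
    done = _stage("bivariate_pcf")
    try:
        biv = {}
        labels = [lbl for lbl in config.size_classes.labels]
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                sa = live.subset(classes == la)
                sb = live.subset(classes == lb)
                if len(sa) < 10 or len(sb) < 10:
                    continue
                for direction, (s1, s2) in {
                    f"{la}_vs_{lb}": (sa, sb),
                    f"{lb}_vs_{la}": (sb, sa),
                }.items():
                    env = envelope(
                        s1, window, "toroidal_independence", points2=s2,
                        statistic="pcf", grid=grid, n_sim=config.n_sim,
                        rank=config.rank,
                        seed=stream(config.seed, f"biv_{direction}"),
                    )
                    biv[direction] = env
                    _env_frame(env).to_csv(out / f"pcf_biv_{direction}.csv",
                                           index=False, float_format=FLOAT_FMT)
                    if plots:
                        _plot_env(env, f"bivariate PCF {direction}",
                                  out / f"pcf_biv_{direction}.png")
        bundle["bivariate"] = biv
        done(gof_p={k: v.gof.p for k, v in biv.items()})
    except Exception as exc:
        raise RuntimeError(f"stage bivariate_pcf failed: {exc}") from exc

    # -- stage 4: live/snag random labelling -------------------------------
    done = _stage("snag_random_labeling")
    try:
        snags = stemmap.snags()
        snag_env = None
        if len(snags) >= 10 and len(live) >= 10:
            snag_env = envelope(
                live, window, "random_labeling", points2=snags,
                statistic="pcf", grid=grid, n_sim=config.n_sim,
                rank=config.rank, seed=stream(config.seed, "snag_rl"),
            )
            _env_frame(snag_env).to_csv(out / "pcf_live_snag.csv", index=False,
                                        float_format=FLOAT_FMT)
            if plots:
                _plot_env(snag_env, "live vs snag (random labelling)",
                          out / "pcf_live_snag.png")
        bundle["live_snag"] = snag_env
        done(gof_p=None if snag_env is None else snag_env.gof.p)
    except Exception as exc:
        raise RuntimeError(f"stage snag_random_labeling failed: {exc}") from exc

    # -- stage 5: crowns, patches, singles, gaps ---------------------------
    done = _stage("mosaic")
    try:
        crowned = assign_crowns(stemmap, model=crown_model,
                                geo=config.geography)
        partition = delineate_patches(crowned)
        tables = summarize_mosaic(partition)
        for name, df in tables.items():
            df.to_csv(out / f"mosaic_{name}.csv", float_format=FLOAT_FMT)
        gaps = delineate_gaps(crowned, cell=config.gap_cell,
                              gap_threshold=config.gap_threshold,
                              spur_threshold=config.spur_threshold)
        gap_table = summarize_gaps(gaps, window, config.edge_gap_limit,
                                   config.edge_gap_mode)
        gap_table.to_csv(out / "gaps.csv", float_format=FLOAT_FMT)
        bundle.update(crowned=crowned, partition=partition,
                      mosaic_tables=tables, gaps=gaps, gap_table=gap_table)
        done(n_patches=len(partition.patches),
             n_singles=len(partition.singles), n_gaps=len(gaps))
    except Exception as exc:
        raise RuntimeError(f"stage mosaic failed: {exc}") from exc

    # -- stage 6: patch typology ------------------------------------------
    done = _stage("typology")
    try:
        typology = None
        if len(partition.patches) >= 10:
            feats = patch_features(partition)
            pca = pca_patch_structure(feats)
            grouping = cluster_patch_types(feats, k=config.cluster_k)
            anovas = {}
            for col in feats.data.columns:
                groups = {
                    str(g): feats.data[col].to_numpy()[grouping.labels == g]
                    for g in np.unique(grouping.labels)
                }
                groups = {k: v for k, v in groups.items() if len(v) >= 2}
                if len(groups) >= 2:
                    anovas[col] = compare_groups_anova(groups)
            typology = {"features": feats, "pca": pca,
                        "grouping": grouping, "anova": anovas}
            pd.DataFrame({
                "component": np.arange(1, len(pca.variance_fraction) + 1),
                "variance_fraction": pca.variance_fraction,
            }).to_csv(out / "pca_variance.csv", index=False,
                      float_format=FLOAT_FMT)
            feats.data.assign(group=grouping.labels).to_csv(
                out / "patch_groups.csv", index=False, float_format=FLOAT_FMT)
        bundle["typology"] = typology
        done(k=None if typology is None else typology["grouping"].k)
    except Exception as exc:
        raise RuntimeError(f"stage typology failed: {exc}") from exc

    # -- stage 7: optional fire history ------------------------------------
    done = _stage("fire_history")
    try:
        fri = None
        if firescars is not None and config.fri_periods:
            records = read_firescars(firescars)
            fri = {}
            rows = []
            for period in config.fri_periods:
                comp = fire_mod.build_composite(records, period)
                filt = fire_mod.apply_filter(
                    comp, fraction_inclusive=config.fri_fraction_inclusive)
                entry = {}
                for name, series in (("all_fires", comp), ("filtered", filt)):
                    if len(series.fire_years) >= 2:
                        s = fire_mod.fri_summary(series)
                        entry[name] = s
                        rows.append({
                            "period": f"{period[0]}-{period[1]}",
                            "composite": name, "n_fires": s.n_fires,
                            "mean": s.mean, "sd": s.sd, "median": s.median,
                        })
                fri[period] = entry
            pd.DataFrame(rows).to_csv(out / "fri_summary.csv", index=False,
                                      float_format=FLOAT_FMT)
        bundle["fri"] = fri
        done(n_periods=0 if fri is None else len(fri))
    except Exception as exc:
        raise RuntimeError(f"stage fire_history failed: {exc}") from exc

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    bundle["manifest"] = manifest
    return bundle
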