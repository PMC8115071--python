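"""End-to-end orchestration: simulate/extract -> fit -> score -> call ->
profile -> Bayesian contrasts -> classical statistics.

Every stochastic stage derives its stream from the single pipeline seed,
so re-running with the same config reproduces every CSV byte-identically.
Disease cohorts are always scored against the frozen pooled-control fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from oxprof import __version__, panel
from oxprof.best import BestPriors, McmcConfig, best_fit
from oxprof.cohort_stats import linreg_r2, mann_whitney, spearman, summarize_counts
from oxprof.control import ControlModel
from oxprof.errors import ConfigError, ConvergenceError, DataError
from oxprof.imaging import extract_neuron_table, read_rois, read_stack
from oxprof.profiling import (
    build_profiles,
    conditional_profile,
    group_medians,
    recovery_metrics,
    severity_stack,
    summarize_case,
)
from oxprof.synthetic import CohortConfig, default_config, simulate_cohort

logger = logging.getLogger("oxprof")


@dataclass
class PipelineConfig:
    """Run configuration; YAML-serialisable, seed mandatory."""

    seed: int
    outdir: str
    mode: str = "synthetic"  # synthetic | table | images
    table_path: str | None = None
    image_path: str | None = None
    panel_path: str | None = None
    roi_path: str | None = None
    metadata_path: str | None = None
    cohort: dict | None = None  # CohortConfig dict for synthetic mode
    control_group: str = "control"
    pi_level: float = 0.80
    z_mode: str = "perpendicular"
    exclusion_targets: tuple[str, ...] = panel.DEFAULT_EXCLUSION_TARGETS
    exclusion_threshold: float = panel.DEFAULT_EXCLUSION_THRESHOLD
    representatives: dict[str, str] = field(
        default_factory=lambda: dict(panel.REPRESENTATIVE_SUBUNITS)
    )
    best: dict = field(
        default_factory=lambda: {"chains": 4, "warmup": 1000, "draws": 2500}
    )
    best_strict: bool = False
    run_group_contrasts: bool = True
    run_mass_contrasts: bool = True
    mass_contrast_min_neurons: int = 3

    def validate(self) -> None:
        if not 0.0 < self.pi_level < 1.0:
            raise ConfigError(f"pi_level must lie in (0, 1), got {self.pi_level}")
        if self.mass_contrast_min_neurons < 2:
            raise ConfigError("mass_contrast_min_neurons must be >= 2")
        if self.mode not in ("synthetic", "table", "images"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.z_mode not in ("perpendicular", "vertical"):
            raise ConfigError(f"unknown z_mode {self.z_mode!r}")
        if self.mode == "table" and not self.table_path:
            raise ConfigError("table mode requires table_path")
        if self.mode == "images" and not (
            self.image_path and self.panel_path and self.roi_path and self.metadata_path
        ):
            raise ConfigError("images mode requires image, panel, roi and metadata paths")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "outdir": str(self.outdir),
            "mode": self.mode,
            "table_path": self.table_path,
            "image_path": self.image_path,
            "panel_path": self.panel_path,
            "roi_path": self.roi_path,
            "metadata_path": self.metadata_path,
            "cohort": self.cohort,
            "control_group": self.control_group,
            "pi_level": self.pi_level,
            "z_mode": self.z_mode,
            "exclusion_targets": list(self.exclusion_targets),
            "exclusion_threshold": self.exclusion_threshold,
            "representatives": dict(self.representatives),
            "best": dict(self.best),
            "best_strict": self.best_strict,
            "run_group_contrasts": self.run_group_contrasts,
            "run_mass_contrasts": self.run_mass_contrasts,
            "mass_contrast_min_neurons": self.mass_contrast_min_neurons,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "seed" not in d or "outdir" not in d:
            raise ConfigError("pipeline config requires seed and outdir")
        kwargs = dict(d)
        if "exclusion_targets" in kwargs:
            kwargs["exclusion_targets"] = tuple(kwargs["exclusion_targets"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_table(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    if config.mode == "synthetic":
        if config.cohort is not None:
            cdict = dict(config.cohort)
            cdict.setdefault("seed", config.seed)
            cohort_cfg = CohortConfig.from_dict(cdict)
        else:
            cohort_cfg = default_config(config.seed)
        return simulate_cohort(cohort_cfg)
    if config.mode == "table":
        table = pd.read_csv(config.table_path)
        needed = {"neuron_id", "case_id", "group", panel.MASS_TARGET}
        missing = needed - set(table.columns)
        if missing:
            raise DataError(f"neuron table missing columns: {sorted(missing)}")
        return table, None
    # images
    stack = read_stack(config.image_path, config.panel_path)
    rois = read_rois(config.roi_path)
    meta_df = pd.read_csv(config.metadata_path)
    metadata = {
        str(r.case_id): (str(r.group), float(r.age)) for r in meta_df.itertuples()
    }
    table, dropped = extract_neuron_table(
        stack,
        rois,
        metadata,
        exclusion_targets=config.exclusion_targets,
        threshold=config.exclusion_threshold,
    )
    for d in dropped:
        logger.warning("dropped ROI %s: %s", d["neuron_id"], d["reason"])
    return table, None


def _best_config(config: PipelineConfig, seed: int) -> McmcConfig:
    b = config.best
    return McmcConfig(
        chains=int(b.get("chains", 4)),
        warmup=int(b.get("warmup", 1000)),
        draws=int(b.get("draws", 2500)),
        seed=seed,
    )


def _group_contrasts(
    profiles: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """BEST on z-scores: each disease group vs control, per subunit + mass."""
    groups = [g for g in profiles["group"].unique() if g != config.control_group]
    controls = profiles.loc[profiles["group"] == config.control_group]
    rows = []
    contrast_idx = 0
    zcols = [c for c in profiles.columns if c.startswith("z_")]
    for group in groups:
        disease = profiles.loc[profiles["group"] == group]
        for zcol in zcols:
            y1 = disease[zcol].dropna().to_numpy()
            y2 = controls[zcol].dropna().to_numpy()
            if len(y1) < 2 or len(y2) < 2:
                continue
            seed = config.seed * 10_000 + contrast_idx
            contrast_idx += 1
            post = best_fit(
                y1, y2, config=_best_config(config, seed), check=config.best_strict
            )
            s = post.summary()
            rows.append(
                {
                    "contrast": f"{group}_vs_{config.control_group}",
                    "target": zcol[2:],
                    "n1": len(y1),
                    "n2": len(y2),
                    "mu_diff_mean": s["mu_diff_mean"],
                    "hdi_low": s["hdi_low"],
                    "hdi_high": s["hdi_high"],
                    "effect_size_mean": s["effect_size_mean"],
                    "rhat_max": s["rhat_max"],
                    "ess_mu_diff": s["ess_mu_diff"],
                    "accepted": post.accepted,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def _mass_contrasts(
    table: pd.DataFrame, profiles: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case decreased-vs-normal ln VDAC1 BEST per complex, gated at
    >= mass_contrast_min_neurons per stratum, plus group Mann-Whitney on
    the per-case mean differences."""
    merged = profiles.merge(
        table[["neuron_id", panel.MASS_TARGET]], on="neuron_id", how="left"
    )
    rows = []
    contrast_idx = 0
    gate = config.mass_contrast_min_neurons
    for cplx in panel.COMPLEXES:
        col = f"dec_complex_{cplx}"
        for case_id, sub in merged.groupby("case_id", sort=False):
            dec = sub.loc[sub[col], panel.MASS_TARGET].to_numpy()
            norm = sub.loc[~sub[col], panel.MASS_TARGET].to_numpy()
            if len(dec) < gate or len(norm) < gate:
                continue
            seed = config.seed * 10_000 + 5000 + contrast_idx
            contrast_idx += 1
            post = best_fit(
                np.log(dec),
                np.log(norm),
                config=_best_config(config, seed),
                check=config.best_strict,
            )
            s = post.summary()
            rows.append(
                {
                    "complex": cplx,
                    "case_id": case_id,
                    "group": sub["group"].iloc[0],
                    "n_decreased": len(dec),
                    "n_normal": len(norm),
                    "mu_diff_mean": s["mu_diff_mean"],
                    "hdi_low": s["hdi_low"],
                    "hdi_high": s["hdi_high"],
                    "effect_size_mean": s["effect_size_mean"],
                    "rhat_max": s["rhat_max"],
                    "ess_mu_diff": s["ess_mu_diff"],
                    "accepted": post.accepted,
                    "seed": seed,
                }
            )
    contrasts = pd.DataFrame(rows)

    test_rows = []
    if not contrasts.empty:
        for cplx, sub in contrasts.groupby("complex", sort=False):
            groups = list(sub["group"].unique())
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    a = sub.loc[sub["group"] == groups[i], "mu_diff_mean"].to_numpy()
                    b = sub.loc[sub["group"] == groups[j], "mu_diff_mean"].to_numpy()
                    if len(a) < 1 or len(b) < 1:
                        continue
                    u, p = mann_whitney(a, b)
                    test_rows.append(
                        {
                            "complex": cplx,
                            "group_a": groups[i],
                            "group_b": groups[j],
                            "n_a": len(a),
                            "n_b": len(b),
                            "U": u,
                            "p": p,
                        }
                    )
    return contrasts, pd.DataFrame(test_rows)


def _classical_stats(
    table: pd.DataFrame,
    profiles: pd.DataFrame,
    case_summary: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    rows = []
    controls = table.loc[table["group"] == config.control_group]
    v = controls[panel.MASS_TARGET].to_numpy(dtype=float)
    for subunit in panel.SUBUNITS:
        if subunit not in controls.columns:
            continue
        i = controls[subunit].to_numpy(dtype=float)
        ok = (v > 0) & (i > 0)
        if ok.sum() >= 4:
            r, p = spearman(np.log(v[ok]), np.log(i[ok]))
            rows.append(
                {
                    "test": "spearman_ln_vs_lnVDAC1",
                    "target": subunit,
                    "groups": config.control_group,
                    "statistic": r,
                    "p": p,
                    "n": int(ok.sum()),
                }
            )

    ctrl_prof = profiles.loc[profiles["group"] == config.control_group]
    if len(ctrl_prof) >= 3 and ctrl_prof["age"].nunique() > 1:
        slope, intercept, r2, p = linreg_r2(
            ctrl_prof["age"].to_numpy(dtype=float),
            ctrl_prof["n_complexes_decreased"].to_numpy(dtype=float),
        )
        rows.append(
            {
                "test": "age_regression_r2",
                "target": "n_complexes_decreased",
                "groups": config.control_group,
                "statistic": r2,
                "p": p,
                "n": len(ctrl_prof),
            }
        )

    # per-subunit % decreased: each disease group vs control (per-case values)
    pct_cols = [c for c in case_summary.columns if c.startswith("pct_")
                and not c.startswith("pct_category_")]
    disease_groups = [
        g for g in case_summary["group"].unique() if g != config.control_group
    ]
    ctrl_rows = case_summary.loc[case_summary["group"] == config.control_group]
    for group in disease_groups:
        grp_rows = case_summary.loc[case_summary["group"] == group]
        for col in pct_cols:
            a = grp_rows[col].to_numpy(dtype=float)
            b = ctrl_rows[col].to_numpy(dtype=float)
            if len(a) < 1 or len(b) < 1:
                continue
            u, p = mann_whitney(a, b)
            rows.append(
                {
                    "test": "mann_whitney_pct_decreased",
                    "target": col[4:],
                    "groups": f"{group}_vs_{config.control_group}",
                    "statistic": u,
                    "p": p,
                    "n": len(a) + len(b),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report as a dict and
    writes all tables under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log(f"oxprof {__version__} starting; mode={config.mode} seed={config.seed}")

    table, truth = _load_table(config)
    table.to_csv(outdir / "neuron_table.csv", index=False)
    if truth is not None:
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    log(f"neuron table: {len(table)} neurons, "
        f"{table['case_id'].nunique()} cases, {table['group'].nunique()} groups")

    controls = table.loc[table["group"] == config.control_group]
    if controls.empty:
        raise DataError(
            f"no neurons in control group {config.control_group!r} (stage: fit-controls)"
        )
    model = ControlModel.fit(controls)
    model.to_yaml(outdir / "control_model.yaml")
    log(f"control model fitted on {len(controls)} control neurons")

    zscores = model.zscores(table, mode=config.z_mode)
    zscores.insert(1, "case_id", table["case_id"].to_numpy())
    zscores.insert(2, "group", table["group"].to_numpy())
    zscores.to_csv(outdir / "zscores.csv", index=False)

    profiles, dropped = build_profiles(
        table,
        model,
        level=config.pi_level,
        z_mode=config.z_mode,
        representatives=config.representatives,
    )
    profiles.to_csv(outdir / "profiles.csv", index=False)
    for d in dropped:
        log(f"dropped neuron {d['neuron_id']}: {d['reason']}")
    log(f"profiles built for {len(profiles)} neurons ({len(dropped)} dropped)")

    case_summary = summarize_case(profiles)
    case_summary.to_csv(outdir / "case_summary.csv", index=False)
    group_medians(case_summary).to_csv(outdir / "group_medians.csv", index=False)
    severity_stack(profiles).to_csv(outdir / "severity_stack.csv", index=False)
    for cplx in panel.COMPLEXES:
        conditional_profile(profiles, cplx).to_csv(
            outdir / f"conditional_{cplx}.csv", index=False
        )

    recovery = None
    if truth is not None:
        recovery = recovery_metrics(profiles, truth)
        recovery.to_csv(outdir / "recovery_metrics.csv", index=False)

    if config.run_group_contrasts:
        contrasts = _group_contrasts(profiles, config)
        contrasts.to_csv(outdir / "best_contrasts.csv", index=False)
        log(f"group contrasts: {len(contrasts)} BEST runs")
    if config.run_mass_contrasts:
        mass_contrasts, mass_tests = _mass_contrasts(table, profiles, config)
        mass_contrasts.to_csv(outdir / "mass_contrasts.csv", index=False)
        mass_tests.to_csv(outdir / "mass_contrast_tests.csv", index=False)
        log(f"mass contrasts: {len(mass_contrasts)} BEST runs "
            f"(gate >= {config.mass_contrast_min_neurons} per stratum)")

    classical = _classical_stats(table, profiles, case_summary, config)
    classical.to_csv(outdir / "classical_stats.csv", index=False)

    counts_by_group = {
        g: sub.groupby("case_id", sort=False).size().tolist()
        for g, sub in table.groupby("group", sort=False)
    }
    counts = summarize_counts(counts_by_group)
    counts_df = pd.DataFrame(
        [
            {"group": c.group, "n_cases": len(c.counts), "mean": c.mean,
             "sd": c.sd, "total": c.total}
            for c in counts.values()
        ]
    )
    counts_df.to_csv(outdir / "count_summary.csv", index=False)

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "n_neurons": int(len(table)),
        "n_profiled": int(len(profiles)),
        "dropped": dropped,
        "counts": {
            g: {"mean": c.mean, "sd": c.sd, "total": c.total}
            for g, c in counts.items()
        },
        "tables": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return report
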