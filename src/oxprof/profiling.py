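"""Deficiency profiling: PI calls, complex categories, case summaries.

A subunit is "decreased" in a neuron when its ln intensity falls strictly
below the lower limit of the 80% prediction interval of the pooled-control
regression at the neuron's ln VDAC1.  Complex-level calls follow the
representative subunit of each complex; the severity category of a neuron
is the number of complexes called decreased (0-5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from oxprof import panel
from oxprof.control import ControlModel, RegressionFit, prediction_interval
from oxprof.errors import DataError

FLAG_PREFIX = "dec_"
COMPLEX_PREFIX = "dec_complex_"


def call_decreased(
    fit: RegressionFit, subunit_intensity, vdac_intensity, level: float = 0.80
) -> np.ndarray:
    """True where ln(subunit) < lower PI limit at ln(VDAC1); strict."""
    i = np.atleast_1d(np.asarray(subunit_intensity, dtype=float))
    v = np.atleast_1d(np.asarray(vdac_intensity, dtype=float))
    if np.any(i <= 0) or np.any(v <= 0):
        raise DataError("intensities must be > 0 for deficiency calling")
    lower, _ = prediction_interval(fit, np.log(v), level)
    return np.log(i) < lower


def complex_calls(
    subunit_flags: dict[str, bool],
    representatives: dict[str, str] = panel.REPRESENTATIVE_SUBUNITS,
) -> dict[str, bool]:
    """Per-complex flag = flag of the complex's representative subunit."""
    out = {}
    for cplx, rep in representatives.items():
        if rep not in subunit_flags:
            raise DataError(f"missing representative subunit {rep!r} for {cplx}")
        out[cplx] = bool(subunit_flags[rep])
    return out


def build_profiles(
    table: pd.DataFrame,
    model: ControlModel,
    level: float = 0.80,
    z_mode: str = "perpendicular",
    representatives: dict[str, str] = panel.REPRESENTATIVE_SUBUNITS,
) -> tuple[pd.DataFrame, list[dict]]:
    """Score and call every neuron against a frozen control model.

    Returns (profiles, dropped).  Neurons with a non-positive value in
    VDAC1 or any fitted subunit are dropped (reason-coded) rather than
    categorised on partial data.
    """
    subunits = list(model.fits)
    required = [panel.MASS_TARGET, *subunits]
    values = table[required].to_numpy(dtype=float)
    ok = np.all(np.isfinite(values) & (values > 0), axis=1)
    dropped = [
        {"neuron_id": nid, "reason": "non_positive_intensity"}
        for nid in table.loc[~ok, "neuron_id"]
    ]
    kept = table.loc[ok].reset_index(drop=True)

    z = model.zscores(kept, mode=z_mode)
    profiles = kept[["neuron_id", "case_id", "group", "age"]].copy()
    v = kept[panel.MASS_TARGET].to_numpy(dtype=float)
    for subunit in subunits:
        flags = call_decreased(model.fits[subunit], kept[subunit], v, level)
        profiles[f"{FLAG_PREFIX}{subunit}"] = flags
        profiles[f"z_{subunit}"] = z[f"z_{subunit}"].to_numpy()
    profiles["z_mass"] = z["z_mass"].to_numpy()
    for cplx, rep in representatives.items():
        profiles[f"{COMPLEX_PREFIX}{cplx}"] = profiles[f"{FLAG_PREFIX}{rep}"]
    ccols = [f"{COMPLEX_PREFIX}{c}" for c in representatives]
    profiles["n_complexes_decreased"] = profiles[ccols].sum(axis=1).astype(int)
    return profiles, dropped


def summarize_case(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-case % decreased per subunit and % of neurons per category 0-5."""
    if profiles.empty:
        raise DataError("no profiles to summarize")
    flag_cols = [c for c in profiles.columns if c.startswith(FLAG_PREFIX)
                 and not c.startswith(COMPLEX_PREFIX)]
    rows = []
    for case_id, sub in profiles.groupby("case_id", sort=False):
        n = len(sub)
        row = {"case_id": case_id, "group": sub["group"].iloc[0], "n_neurons": n}
        for col in flag_cols:
            row[f"pct_{col[len(FLAG_PREFIX):]}"] = 100.0 * int(sub[col].sum()) / n
        cats = sub["n_complexes_decreased"].value_counts()
        for k in range(6):
            row[f"pct_category_{k}"] = 100.0 * int(cats.get(k, 0)) / n
        rows.append(row)
    return pd.DataFrame(rows)


def group_medians(case_summary: pd.DataFrame) -> pd.DataFrame:
    """Median of per-case percentages within each group (bar-chart view)."""
    pct_cols = [c for c in case_summary.columns if c.startswith("pct_")]
    return case_summary.groupby("group", sort=False)[pct_cols].median().reset_index()


def conditional_profile(
    profiles: pd.DataFrame, anchor: str
) -> pd.DataFrame:
    """Per-case % decreased per complex, split by anchor-complex status.

    Rows: one per (case, stratum in {decreased, normal}); cases with an
    empty stratum contribute no row for that stratum.
    """
    if anchor not in panel.COMPLEXES:
        raise DataError(f"anchor must be one of {panel.COMPLEXES}, got {anchor!r}")
    acol = f"{COMPLEX_PREFIX}{anchor}"
    rows = []
    for case_id, sub in profiles.groupby("case_id", sort=False):
        for stratum, mask in (
            ("decreased", sub[acol]),
            ("normal", ~sub[acol]),
        ):
            part = sub.loc[mask]
            if part.empty:
                continue
            row = {
                "case_id": case_id,
                "group": sub["group"].iloc[0],
                "anchor": anchor,
                "stratum": stratum,
                "n_neurons": len(part),
            }
            for cplx in panel.COMPLEXES:
                row[f"pct_{cplx}"] = (
                    100.0 * int(part[f"{COMPLEX_PREFIX}{cplx}"].sum()) / len(part)
                )
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["case_id", "group", "anchor", "stratum", "n_neurons",
                 *[f"pct_{c}" for c in panel.COMPLEXES]],
    )


def severity_stack(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-group severity distribution with per-complex composition.

    For each group and category k: percentage of the group's neurons in k,
    and — among all complex-level flags raised by those neurons — the share
    contributed by each complex.
    """
    rows = []
    for group, sub in profiles.groupby("group", sort=False):
        n = len(sub)
        for k in range(6):
            part = sub.loc[sub["n_complexes_decreased"] == k]
            row = {
                "group": group,
                "category": k,
                "pct_neurons": 100.0 * len(part) / n,
                "n_neurons": len(part),
            }
            total_flags = int(
                part[[f"{COMPLEX_PREFIX}{c}" for c in panel.COMPLEXES]].to_numpy().sum()
            )
            for cplx in panel.COMPLEXES:
                cnt = int(part[f"{COMPLEX_PREFIX}{cplx}"].sum())
                row[f"share_{cplx}"] = (
                    100.0 * cnt / total_flags if total_flags else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)


def recovery_metrics(
    profiles: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Recall / false-flag rate of complex calls against ground truth."""
    merged = profiles.merge(truth, on="neuron_id", suffixes=("", "_truth"))
    rows = []
    for cplx in panel.COMPLEXES:
        called = merged[f"{COMPLEX_PREFIX}{cplx}"].to_numpy(dtype=bool)
        actual = merged[f"deficit_{cplx}"].to_numpy(dtype=bool)
        n_pos = int(actual.sum())
        n_neg = int((~actual).sum())
        rows.append(
            {
                "complex": cplx,
                "n_true_deficient": n_pos,
                "n_true_normal": n_neg,
                "recall": float((called & actual).sum() / n_pos) if n_pos else np.nan,
                "false_flag_rate": (
                    float((called & ~actual).sum() / n_neg) if n_neg else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
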