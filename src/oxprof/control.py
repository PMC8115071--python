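"""Pooled-control normative model.

For each OxPhos subunit, ordinary least squares of ln(subunit) on
ln(VDAC1) over the pooled control neurons gives the reference line.
Neurons are scored by the signed straight-line (perpendicular) distance to
that line in units of the control SD of that distance; deficiency calls
use the vertical 80% prediction interval.  Mitochondrial mass is scored
against the mean/SD of the control ln VDAC1 distribution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from oxprof import panel
from oxprof.errors import DataError, DegenerateDesignError, DegenerateFitError

_EPS = 1e-12


@dataclass
class RegressionFit:
    """OLS fit of y = ln(subunit) on x = ln(VDAC1) over pooled controls.

    ``s_resid`` is the vertical residual SD with the n-2 denominator used
    by the prediction interval; ``s_perp`` is the n-1 sample SD of signed
    perpendicular distances used by the z-score; ``s_vert`` is the n-1
    sample SD of vertical residuals (alternative z denominator).
    """

    subunit: str
    slope: float
    intercept: float
    n: int
    x_mean: float
    sxx: float
    s_resid: float
    s_perp: float
    s_vert: float

    def predict(self, x0):
        return self.intercept + self.slope * np.asarray(x0, dtype=float)


@dataclass
class MassReference:
    """Mean/SD of ln VDAC1 over pooled control neurons."""

    mean: float
    sd: float
    n: int


def _require_positive(values: np.ndarray, label: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values) & (values > 0)
    return keep


def fit_control_regression(controls: pd.DataFrame, subunit: str) -> RegressionFit:
    """Fit the pooled-control ln-ln regression for one subunit.

    Neurons with non-positive or non-finite intensity in either channel
    are dropped.  Requires >= 3 usable neurons, non-degenerate design and
    non-zero residual scatter.
    """
    if subunit not in controls.columns:
        raise DataError(f"subunit column {subunit!r} missing")
    if panel.MASS_TARGET not in controls.columns:
        raise DataError(f"mass column {panel.MASS_TARGET!r} missing")
    v = controls[panel.MASS_TARGET].to_numpy(dtype=float)
    i = controls[subunit].to_numpy(dtype=float)
    keep = _require_positive(v, "VDAC1") & _require_positive(i, subunit)
    x = np.log(v[keep])
    y = np.log(i[keep])
    n = len(x)
    if n < 3:
        raise DataError(f"need >= 3 control neurons with positive values, got {n}")

    x_mean = float(x.mean())
    sxx = float(np.sum((x - x_mean) ** 2))
    if sxx <= _EPS:
        raise DegenerateDesignError(f"no spread in ln VDAC1 for {subunit}")
    sxy = float(np.sum((x - x_mean) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x_mean)

    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    s_resid = float(np.sqrt(sse / (n - 2)))
    if s_resid <= _EPS:
        raise DegenerateFitError(
            f"perfect collinearity for {subunit}: zero-width intervals refused"
        )
    perp = resid / np.sqrt(1.0 + slope**2)
    s_perp = float(np.std(perp, ddof=1))
    s_vert = float(np.std(resid, ddof=1))
    return RegressionFit(
        subunit=subunit,
        slope=float(slope),
        intercept=intercept,
        n=n,
        x_mean=x_mean,
        sxx=sxx,
        s_resid=s_resid,
        s_perp=s_perp,
        s_vert=s_vert,
    )


def prediction_interval(
    fit: RegressionFit, x0, level: float = 0.80
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided prediction interval for a new observation at x0.

    yhat +- t_{(1+level)/2, n-2} * s_resid * sqrt(1 + 1/n + (x0-xbar)^2/Sxx).
    """
    if not 0.0 < level < 1.0:
        raise DataError(f"level must lie in (0, 1), got {level}")
    x0 = np.asarray(x0, dtype=float)
    tcrit = stats.t.ppf((1.0 + level) / 2.0, fit.n - 2)
    half = (
        tcrit
        * fit.s_resid
        * np.sqrt(1.0 + 1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.sxx)
    )
    yhat = fit.predict(x0)
    return yhat - half, yhat + half


def zscore_perpendicular(fit: RegressionFit, x0, y0) -> np.ndarray:
    """Signed perpendicular distance to the control line / control SD."""
    if fit.s_perp <= _EPS:
        raise DegenerateFitError("zero perpendicular scatter")
    x0 = np.asarray(x0, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    d = (y0 - fit.intercept - fit.slope * x0) / np.sqrt(1.0 + fit.slope**2)
    return d / fit.s_perp


def zscore_vertical(fit: RegressionFit, x0, y0) -> np.ndarray:
    """Vertical residual / control residual SD (sensitivity variant)."""
    if fit.s_vert <= _EPS:
        raise DegenerateFitError("zero vertical scatter")
    x0 = np.asarray(x0, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    return (y0 - fit.intercept - fit.slope * x0) / fit.s_vert


def fit_mass_reference(controls: pd.DataFrame) -> MassReference:
    """Mean/SD (n-1) of ln VDAC1 over controls with positive VDAC1."""
    if panel.MASS_TARGET not in controls.columns:
        raise DataError(f"mass column {panel.MASS_TARGET!r} missing")
    v = controls[panel.MASS_TARGET].to_numpy(dtype=float)
    keep = _require_positive(v, "VDAC1")
    x = np.log(v[keep])
    if len(x) < 3:
        raise DataError(f"need >= 3 controls with positive VDAC1, got {len(x)}")
    sd = float(np.std(x, ddof=1))
    if sd <= _EPS:
        raise DegenerateFitError("zero spread in control ln VDAC1")
    return MassReference(mean=float(x.mean()), sd=sd, n=len(x))


def mass_zscore(ref: MassReference, v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise DataError("VDAC1 intensity must be > 0 for mass z-score")
    return (np.log(v) - ref.mean) / ref.sd


class ControlModel:
    """Per-subunit regression fits plus the ln-VDAC1 mass reference."""

    def __init__(self, fits: dict[str, RegressionFit], mass: MassReference):
        # canonical panel order regardless of construction/deserialization order
        order = {s: i for i, s in enumerate(panel.SUBUNITS)}
        self.fits = dict(
            sorted(fits.items(), key=lambda kv: (order.get(kv[0], len(order)), kv[0]))
        )
        self.mass = mass

    @classmethod
    def fit(
        cls, controls: pd.DataFrame, subunits: tuple[str, ...] = panel.SUBUNITS
    ) -> "ControlModel":
        fits = {s: fit_control_regression(controls, s) for s in subunits}
        return cls(fits, fit_mass_reference(controls))

    def zscores(self, table: pd.DataFrame, mode: str = "perpendicular") -> pd.DataFrame:
        """Per-neuron z per subunit plus mass z; non-positive rows get NaN."""
        if mode not in ("perpendicular", "vertical"):
            raise DataError(f"unknown z mode {mode!r}")
        zfun = zscore_perpendicular if mode == "perpendicular" else zscore_vertical
        v = table[panel.MASS_TARGET].to_numpy(dtype=float)
        ok_v = np.isfinite(v) & (v > 0)
        x = np.where(ok_v, np.log(np.where(ok_v, v, 1.0)), np.nan)
        out = {"neuron_id": table["neuron_id"].to_numpy()}
        for subunit, fit in self.fits.items():
            i = table[subunit].to_numpy(dtype=float)
            ok = ok_v & np.isfinite(i) & (i > 0)
            y = np.where(ok, np.log(np.where(ok, i, 1.0)), np.nan)
            z = np.full(len(table), np.nan)
            z[ok] = zfun(fit, x[ok], y[ok])
            out[f"z_{subunit}"] = z
        zm = np.full(len(table), np.nan)
        zm[ok_v] = mass_zscore(self.mass, v[ok_v])
        out["z_mass"] = zm
        return pd.DataFrame(out)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fits": {s: asdict(f) for s, f in self.fits.items()},
            "mass": asdict(self.mass),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControlModel":
        fits = {s: RegressionFit(**f) for s, f in d["fits"].items()}
        return cls(fits, MassReference(**d["mass"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ControlModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
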