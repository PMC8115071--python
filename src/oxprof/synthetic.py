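"""Synthetic cohort generator.

Produces per-neuron intensity tables with the statistical structure the
downstream analysis assumes: ln-intensity of each OxPhos subunit depends
linearly on ln VDAC1 in controls, with per-complex multiplicative deficits
applied to labelled subsets of neurons in disease groups.  Ground-truth
deficit labels are returned alongside so recovery can be scored exactly.

Also plans non-overlapping cell geometry (cytoplasm polygon, nucleus disc,
neuromelanin blobs) handed to :mod:`oxprof.imaging` for image synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm
from shapely.geometry import Point, Polygon

from oxprof import panel
from oxprof.errors import CapacityError, ConfigError

MIN_NEURONS_PER_CASE = 5

VALID_GROUPS = ("control", "PD", "POLG")


@dataclass
class SubunitModel:
    """Control ln-ln law for one subunit: ln I = a + b * ln V + N(0, s)."""

    intercept: float
    slope: float
    resid_sd: float

    def validate(self) -> None:
        if self.resid_sd < 0:
            raise ConfigError(f"residual SD must be >= 0, got {self.resid_sd}")


@dataclass
class GroupSpec:
    """One cohort group: case count, neuron-count law, deficit fractions."""

    name: str
    n_cases: int
    neurons_per_case_mean: float
    neurons_per_case_sd: float
    # per-complex fraction of neurons carrying the deficit
    deficit_fraction: dict[str, float] = field(default_factory=dict)
    ages: list[float] | None = None
    age_range: tuple[float, float] = (55.0, 90.0)

    def validate(self) -> None:
        if self.name not in VALID_GROUPS:
            raise ConfigError(
                f"group name must be one of {VALID_GROUPS}, got {self.name!r}"
            )
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        if self.neurons_per_case_sd < 0:
            raise ConfigError("neurons_per_case_sd must be >= 0")
        for cplx, pi in self.deficit_fraction.items():
            if cplx not in panel.COMPLEXES:
                raise ConfigError(f"unknown complex {cplx!r}")
            if not 0.0 <= pi <= 1.0:
                raise ConfigError(f"deficit fraction for {cplx} outside [0, 1]: {pi}")
        if self.ages is not None and len(self.ages) != self.n_cases:
            raise ConfigError("ages list length must equal n_cases")


@dataclass
class CohortConfig:
    """Full generator configuration; `seed` is mandatory."""

    seed: int
    groups: list[GroupSpec]
    regression: dict[str, SubunitModel]
    vdac_mean: float = 5.0
    vdac_sd: float = 0.5
    # ln-units subtracted from every subunit of an affected complex
    deficits: dict[str, float] = field(default_factory=dict)
    # within-neuron correlation of deficit labels across complexes
    label_correlation: float = 0.0

    def validate(self) -> None:
        if self.vdac_sd <= 0:
            raise ConfigError(f"vdac_sd must be > 0, got {self.vdac_sd}")
        if not self.groups:
            raise ConfigError("at least one group is required")
        missing = set(panel.SUBUNITS) - set(self.regression)
        if missing:
            raise ConfigError(f"regression missing subunits: {sorted(missing)}")
        for model in self.regression.values():
            model.validate()
        for spec in self.groups:
            spec.validate()
        for cplx, delta in self.deficits.items():
            if cplx not in panel.COMPLEXES:
                raise ConfigError(f"unknown complex {cplx!r} in deficits")
            if delta < 0:
                raise ConfigError(f"deficit for {cplx} must be >= 0, got {delta}")
        if not 0.0 <= self.label_correlation <= 1.0:
            raise ConfigError("label_correlation must lie in [0, 1]")

    # -- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "vdac_mean": self.vdac_mean,
            "vdac_sd": self.vdac_sd,
            "label_correlation": self.label_correlation,
            "deficits": dict(self.deficits),
            "regression": {
                k: {"intercept": m.intercept, "slope": m.slope, "resid_sd": m.resid_sd}
                for k, m in self.regression.items()
            },
            "groups": [
                {
                    "name": g.name,
                    "n_cases": g.n_cases,
                    "neurons_per_case_mean": g.neurons_per_case_mean,
                    "neurons_per_case_sd": g.neurons_per_case_sd,
                    "deficit_fraction": dict(g.deficit_fraction),
                    "ages": list(g.ages) if g.ages is not None else None,
                    "age_range": list(g.age_range),
                }
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        if "seed" not in d:
            raise ConfigError("cohort config requires a seed")
        groups = [
            GroupSpec(
                name=g["name"],
                n_cases=int(g["n_cases"]),
                neurons_per_case_mean=float(g["neurons_per_case_mean"]),
                neurons_per_case_sd=float(g["neurons_per_case_sd"]),
                deficit_fraction={
                    k: float(v) for k, v in (g.get("deficit_fraction") or {}).items()
                },
                ages=list(g["ages"]) if g.get("ages") else None,
                age_range=tuple(g.get("age_range", (55.0, 90.0))),
            )
            for g in d["groups"]
        ]
        regression = {
            k: SubunitModel(
                intercept=float(m["intercept"]),
                slope=float(m["slope"]),
                resid_sd=float(m["resid_sd"]),
            )
            for k, m in d["regression"].items()
        }
        cfg = cls(
            seed=int(d["seed"]),
            groups=groups,
            regression=regression,
            vdac_mean=float(d.get("vdac_mean", 5.0)),
            vdac_sd=float(d.get("vdac_sd", 0.5)),
            deficits={k: float(v) for k, v in (d.get("deficits") or {}).items()},
            label_correlation=float(d.get("label_correlation", 0.0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(
    seed: int,
    *,
    deficits: dict[str, float] | None = None,
    pd_fraction: dict[str, float] | None = None,
    polg_fraction: dict[str, float] | None = None,
) -> CohortConfig:
    """A cohort shaped like the study: 10 controls, 9 PD, 4 POLG cases."""
    regression = {
        s: SubunitModel(intercept=0.5, slope=0.9, resid_sd=0.25) for s in panel.SUBUNITS
    }
    groups = [
        GroupSpec("control", 10, 43.6, 4.7),
        GroupSpec("PD", 9, 35.1, 9.6, deficit_fraction=pd_fraction or {}),
        GroupSpec("POLG", 4, 39.0, 11.7, deficit_fraction=polg_fraction or {}),
    ]
    return CohortConfig(
        seed=seed, groups=groups, regression=regression, deficits=deficits or {}
    )


def _draw_case_counts(spec: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    """Rounded normal draws truncated (by redraw) at MIN_NEURONS_PER_CASE."""
    counts = np.empty(spec.n_cases, dtype=int)
    for i in range(spec.n_cases):
        value = None
        for _ in range(100):
            cand = int(round(rng.normal(spec.neurons_per_case_mean, spec.neurons_per_case_sd)))
            if cand >= MIN_NEURONS_PER_CASE:
                value = cand
                break
        counts[i] = MIN_NEURONS_PER_CASE if value is None else value
    return counts


def _draw_labels(
    n: int,
    fractions: dict[str, float],
    rho: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-neuron per-complex Bernoulli labels, Gaussian-copula correlated."""
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, len(panel.COMPLEXES)))
    latent = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own
    u = norm.cdf(latent)
    out = {}
    for j, cplx in enumerate(panel.COMPLEXES):
        pi = fractions.get(cplx, 0.0)
        out[cplx] = u[:, j] < pi
    return pd.DataFrame(out)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (NeuronTable, GroundTruth) deterministically from the seed.

    Counts, labels and intensity noise come from three independent
    substreams of the shared seed so each layer is reproducible in
    isolation.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    counts_rng, labels_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    rows: list[pd.DataFrame] = []
    truths: list[pd.DataFrame] = []
    neuron_counter = 0
    for spec in config.groups:
        counts = _draw_case_counts(spec, counts_rng)
        if spec.ages is not None:
            ages = np.asarray(spec.ages, dtype=float)
        else:
            lo, hi = spec.age_range
            ages = counts_rng.uniform(lo, hi, size=spec.n_cases).round(1)
        for case_idx in range(spec.n_cases):
            n = int(counts[case_idx])
            case_id = f"{spec.name}{case_idx + 1:02d}"
            labels = _draw_labels(
                n, spec.deficit_fraction, config.label_correlation, labels_rng
            )

            ln_v = noise_rng.normal(config.vdac_mean, config.vdac_sd, size=n)
            data = {
                "neuron_id": [f"n{neuron_counter + i:06d}" for i in range(n)],
                "case_id": case_id,
                "group": spec.name,
                "age": ages[case_idx],
                panel.MASS_TARGET: np.exp(ln_v),
            }
            for subunit in panel.SUBUNITS:
                m = config.regression[subunit]
                eps = noise_rng.normal(0.0, m.resid_sd, size=n) if m.resid_sd > 0 else 0.0
                ln_i = m.intercept + m.slope * ln_v + eps
                cplx = panel.complex_of(subunit)
                delta = config.deficits.get(cplx, 0.0)
                if delta:
                    ln_i = ln_i - delta * labels[cplx].to_numpy()
                data[subunit] = np.exp(ln_i)
            rows.append(pd.DataFrame(data))

            truth = labels.rename(columns={c: f"deficit_{c}" for c in panel.COMPLEXES})
            truth.insert(0, "neuron_id", data["neuron_id"])
            truth.insert(1, "case_id", case_id)
            truth.insert(2, "group", spec.name)
            for cplx in panel.COMPLEXES:
                truth[f"delta_{cplx}"] = np.where(
                    labels[cplx], config.deficits.get(cplx, 0.0), 0.0
                )
            truths.append(truth)
            neuron_counter += n

    table = pd.concat(rows, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return table, truth


# ---------------------------------------------------------------------------
# cell geometry for image synthesis
# ---------------------------------------------------------------------------


@dataclass
class CellGeometry:
    """Planned geometry for one rendered neuron."""

    neuron_id: str
    case_id: str
    polygon: Polygon  # cytoplasm outline, pixel coordinates (x=col, y=row)
    nucleus_center: tuple[float, float]
    nucleus_radius: float
    nm_blobs: list[tuple[float, float, float]]  # (x, y, radius)


def _blob_polygon(
    cx: float, cy: float, radius: float, rng: np.random.Generator, n_vertices: int = 16
) -> Polygon:
    """Star-shaped (hence simple) polygon: radially perturbed circle."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = radius * rng.uniform(0.75, 1.0, size=n_vertices)
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    return Polygon(zip(xs, ys))


def plan_geometry(
    table: pd.DataFrame,
    image_shape: tuple[int, int],
    seed: int = 0,
    *,
    cell_radius: float = 11.0,
    min_area_px: int = 100,
    max_tries: int = 200,
) -> list[CellGeometry]:
    """Place one disjoint cell per table row inside ``image_shape``.

    Disjointness is guaranteed by keeping bounding circles separated;
    placement failure after bounded retries raises :class:`CapacityError`.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = image_shape
    margin = cell_radius + 1.0
    if n_rows <= 2 * margin or n_cols <= 2 * margin:
        if len(table) > 0:
            raise CapacityError(f"image shape {image_shape} too small for any cell")

    centers: list[tuple[float, float]] = []
    cells: list[CellGeometry] = []
    for _, row in table.iterrows():
        placed = False
        for _ in range(max_tries):
            cx = rng.uniform(margin, n_cols - margin)
            cy = rng.uniform(margin, n_rows - margin)
            if all(
                (cx - ox) ** 2 + (cy - oy) ** 2 > (2 * cell_radius + 2.0) ** 2
                for ox, oy in centers
            ):
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place {len(table)} cells in {image_shape} "
                f"after {max_tries} tries"
            )
        centers.append((cx, cy))

        poly = _blob_polygon(cx, cy, cell_radius, rng)
        # retry until the rasterized interior is large enough
        while poly.area < min_area_px * 1.3:
            poly = _blob_polygon(cx, cy, cell_radius, rng)

        nucleus_r = cell_radius * 0.28
        nm_r = cell_radius * 0.18
        # nucleus left of center, neuromelanin right: both well inside
        nucleus_c = (cx - cell_radius * 0.3, cy)
        nm = [(cx + cell_radius * 0.35, cy + cell_radius * 0.2, nm_r)]
        if not poly.contains(Point(*nucleus_c).buffer(nucleus_r)):
            # fall back to the centroid if the perturbed outline cut it off
            nucleus_c = (cx, cy)
        cells.append(
            CellGeometry(
                neuron_id=str(row["neuron_id"]),
                case_id=str(row["case_id"]),
                polygon=poly,
                nucleus_center=nucleus_c,
                nucleus_radius=nucleus_r,
                nm_blobs=nm,
            )
        )
    return cells
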