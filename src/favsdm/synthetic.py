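"""Synthetic gridded landscapes for exercising the modelling pipeline.

The real modelling universe is an atlas-style regular grid of cells with a
binary breeding record and environmental covariates per cell.  This module
generates landscapes with the statistical structure the analysis assumes:

* spatially autocorrelated continuous covariates, built by smoothing
  seeded white noise with a uniform kernel over neighbouring cells and
  rescaling to a target marginal variance (cheap, and enough structure for
  the trend surface to detect);
* a Bernoulli-logistic occurrence process whose linear predictor can mix
  environmental columns with coordinate-polynomial ("pure spatial")
  terms, with the intercept calibrated by bisection so the mean generating
  probability hits a target prevalence;
* future climate scenarios as additive (optionally spatially graded)
  shifts of the climatic covariates.

Coordinates are abstract planar units; "lon"/"lat" are labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from .trend_surface import BASIS_TERMS, build_basis

#: Calibration tolerance on |mean probability - target prevalence|.
PREVALENCE_TOL = 0.005
#: Bisection iteration cap for the intercept search.
CALIBRATION_MAX_ITER = 100


@dataclass
class SyntheticTruth:
    """Generating-model parameters for one synthetic landscape.

    ``true_coefficients`` maps term names to values; every key except
    ``(Intercept)`` must be a predictor column or one of the coordinate
    monomials (X, Y, X^2, ...), which are computed from centred/scaled
    coordinates.  The stated intercept is only a starting point: it is
    re-calibrated so the mean generating probability matches
    ``target_prevalence``.
    """

    true_coefficients: dict[str, float]
    field_params: dict[str, dict[str, float]] = field(default_factory=dict)
    target_prevalence: float = 0.055
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")


@dataclass
class ClimateScenario:
    """Replacement values for the climatic predictors of every cell."""

    label: str
    replacements: pd.DataFrame  # cell_id + one column per shifted climate variable

    def columns(self) -> list[str]:
        return [c for c in self.replacements.columns if c != "cell_id"]


def gen_grid(nx: int, ny: int, extent=((0.0, 1.0), (0.0, 1.0))) -> pd.DataFrame:
    """Regular lattice of cell centroids; x varies fastest, row-major in y."""
    if nx < 2 or ny < 2:
        raise ValueError("need nx >= 2 and ny >= 2")
    (x0, x1), (y0, y1) = extent
    dx = (x1 - x0) / nx
    dy = (y1 - y0) / ny
    xs = x0 + (np.arange(nx) + 0.5) * dx
    ys = y0 + (np.arange(ny) + 0.5) * dy
    gx, gy = np.meshgrid(xs, ys)
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, nx * ny + 1),
            "lon": gx.ravel(),
            "lat": gy.ravel(),
        }
    )


def _lattice_spacing(grid: pd.DataFrame) -> float:
    xs = np.unique(grid["lon"])
    ys = np.unique(grid["lat"])
    gaps = []
    if len(xs) > 1:
        gaps.append(np.diff(xs).min())
    if len(ys) > 1:
        gaps.append(np.diff(ys).min())
    if not gaps:
        raise ValueError("grid has no spatial extent")
    return float(min(gaps))


def gen_spatial_field(
    grid: pd.DataFrame, radius: float, variance: float, seed: int
) -> np.ndarray:
    """Spatially autocorrelated covariate: kernel-smoothed seeded white noise.

    Each cell receives the mean of i.i.d. normal noise over all cells
    within ``radius`` (coordinate units, self included); the result is
    standardized to zero mean and the requested marginal ``variance``.
    ``radius = 0`` degenerates to pure white noise.
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if variance <= 0:
        raise ValueError("variance must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(grid))
    if radius == 0:
        smoothed = noise
    else:
        pts = grid[["lon", "lat"]].to_numpy()
        tree = cKDTree(pts)
        neighbours = tree.query_ball_point(pts, r=radius)
        smoothed = np.array([noise[idx].mean() for idx in neighbours])
    smoothed = smoothed - smoothed.mean()
    sd = smoothed.std()
    if sd == 0:
        raise ValueError("degenerate field (constant after smoothing)")
    return smoothed / sd * np.sqrt(variance)


def _linear_predictor_no_intercept(
    predictors: pd.DataFrame, coefficients: dict[str, float]
) -> np.ndarray:
    """Sum of coefficient * column over named terms; coordinate monomials allowed."""
    lp = np.zeros(len(predictors))
    basis = None
    for name, coef in coefficients.items():
        if name == "(Intercept)":
            continue
        if name in predictors.columns:
            lp += coef * predictors[name].to_numpy(dtype=float)
        elif name in BASIS_TERMS:
            if basis is None:
                basis = build_basis(predictors["lon"], predictors["lat"]).terms
            lp += coef * basis[name].to_numpy()
        else:
            raise ValueError(f"coefficient references unknown column: {name!r}")
    return lp


def calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Bisection on b0 so that mean(expit(b0 + lp)) = target within tolerance."""
    lo, hi = -40.0, 40.0
    b0 = 0.0
    for _ in range(CALIBRATION_MAX_ITER):
        b0 = 0.5 * (lo + hi)
        mean_p = float(expit(b0 + lp).mean())
        if abs(mean_p - target) <= PREVALENCE_TOL:
            return b0
        if mean_p < target:
            lo = b0
        else:
            hi = b0
    raise RuntimeError("intercept calibration did not reach tolerance")


def gen_occurrences(
    predictors: pd.DataFrame, truth: SyntheticTruth
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Draw presences from the logistic generating model.

    Returns ``(grid, probabilities, intercept)`` where ``grid`` carries
    cell_id, lon, lat and the sampled ``presence`` column, ``probabilities``
    are the per-cell generating probabilities (before sampling) and
    ``intercept`` is the calibrated value.
    """
    lp = _linear_predictor_no_intercept(predictors, truth.true_coefficients)
    b0 = calibrate_intercept(lp, truth.target_prevalence)
    probs = expit(b0 + lp)
    rng = np.random.default_rng(truth.seed)
    presence = (rng.random(len(probs)) < probs).astype(int)
    out = predictors[["cell_id", "lon", "lat"]].copy()
    out["presence"] = presence
    return out, probs, b0


def gen_future_scenario(
    predictors: pd.DataFrame,
    deltas: dict[str, float],
    label: str,
    climate_columns: list[str],
    gradient=None,
) -> ClimateScenario:
    """Additive climate shift: scenario value = current + delta (x gradient).

    ``gradient``, if given, is a per-cell multiplier array (e.g. doubling
    the shift from south to north).  Only climatic columns may be shifted,
    and only shifted columns appear in the scenario table.
    """
    bad = sorted(set(deltas) - set(climate_columns))
    if bad:
        raise ValueError(f"deltas on non-climate columns: {', '.join(bad)}")
    mult = np.ones(len(predictors)) if gradient is None else np.asarray(gradient, dtype=float)
    repl = pd.DataFrame({"cell_id": predictors["cell_id"].to_numpy()})
    for col, d in deltas.items():
        repl[col] = predictors[col].to_numpy(dtype=float) + d * mult
    return ClimateScenario(label=label, replacements=repl)


def morans_i(values, grid: pd.DataFrame, neighbour_radius: float | None = None) -> float:
    """Moran's I with binary contiguity weights from a distance radius.

    The default radius picks first-order rook neighbours on a regular
    lattice (slightly more than one cell width, less than the diagonal).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three cells")
    dev = x - x.mean()
    denom = float(dev @ dev)
    if denom == 0:
        raise ValueError("Moran's I is undefined for constant values")
    if neighbour_radius is None:
        neighbour_radius = 1.05 * _lattice_spacing(grid)
    pts = grid[["lon", "lat"]].to_numpy()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=neighbour_radius, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no neighbour pairs within the given radius")
    cross = float((dev[pairs[:, 0]] * dev[pairs[:, 1]]).sum())
    s0 = 2 * len(pairs)  # symmetric binary weights
    n = len(x)
    return (n / s0) * (2 * cross) / denom


#: Default study-style landscape: grid, covariates, sets and generating model.
STUDY_NX = 40
STUDY_NY = 40
#: Kernel radius ~5 cell widths on the unit square: enough autocorrelation
#: for the trend surface to have signal to absorb.
STUDY_FIELD_RADIUS = 0.125
STUDY_SETS = {
    "Pannual": "climate",
    "Range": "climate",
    "Tapr_jul": "climate",
    "DCP": "land_use",
    "HPd": "land_use",
    "Slope": "topography",
}
STUDY_QUADRATICS = ("Pannual", "Range", "Tapr_jul")
#: Environmental effects (per-SD log-odds) of the generating model.
STUDY_ENV_COEFS = {
    "Pannual": -0.8,
    "Range": -0.5,
    "Tapr_jul": 0.6,
    "DCP": 0.8,
    "HPd": -0.4,
    "Slope": -0.5,
}
#: Pure spatial component, inside the nine-monomial trend-surface span.
STUDY_SPATIAL_COEFS = {"Y": -1.2, "Y^3": 0.8, "X": 0.6}
#: Future shift (in covariate SD units): a large climate change signal.
STUDY_SCENARIO_DELTAS = {"Pannual": -1.0, "Tapr_jul": 1.5, "Range": 0.5}


def study_landscape(
    seed: int,
    nx: int = STUDY_NX,
    ny: int = STUDY_NY,
    target_prevalence: float = 0.055,
    spatial_strength: float = 2.0,
    env_strength: float = 1.0,
):
    """A seeded landscape with the statistical shape of the atlas study.

    Six autocorrelated covariates in three environmental predictor sets
    (quadratic climate terms included), a Bernoulli-logistic occurrence
    process mixing environmental effects with a pure coordinate-polynomial
    spatial term, and a rare-species prevalence.  ``spatial_strength``
    scales the spatial term (2.0 makes it the dominant driver, mirroring
    a distribution constrained beyond its measured environment;
    0 removes it), ``env_strength`` scales the environmental effects.

    Returns ``(table, presence, probs, truth)`` where ``table`` is a
    :class:`~favsdm.pipeline.PredictorTable` without the Geog column.
    """
    from .pipeline import PredictorTable

    grid = gen_grid(nx, ny)
    data = grid.copy()
    for i, name in enumerate(STUDY_SETS):
        data[name] = gen_spatial_field(
            grid, radius=STUDY_FIELD_RADIUS, variance=1.0, seed=seed * 1009 + i
        )
    table = PredictorTable(data=data, sets=dict(STUDY_SETS))
    for c in STUDY_QUADRATICS:
        table = table.add_quadratic(c)
    coefs = {k: env_strength * v for k, v in STUDY_ENV_COEFS.items()}
    coefs.update({k: spatial_strength * v for k, v in STUDY_SPATIAL_COEFS.items()})
    truth = SyntheticTruth(
        true_coefficients=coefs,
        field_params={n: {"radius": STUDY_FIELD_RADIUS, "variance": 1.0} for n in STUDY_SETS},
        target_prevalence=target_prevalence,
        seed=seed,
    )
    occ, probs, _ = gen_occurrences(table.data, truth)
    table.data["presence"] = occ["presence"].to_numpy()
    return table, occ["presence"].to_numpy(), probs, truth


def study_scenario(table_data: pd.DataFrame, label: str = "future") -> ClimateScenario:
    """The default large climate shift on the study landscape's climate columns."""
    return gen_future_scenario(
        table_data, dict(STUDY_SCENARIO_DELTAS), label,
        [c for c in STUDY_SETS if STUDY_SETS[c] == "climate"],
    )


def write_grid_csv(path, grid: pd.DataFrame) -> None:
    """Grid table as CSV: cell_id, lon, lat, presence, then predictors."""
    lead = [c for c in ("cell_id", "lon", "lat", "presence") if c in grid.columns]
    rest = [c for c in grid.columns if c not in lead]
    grid[lead + rest].to_csv(path, index=False)


def write_scenario_csv(path, scenario: ClimateScenario) -> None:
    scenario.replacements.to_csv(path, index=False)
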