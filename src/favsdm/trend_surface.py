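"""Trend-surface geographic predictor.

Pure spatial structure in a species' range (history, dispersal limits,
conspecific attraction) is summarized by one covariate, here called
``Geog``: the nine coordinate monomials X, Y, X2, Y2, X3, Y3, XY, X2Y,
XY2 of each cell centroid are offered to a backward-stepwise logistic
regression of presence, and Geog is the logit (linear predictor) of the
surviving model.  Coordinates are centred and scaled before the monomials
are built -- raw degree-3 coordinate values are numerically hostile -- and
the scaling constants are stored so the surface is exactly reproducible on
new cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import (
    INTERCEPT,
    P_REMOVE_DEFAULT,
    FittedLogisticModel,
    RankDeficiencyError,
    fit_terms,
    lr_test,
)

#: The nine monomial terms, in canonical order.
BASIS_TERMS = ("X", "Y", "X^2", "Y^2", "X^3", "Y^3", "XY", "X^2Y", "XY^2")

#: Name of the geographic predictor column.
GEOG = "Geog"


def _monomials(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "X": x,
            "Y": y,
            "X^2": x**2,
            "Y^2": y**2,
            "X^3": x**3,
            "Y^3": y**3,
            "XY": x * y,
            "X^2Y": x**2 * y,
            "XY^2": x * y**2,
        }
    )


@dataclass
class TrendSurfaceBasis:
    """Nine coordinate monomials plus the centring/scaling that built them."""

    terms: pd.DataFrame
    scaling: dict[str, float]

    def evaluate(self, lon, lat) -> pd.DataFrame:
        """Recompute the basis for (possibly new) cells with the stored scaling."""
        s = self.scaling
        x = (np.asarray(lon, dtype=float) - s["x_mean"]) / s["x_sd"]
        y = (np.asarray(lat, dtype=float) - s["y_mean"]) / s["y_sd"]
        return _monomials(x, y)


@dataclass
class GeogVariable:
    """The fitted trend surface: retained terms, coefficients, per-cell logit."""

    retained_terms: list[str]
    coefficients: dict[str, float]  # includes the intercept
    values: np.ndarray
    scaling: dict[str, float]
    model: FittedLogisticModel | None = None
    warnings: list[str] = field(default_factory=list)

    def evaluate(self, lon, lat) -> np.ndarray:
        """Geog on new cells: same scaling, same coefficients."""
        basis = TrendSurfaceBasis(terms=pd.DataFrame(), scaling=self.scaling).evaluate(lon, lat)
        eta = np.full(len(basis), self.coefficients[INTERCEPT])
        for t in self.retained_terms:
            eta += self.coefficients[t] * basis[t].to_numpy()
        return eta


def build_basis(lon, lat) -> TrendSurfaceBasis:
    """Centre and scale the centroid coordinates, then build the nine monomials."""
    x = np.asarray(lon, dtype=float)
    y = np.asarray(lat, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("coordinates must be finite")
    if len(np.unique(np.column_stack([x, y]), axis=0)) < 3:
        raise ValueError("need at least three distinct cell locations")
    scaling = {
        "x_mean": float(x.mean()),
        "x_sd": float(x.std()) or 1.0,  # degenerate axis: centre only
        "y_mean": float(y.mean()),
        "y_sd": float(y.std()) or 1.0,
    }
    xs = (x - scaling["x_mean"]) / scaling["x_sd"]
    ys = (y - scaling["y_mean"]) / scaling["y_sd"]
    return TrendSurfaceBasis(terms=_monomials(xs, ys), scaling=scaling)


def fit_geog(
    basis: TrendSurfaceBasis,
    presence,
    p_remove: float = P_REMOVE_DEFAULT,
    log: list | None = None,
) -> GeogVariable:
    """Backward-stepwise elimination over the nine monomials; Geog is the logit.

    Starts from the full nine-term model (degenerate columns dropped up
    front), repeatedly removes the term with the largest likelihood-ratio
    p-value above ``p_remove``, and stops when all survivors test at or
    below it.  If everything is eliminated, Geog degenerates to the
    constant intercept logit and a warning is recorded.
    """
    notes: list[str] = []
    included = [t for t in BASIS_TERMS if basis.terms[t].std() > 0]
    dropped_degenerate = [t for t in BASIS_TERMS if t not in included]
    if dropped_degenerate:
        notes.append("degenerate basis columns dropped: " + ", ".join(dropped_degenerate))
    # Peel off collinear columns (e.g. 1-D lattices) until the design has full rank.
    while included:
        try:
            current = fit_terms(basis.terms, included, presence)
            break
        except RankDeficiencyError as err:
            victim = next(t for t in reversed(included) if t in err.columns)
            included.remove(victim)
            notes.append(f"collinear basis column dropped: {victim}")
    else:
        current = fit_terms(basis.terms, [], presence)
    if current.separation:
        notes.append("(quasi-)separation flagged in the geographic model")
        warnings.warn("separation in the full geographic model; elimination proceeds", stacklevel=2)

    while included:
        worst = None
        for t in included:
            rest = [u for u in included if u != t]
            p = lr_test(current, fit_terms(basis.terms, rest, presence))
            if worst is None or p > worst[0]:
                worst = (p, t)
        if worst[0] <= p_remove:
            break
        included.remove(worst[1])
        if log is not None:
            log.append(("remove", worst[1], worst[0]))
        current = fit_terms(basis.terms, included, presence)
    if not included:
        notes.append("all geographic terms eliminated; Geog is the constant intercept logit")
        warnings.warn(notes[-1], stacklevel=2)

    coefs = {t: float(b) for t, b in zip(current.terms, current.beta)}
    values = current.linear_predictor(basis.terms)
    return GeogVariable(
        retained_terms=included,
        coefficients=coefs,
        values=values,
        scaling=dict(basis.scaling),
        model=current,
        warnings=notes,
    )
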