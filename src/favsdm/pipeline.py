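"""End-to-end favourability modelling workflow.

Per species: FDR screening within each predictor set -> stepwise
predictor-set models -> combined space-included / space-excluded models on
a 70/30 split -> evaluation on the held-out cells -> variation
partitioning by inclusion-exclusion -> favourability surfaces for the
current climate and for future scenarios (climatic columns replaced,
everything else, including the geographic predictor, held fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import glm
from .favourability import favourability
from .glm import (
    INTERCEPT,
    EvaluationReport,
    FittedLogisticModel,
    SingleClassError,
)
from .synthetic import ClimateScenario
from .trend_surface import GEOG, build_basis, fit_geog

PREDICTOR_SETS = ("climate", "land_use", "topography", "geographic")

QUADRATIC_SUFFIX = "^2"


def quadratic_parent(column: str) -> str | None:
    """Parent of a quadratic column under the "<name>^2" convention, else None."""
    if column.endswith(QUADRATIC_SUFFIX):
        return column[: -len(QUADRATIC_SUFFIX)]
    return None


@dataclass
class PredictorTable:
    """Per-cell named covariates with predictor-set assignments.

    ``data`` holds cell_id, lon, lat plus one numeric column per predictor;
    ``sets`` maps every modelled column to one of the predictor sets.
    Quadratic columns follow the "<name>^2" naming convention and belong to
    their parent's set.
    """

    data: pd.DataFrame
    sets: dict[str, str]

    def __post_init__(self) -> None:
        for col, s in self.sets.items():
            if col not in self.data.columns:
                raise ValueError(f"assigned column missing from table: {col!r}")
            if s not in PREDICTOR_SETS:
                raise ValueError(f"unknown predictor set {s!r} for column {col!r}")
        modelled = self.data[list(self.sets)]
        if modelled.isna().any().any():
            bad = modelled.columns[modelled.isna().any()].tolist()
            raise ValueError(f"missing values in modelled columns: {', '.join(bad)}")

    def columns_of(self, set_name: str) -> list[str]:
        return [c for c, s in self.sets.items() if s == set_name]

    def set_of(self, column: str) -> str:
        return self.sets[column]

    def with_geog(self, geog_values: np.ndarray) -> "PredictorTable":
        data = self.data.copy()
        data[GEOG] = geog_values
        sets = dict(self.sets)
        sets[GEOG] = "geographic"
        return PredictorTable(data=data, sets=sets)

    def add_quadratic(self, column: str) -> "PredictorTable":
        """Append the square of ``column`` under the naming convention."""
        name = column + QUADRATIC_SUFFIX
        data = self.data.copy()
        data[name] = data[column].to_numpy(dtype=float) ** 2
        sets = dict(self.sets)
        sets[name] = self.sets[column]
        return PredictorTable(data=data, sets=sets)


@dataclass
class PartitionResult:
    """Pure and shared variation fractions over subsets of predictor sets.

    ``fractions`` maps each non-empty subset (a sorted tuple of set names)
    to the variation attributable exactly to that subset; singletons are
    pure effects, larger subsets shared effects (which may be negative --
    suppression).  All fractions sum to ``total``, the full model's
    Nagelkerke R-squared, by construction.
    """

    fractions: dict[tuple[str, ...], float]
    total: float

    def as_percentages(self) -> dict[tuple[str, ...], float]:
        if self.total == 0:
            return {k: 0.0 for k in self.fractions}
        return {k: 100.0 * v / self.total for k, v in self.fractions.items()}


@dataclass
class CombinedModelPair:
    """Space-included and space-excluded combined models on a shared split."""

    space_included: FittedLogisticModel
    space_excluded: FittedLogisticModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    vif_included: pd.Series | None = None
    vif_excluded: pd.Series | None = None
    eval_included: EvaluationReport | None = None
    eval_excluded: EvaluationReport | None = None


def split_train_test(
    presence, fraction: float, seed: int, stratified: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition; both parts must contain both classes.

    Unstratified draws are retried (fresh seeds derived from ``seed``) up
    to 100 times until both classes appear on both sides; the stratified
    mode splits each class separately.
    """
    y = np.asarray(presence)
    n = len(y)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n_train = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    if stratified:
        train = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            k = int(np.floor(fraction * len(idx)))
            train.append(rng.permutation(idx)[:k])
        train_idx = np.sort(np.concatenate(train))
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        if min(len(train_idx), len(test_idx)) == 0 or {0, 1} - set(y[train_idx]) or {0, 1} - set(y[test_idx]):
            raise ValueError("stratified split cannot place both classes in both parts")
        return train_idx, test_idx
    for _ in range(100):
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
        if not ({0, 1} - set(y[train_idx])) and not ({0, 1} - set(y[test_idx])):
            return train_idx, test_idx
    raise ValueError(
        "could not place both classes in both parts after 100 attempts; "
        f"class counts are {int(y.sum())}/{int(len(y) - y.sum())}"
    )


def screen_predictor_set(
    table: PredictorTable, set_name: str, presence, q: float = 0.05,
    log: list | None = None,
) -> list[str]:
    """FDR screening within one predictor set.

    Each column (quadratic terms included) is tested as a single-term
    logistic model against the intercept-only model by likelihood ratio;
    Benjamini-Hochberg at rate ``q`` is applied within the set and the
    surviving column names are returned (possibly none).
    """
    cols = table.columns_of(set_name)
    if not cols:
        raise ValueError(f"predictor set {set_name!r} is empty")
    null = glm.fit_terms(table.data, [], presence)
    pvals = []
    for c in cols:
        model = glm.fit_terms(table.data, [c], presence)
        pvals.append(glm.lr_test(model, null))
    keep = glm.bh_fdr(pvals, q)
    if log is not None:
        for c, p, k in zip(cols, pvals, keep):
            log.append(("screen", set_name, c, p, bool(k)))
    return [c for c, k in zip(cols, keep) if k]


def fit_predictor_set_model(
    table: PredictorTable, retained: list[str], presence,
    p_enter: float = glm.P_ENTER_DEFAULT, p_remove: float = glm.P_REMOVE_DEFAULT,
    log: list | None = None,
) -> FittedLogisticModel:
    """Stepwise model over one set's FDR survivors (intercept-only if none)."""
    if not retained:
        return glm.fit_terms(table.data, [], presence)
    return glm.stepwise(table.data[retained], presence, p_enter, p_remove, log=log)


def fit_combined_pair(
    set_models: dict[str, FittedLogisticModel],
    table: PredictorTable,
    presence,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    p_enter: float = glm.P_ENTER_DEFAULT,
    p_remove: float = glm.P_REMOVE_DEFAULT,
    log: list | None = None,
) -> CombinedModelPair:
    """Stepwise over the pooled set-model variables, with and without Geog.

    Both models are trained on the same training rows; the space-excluded
    candidate pool is the space-included pool minus the geographic set.
    VIF is computed on each final model's non-intercept terms (when >= 2).
    """
    pool: list[str] = []
    for m in set_models.values():
        for t in m.terms:
            if t != INTERCEPT and t not in pool:
                pool.append(t)
    if not pool:
        raise ValueError("no predictor-set model contributed any variable")
    geographic = set(table.columns_of("geographic"))
    pool_excl = [c for c in pool if c not in geographic]
    y = np.asarray(presence)
    train = table.data.iloc[train_idx]
    y_train = y[train_idx]

    included = glm.stepwise(train[pool], y_train, p_enter, p_remove, log=log)
    if pool_excl:
        excluded = glm.stepwise(train[pool_excl], y_train, p_enter, p_remove, log=log)
    else:
        excluded = glm.fit_terms(train, [], y_train)

    def _vif(model: FittedLogisticModel) -> pd.Series | None:
        terms = [t for t in model.terms if t != INTERCEPT]
        return glm.vif(train[terms]) if len(terms) >= 2 else None

    return CombinedModelPair(
        space_included=included,
        space_excluded=excluded,
        train_idx=np.asarray(train_idx),
        test_idx=np.asarray(test_idx),
        vif_included=_vif(included),
        vif_excluded=_vif(excluded),
    )


def evaluate_model(
    model: FittedLogisticModel, table: PredictorTable, presence, test_idx
) -> EvaluationReport:
    """Held-out discrimination at the neutral favourability threshold.

    Probabilities on the test cells are transformed to favourability with
    the training (n1, n0); sensitivity/specificity/CCR are computed at
    F >= 0.5 and AUC on F.  Deviance explained (Nagelkerke) and AIC come
    from the training fit.
    """
    test = table.data.iloc[np.asarray(test_idx)]
    if len(test) == 0:
        raise ValueError("empty test set")
    y_test = np.asarray(presence)[np.asarray(test_idx)]
    if y_test.min() == y_test.max():
        raise SingleClassError("test split contains a single class")
    probs = model.predict_proba(test)
    fav = favourability(probs, model.n1, model.n0)
    sens, spec, ccr = glm.confusion_metrics(fav, y_test, 0.5)
    return EvaluationReport(
        sensitivity=sens,
        specificity=spec,
        ccr=ccr,
        auc=glm.roc_auc(fav, y_test),
        deviance_explained=glm.nagelkerke_r2(model),
        aic=glm.aic(model),
    )


def variation_partition(
    model: FittedLogisticModel, table: PredictorTable, presence,
    subset_rows: np.ndarray | None = None,
) -> PartitionResult:
    """Inclusion-exclusion partition of the combined model's variation.

    The model's terms are grouped by predictor set; for every non-empty
    subset S of those sets the model containing exactly the terms of S is
    refitted (fixed variable lists, no reselection) and its Nagelkerke
    R-squared recorded.  Moebius inversion of g(S) = R2(all) - R2(all - S)
    yields one fraction per subset: singletons are pure effects, the rest
    shared effects (possibly negative), and the fractions sum exactly to
    the full model's R-squared.
    """
    terms = [t for t in model.terms if t != INTERCEPT]
    by_set: dict[str, list[str]] = {}
    for t in terms:
        by_set.setdefault(table.set_of(t), []).append(t)
    sets = sorted(by_set)
    data = table.data if subset_rows is None else table.data.iloc[np.asarray(subset_rows)]
    y = np.asarray(presence) if subset_rows is None else np.asarray(presence)[np.asarray(subset_rows)]

    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(sets) + 1):
        for combo in combinations(sets, r):
            cols = [t for s in combo for t in by_set[s]]
            r2[frozenset(combo)] = glm.nagelkerke_r2(glm.fit_terms(data, cols, y))

    allsets = frozenset(sets)
    total = r2[allsets]
    if len(sets) == 1:
        return PartitionResult(fractions={tuple(sets): total}, total=total)

    def g(subset: frozenset) -> float:
        return total - r2[allsets - subset]

    fractions: dict[tuple[str, ...], float] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(sets, r):
            u = frozenset(combo)
            val = 0.0
            for rr in range(len(combo) + 1):
                for sub in combinations(combo, rr):
                    val += (-1) ** (len(combo) - rr) * g(frozenset(sub))
            fractions[tuple(sorted(combo))] = val
    return PartitionResult(fractions=fractions, total=total)


def scenario_term_table(
    model: FittedLogisticModel, table: PredictorTable, scenario: ClimateScenario
) -> pd.DataFrame:
    """Per-cell term values under a scenario.

    Climatic columns take their scenario values; quadratic climatic terms
    are recomputed as the square of the shifted parent (never replaced
    independently); land use, topography and Geog stay at current values.
    A scenario missing a needed climatic column is rejected by name.
    """
    repl = scenario.replacements
    if not np.array_equal(repl["cell_id"].to_numpy(), table.data["cell_id"].to_numpy()):
        aligned = repl.set_index("cell_id")
        try:
            repl = aligned.loc[table.data["cell_id"]].reset_index()
        except KeyError as err:
            raise ValueError(f"scenario cells do not match the grid: {err}") from None
    out = table.data.copy()
    climate = set(table.columns_of("climate"))
    for t in model.terms:
        if t == INTERCEPT or t not in climate:
            continue
        parent = quadratic_parent(t)
        source = parent if parent is not None else t
        if source not in repl.columns:
            raise ValueError(f"scenario {scenario.label!r} lacks climatic column {source!r}")
        shifted = repl[source].to_numpy(dtype=float)
        out[t] = shifted**2 if parent is not None else shifted
    return out


def project_future(
    model: FittedLogisticModel,
    table: PredictorTable,
    scenario: ClimateScenario,
    n1: int,
    n0: int,
) -> pd.DataFrame:
    """FavourabilitySurface under a climate scenario, coefficients unchanged.

    Returns a frame with cell_id, probability, favourability and the
    scenario label.  Pass ``scenario=None``-like identity by building a
    scenario with zero deltas; use :func:`current_surface` for the current
    climate.
    """
    term_table = scenario_term_table(model, table, scenario)
    probs = model.predict_proba(term_table)
    return pd.DataFrame(
        {
            "cell_id": table.data["cell_id"].to_numpy(),
            "probability": probs,
            "favourability": favourability(probs, n1, n0),
            "scenario_label": scenario.label,
        }
    )


def current_surface(
    model: FittedLogisticModel, table: PredictorTable, n1: int, n0: int
) -> pd.DataFrame:
    """FavourabilitySurface under current covariates."""
    probs = model.predict_proba(table.data)
    return pd.DataFrame(
        {
            "cell_id": table.data["cell_id"].to_numpy(),
            "probability": probs,
            "favourability": favourability(probs, n1, n0),
            "scenario_label": "current",
        }
    )


@dataclass
class RunResult:
    """Everything one pipeline run produces."""

    table: PredictorTable
    geog: object
    screened: dict[str, list[str]]
    set_models: dict[str, FittedLogisticModel]
    pair: CombinedModelPair
    partition_included: PartitionResult | None
    partition_excluded: PartitionResult | None
    surfaces: dict[str, pd.DataFrame] = field(default_factory=dict)
    selection_log: list = field(default_factory=list)


def run_pipeline(
    table: PredictorTable,
    presence,
    scenarios: list[ClimateScenario] | None = None,
    q: float = 0.05,
    p_enter: float = glm.P_ENTER_DEFAULT,
    p_remove: float = glm.P_REMOVE_DEFAULT,
    split_fraction: float = 0.7,
    split_seed: int = 0,
    stratified: bool = False,
    trend_surface_mode: str = "all-data",
) -> RunResult:
    """The full workflow on one species' grid.

    ``trend_surface_mode`` is "all-data" (Geog fitted on every cell before
    the split, the default, matching the treatment of the trend surface as
    data preparation) or "split-safe" (Geog fitted on training cells only,
    avoiding any leakage into evaluation).
    """
    if trend_surface_mode not in ("all-data", "split-safe"):
        raise ValueError("trend_surface_mode must be 'all-data' or 'split-safe'")
    y = np.asarray(presence)
    log: list = []
    train_idx, test_idx = split_train_test(y, split_fraction, split_seed, stratified)

    if trend_surface_mode == "all-data":
        basis = build_basis(table.data["lon"], table.data["lat"])
        geog = fit_geog(basis, y, p_remove, log=log)
        geog_values = geog.values
    else:
        sub = table.data.iloc[train_idx]
        basis = build_basis(sub["lon"], sub["lat"])
        geog = fit_geog(basis, y[train_idx], p_remove, log=log)
        geog_values = geog.evaluate(table.data["lon"], table.data["lat"])
    table = table.with_geog(geog_values)

    screened: dict[str, list[str]] = {}
    set_models: dict[str, FittedLogisticModel] = {}
    for s in PREDICTOR_SETS:
        if not table.columns_of(s):
            continue
        screened[s] = screen_predictor_set(table, s, y, q, log=log)
        set_models[s] = fit_predictor_set_model(table, screened[s], y, p_enter, p_remove, log=log)

    pair = fit_combined_pair(set_models, table, y, train_idx, test_idx, p_enter, p_remove, log=log)
    pair.eval_included = evaluate_model(pair.space_included, table, y, test_idx)
    pair.eval_excluded = evaluate_model(pair.space_excluded, table, y, test_idx)

    def _partition(model):
        terms = [t for t in model.terms if t != INTERCEPT]
        if not terms:
            return None
        return variation_partition(model, table, y, subset_rows=pair.train_idx)

    n1_full = int(y.sum())
    n0_full = int(len(y) - n1_full)
    surfaces = {
        "included:current": current_surface(pair.space_included, table, n1_full, n0_full),
        "excluded:current": current_surface(pair.space_excluded, table, n1_full, n0_full),
    }
    for sc in scenarios or []:
        surfaces[f"included:{sc.label}"] = project_future(pair.space_included, table, sc, n1_full, n0_full)
        surfaces[f"excluded:{sc.label}"] = project_future(pair.space_excluded, table, sc, n1_full, n0_full)

    return RunResult(
        table=table,
        geog=geog,
        screened=screened,
        set_models=set_models,
        pair=pair,
        partition_included=_partition(pair.space_included),
        partition_excluded=_partition(pair.space_excluded),
        surfaces=surfaces,
        selection_log=log,
    )
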