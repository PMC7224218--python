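"""Suitability modelling: pseudo-absence data, nested splits, a pluggable
learner contract, AUC/TSS evaluation, TSS-weighted ensembles, raster
projection, and clamping detection.

Learners are opaque objects satisfying ``fit(X, y, sample_weight)`` /
``predict_suitability(X) -> [0, 1]``; four are shipped (regularised logistic
regression, a spline-basis additive classifier, random forest, and gradient
boosted trees) and more can be registered under the same contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, NicheShiftError
from .occurrences import OccurrenceSet
from .raster import Raster, RasterStack

logger = logging.getLogger(__name__)

KM_PER_DEGREE = 111.32

AUC_BANDS = (
    (0.90, "excellent"),
    (0.80, "good"),
    (0.70, "fair"),
    (0.60, "poor"),
    (0.50, "fail"),
)


# ---------------------------------------------------------------------------
# Occurrence preparation
# ---------------------------------------------------------------------------

def thin_records(occ, cell_size_km: float, seed: int | None = None):
    """Keep at most one record per cell of a ``cell_size_km`` lon/lat grid.

    The retained record is the lowest-index one unless a seed requests a
    random pick.  Accepts an OccurrenceSet or a DataFrame with lon/lat.
    """
    if cell_size_km <= 0:
        raise ConfigurationError("cell_size must be positive")
    df = occ.data if isinstance(occ, OccurrenceSet) else occ
    if len(df) == 0:
        raise NicheShiftError("cannot thin an empty occurrence table")
    step = cell_size_km / KM_PER_DEGREE
    ix = np.floor(df["lon"].to_numpy(dtype=float) / step).astype(np.int64)
    iy = np.floor(df["lat"].to_numpy(dtype=float) / step).astype(np.int64)
    cells = pd.Series(list(zip(ix, iy)), index=df.index)
    if seed is None:
        keep = cells.groupby(cells).apply(lambda s: s.index.min())
    else:
        rng = np.random.default_rng(seed)
        keep = cells.groupby(cells).apply(
            lambda s: s.index[rng.integers(len(s))]
        )
    thinned = df.loc[sorted(keep)].copy()
    logger.info("thinning retained %d of %d records", len(thinned), len(df))
    if isinstance(occ, OccurrenceSet):
        return OccurrenceSet(species=occ.species, range_label=occ.range_label,
                             data=thinned)
    return thinned


def correlation_filter(env_table: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Greedily drop one variable of each pair with |Pearson r| > threshold,
    keeping the earlier-listed variable.  Pairs at exactly the threshold are
    retained (<= rule)."""
    cols = list(env_table.columns)
    if len(cols) < 2:
        raise NicheShiftError("correlation filter needs >= 2 variables")
    x = env_table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise NicheShiftError(f"constant variable: {cols[const[0]]!r}")
    r = np.corrcoef(x, rowvar=False)
    kept: list[int] = []
    tol = 1e-12  # float guard so pairs at exactly the threshold are retained
    for j in range(len(cols)):
        if all(abs(r[j, i]) <= threshold + tol for i in kept):
            kept.append(j)
    return [cols[j] for j in kept]


def sample_pseudo_absences(background: pd.DataFrame, presences: pd.DataFrame,
                           n: int = 10_000, variables: list[str] | None = None,
                           seed: int | None = None,
                           decimals: int = 9) -> pd.DataFrame:
    """Sample n background rows, without replacement, excluding any row whose
    environmental values coincide with a presence record."""
    if variables is None:
        variables = [c for c in background.columns
                     if np.issubdtype(background[c].dtype, np.number)]
    bg_key = [tuple(row) for row in
              background[variables].round(decimals).to_numpy()]
    pres_key = {tuple(row) for row in
                presences[variables].round(decimals).to_numpy()}
    eligible = np.array([k not in pres_key for k in bg_key])
    n_eligible = int(eligible.sum())
    if n_eligible < n:
        raise NicheShiftError(
            f"only {n_eligible} background cells without presences;"
            f" cannot sample {n} pseudo-absences without replacement"
        )
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(eligible)
    chosen = rng.choice(idx, size=n, replace=False)
    return background.iloc[np.sort(chosen)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Datasets and splits
# ---------------------------------------------------------------------------

@dataclass
class PADataset:
    """Presence / pseudo-absence dataset with prevalence-0.5 case weights."""

    presences: pd.DataFrame
    absences: pd.DataFrame
    variables: list[str]
    range_label: str = "native"

    def __post_init__(self) -> None:
        if self.range_label not in {"native", "invaded", "combined"}:
            raise ConfigurationError(f"bad range_label {self.range_label!r}")
        for name, df in (("presence", self.presences), ("pseudo-absence", self.absences)):
            missing = [v for v in self.variables if v not in df.columns]
            if missing:
                raise NicheShiftError(f"{name} table missing variable(s): {missing}")

    def __len__(self) -> int:
        return len(self.presences) + len(self.absences)

    @property
    def X(self) -> np.ndarray:
        return np.vstack([
            self.presences[self.variables].to_numpy(dtype=float),
            self.absences[self.variables].to_numpy(dtype=float),
        ])

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([
            np.ones(len(self.presences), dtype=int),
            np.zeros(len(self.absences), dtype=int),
        ])

    @property
    def weights(self) -> np.ndarray:
        """Case weights equalising total presence and absence weight."""
        n_p, n_a = len(self.presences), len(self.absences)
        return np.concatenate([
            np.ones(n_p),
            np.full(n_a, n_p / n_a if n_a else 0.0),
        ])


@dataclass
class SplitPlan:
    """One fixed evaluation slice plus repeated inner train/test resamples of
    the remainder, all stratified by class."""

    eval_idx: np.ndarray
    repeats: list[tuple[np.ndarray, np.ndarray]]
    n_total: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def _stratified_take(idx_by_class: list[np.ndarray], frac: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    taken, rest = [], []
    for idx in idx_by_class:
        perm = rng.permutation(idx)
        k = int(round(frac * len(idx)))
        taken.append(perm[:k])
        rest.append(perm[k:])
    return np.sort(np.concatenate(taken)), np.sort(np.concatenate(rest))


def split_dataset(pa: PADataset, eval_frac: float = 0.3,
                  inner_test_frac: float = 0.3, n_repeats: int = 10,
                  seed: int | None = None) -> SplitPlan:
    """70/30 evaluation hold-out, then n_repeats inner 70/30 resamples."""
    y = pa.y
    for cls in (0, 1):
        if (y == cls).sum() < 10:
            raise NicheShiftError(
                "need >= 10 records per class for stratified splitting"
            )
    rng = np.random.default_rng(seed)
    classes = [np.flatnonzero(y == 1), np.flatnonzero(y == 0)]
    eval_idx, remainder = _stratified_take(classes, eval_frac, rng)
    rem_classes = [remainder[y[remainder] == 1], remainder[y[remainder] == 0]]
    repeats = []
    for _ in range(n_repeats):
        test_idx, train_idx = _stratified_take(rem_classes, inner_test_frac, rng)
        repeats.append((train_idx, test_idx))
    return SplitPlan(eval_idx=eval_idx, repeats=repeats, n_total=len(y))


# ---------------------------------------------------------------------------
# Learner contract
# ---------------------------------------------------------------------------

class SklearnLearner:
    """Adapter giving any binary sklearn classifier the suitability-learner
    contract: fit(X, y, sample_weight) and predict_suitability(X) in [0, 1]."""

    def __init__(self, name: str, estimator) -> None:
        self.name = name
        self.estimator = estimator
        self.fitted = False

    def fit(self, X, y, sample_weight=None) -> "SklearnLearner":
        kwargs = {}
        if sample_weight is not None:
            if isinstance(self.estimator, Pipeline):
                # weights are routed to the final pipeline step
                kwargs[f"{self.estimator.steps[-1][0]}__sample_weight"] = sample_weight
            else:
                kwargs["sample_weight"] = sample_weight
        try:
            self.estimator.fit(X, y, **kwargs)
        except TypeError:
            logger.warning("%s: estimator ignores sample weights", self.name)
            self.estimator.fit(X, y)
        self.fitted = True
        return self

    def predict_suitability(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        return proba[:, list(self.estimator.classes_).index(1)]


def _make_glm(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(max_iter=2000)),
    ])


def _make_gam(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("spline", SplineTransformer(degree=3, n_knots=5)),
        ("clf", LogisticRegression(max_iter=2000, C=1.0)),
    ])


def _make_rf(seed):
    return RandomForestClassifier(n_estimators=200, random_state=seed)


def _make_brt(seed):
    return GradientBoostingClassifier(random_state=seed)


def _make_cart(seed):
    return DecisionTreeClassifier(random_state=seed, min_samples_leaf=5)


def _make_ann(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                              random_state=seed)),
    ])


LEARNER_FACTORIES = {
    "glm": _make_glm,
    "gam": _make_gam,
    "rf": _make_rf,
    "brt": _make_brt,
    "cart": _make_cart,
    "ann": _make_ann,
}

DEFAULT_LEARNERS = ("glm", "gam", "rf", "brt")


def make_learner(name: str, seed: int | None = None) -> SklearnLearner:
    if name not in LEARNER_FACTORIES:
        raise ConfigurationError(
            f"unknown learner {name!r}; available: {sorted(LEARNER_FACTORIES)}"
        )
    return SklearnLearner(name, LEARNER_FACTORIES[name](seed))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalScores:
    auc: float
    tss: float
    tss_threshold: float
    sensitivity: float
    specificity: float
    auc_band: str


def auc_band(auc: float) -> str:
    for lo, label in AUC_BANDS:
        if auc > lo:
            return label
    return "no-better-than-random"


def _auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC (ties get half credit)."""
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _max_tss(scores: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Maximise sensitivity + specificity - 1 over unique-score thresholds
    (predict presence when score >= threshold)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    ys = y[order]
    n1 = int(y.sum())
    n0 = y.size - n1
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    # candidate cuts: last index of each tied score block
    last = np.r_[s[1:] != s[:-1], True]
    sens = tp[last] / n1
    spec = 1 - fp[last] / n0
    tss = sens + spec - 1
    best = int(np.argmax(tss))
    return (float(tss[best]), float(s[last][best]),
            float(sens[best]), float(spec[best]))


def evaluate_scores(scores: np.ndarray, y: np.ndarray) -> EvalScores:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise NicheShiftError("evaluation dataset has a single class")
    auc = _auc_rank(scores, y)
    tss, thr, sens, spec = _max_tss(scores, y)
    return EvalScores(auc=auc, tss=tss, tss_threshold=thr,
                      sensitivity=sens, specificity=spec,
                      auc_band=auc_band(auc))


def evaluate(model, dataset: PADataset | tuple) -> EvalScores:
    """Evaluate a fitted learner or ensemble on a presence/absence dataset."""
    if isinstance(dataset, PADataset):
        X, y = dataset.X, dataset.y
    else:
        X, y = dataset
    return evaluate_scores(model.predict_suitability(X), np.asarray(y, dtype=int))


# ---------------------------------------------------------------------------
# Members and ensembles
# ---------------------------------------------------------------------------

@dataclass
class MemberModel:
    learner_name: str
    repeat: int
    model: SklearnLearner
    inner_scores: EvalScores

    def predict_suitability(self, X) -> np.ndarray:
        return self.model.predict_suitability(X)


def fit_members(pa: PADataset, plan: SplitPlan,
                learners=DEFAULT_LEARNERS,
                seed: int | None = None) -> list[MemberModel]:
    """One fitted model per (learner, inner repeat); failures are logged and
    skipped provided at least one member survives."""
    if not learners:
        raise ConfigurationError("need at least one learner")
    X, y, w = pa.X, pa.y, pa.weights
    ss = np.random.SeedSequence(seed)
    members: list[MemberModel] = []
    failures: list[str] = []
    for repeat, (train_idx, test_idx) in enumerate(plan.repeats):
        for name in learners:
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            try:
                model = make_learner(name, child_seed)
                model.fit(X[train_idx], y[train_idx], w[train_idx])
                pred = model.predict_suitability(X[test_idx])
                if np.any(pred < 0) or np.any(pred > 1):
                    raise NicheShiftError(
                        f"{name}: predictions outside [0, 1]"
                    )
                scores = evaluate_scores(pred, y[test_idx])
            except Exception as exc:  # member failure is not fatal
                failures.append(f"{name}/rep{repeat}: {exc}")
                logger.warning("member %s repeat %d failed: %s", name, repeat, exc)
                continue
            members.append(MemberModel(name, repeat, model, scores))
    if not members:
        raise NicheShiftError(
            "all member fits failed: " + "; ".join(failures[:5])
        )
    return members


@dataclass
class EnsembleModel:
    """TSS-weighted average of member suitability models."""

    members: list[MemberModel]
    weights: np.ndarray

    def predict_suitability(self, X) -> np.ndarray:
        preds = np.vstack([m.predict_suitability(X) for m in self.members])
        return (self.weights[:, None] * preds).sum(axis=0) / self.weights.sum()


def build_ensemble(members: list[MemberModel],
                   member_scores: list[EvalScores] | None = None) -> EnsembleModel:
    """Weights w_i = max(TSS_i, 0); members with TSS <= 0 contribute nothing."""
    if member_scores is None:
        member_scores = [m.inner_scores for m in members]
    if len(member_scores) != len(members):
        raise ConfigurationError("one score per member required")
    weights = np.array([max(s.tss, 0.0) for s in member_scores])
    if weights.sum() <= 0:
        raise NicheShiftError("no member has positive TSS; cannot build ensemble")
    keep = weights > 0
    return EnsembleModel(
        members=[m for m, k in zip(members, keep) if k],
        weights=weights[keep],
    )


# ---------------------------------------------------------------------------
# Projection and clamping
# ---------------------------------------------------------------------------

def project_suitability(model, stack: RasterStack,
                        variables: list[str]) -> Raster:
    """Per-cell suitability raster; nodata cells propagate."""
    missing = [v for v in variables if v not in stack.layers]
    if missing:
        raise NicheShiftError(f"missing raster layer(s): {missing}")
    X = stack.table(variables)
    valid = ~np.isnan(X).any(axis=1)
    template = stack[variables[0]]
    out = np.full(X.shape[0], template.nodata)
    if valid.any():
        out[valid] = model.predict_suitability(X[valid])
    return Raster(data=out.reshape(template.shape), xll=template.xll,
                  yll=template.yll, cellsize=template.cellsize,
                  nodata=template.nodata)


@dataclass
class ClampingReport:
    variables: list[str]
    per_variable: dict[str, np.ndarray]     # bool arrays over target cells/rows
    combined: np.ndarray
    fractions: dict[str, float]
    combined_fraction: float


def clamping_mask(training_env: pd.DataFrame, target_env,
                  variables: list[str] | None = None) -> ClampingReport:
    """Flag target cells whose value for any variable falls outside the closed
    training range [min, max] — projections there are extrapolations."""
    if variables is None:
        variables = list(training_env.columns)
    missing = [v for v in variables if v not in training_env.columns]
    if missing:
        raise NicheShiftError(f"training table missing variable(s): {missing}")

    if isinstance(target_env, RasterStack):
        shape = next(iter(target_env.layers.values())).shape
        values = {v: target_env[v].values() for v in variables}
    else:
        missing = [v for v in variables if v not in target_env.columns]
        if missing:
            raise NicheShiftError(f"target table missing variable(s): {missing}")
        shape = None
        values = {v: target_env[v].to_numpy(dtype=float) for v in variables}

    per_variable: dict[str, np.ndarray] = {}
    fractions: dict[str, float] = {}
    combined = None
    for v in variables:
        lo = training_env[v].min()
        hi = training_env[v].max()
        t = values[v]
        valid = ~np.isnan(t)
        clamped = valid & ((t < lo) | (t > hi))
        frac = float(clamped.sum() / valid.sum()) if valid.any() else 0.0
        if shape is not None:
            clamped = clamped.reshape(shape)
        per_variable[v] = clamped
        fractions[v] = frac
        combined = clamped if combined is None else (combined | clamped)

    n_valid = np.sum(~np.isnan(np.column_stack(list(values.values()))).any(axis=1))
    combined_fraction = float(combined.sum() / n_valid) if n_valid else 0.0
    return ClampingReport(variables=list(variables), per_variable=per_variable,
                          combined=combined, fractions=fractions,
                          combined_fraction=combined_fraction)
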