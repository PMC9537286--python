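"""Model development: redundancy clustering, MRMR + enhanced-Borda feature
selection under repeated cross-validation, and the two final model families
(one-versus-all ridge logistic regression, Cox proportional hazards with
forced covariates).

The module is organised statsmodels-style: ``LogisticOVA`` and ``CoxPH`` are
model objects built from data whose ``fit()`` returns a results object
carrying coefficients, Wald confidence intervals, p-values and a
``summary()`` table; prediction and persistence hang off the results.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, spearmanr
from sklearn.metrics import mutual_info_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold
from lifelines.utils import concordance_index

from .errors import ModelError
from .transforms import TransformParams, apply_transforms, yeo_johnson

DEFAULT_PENALTY_GRID = (0.0, 0.01, 0.1, 1.0, 10.0)
#: |Spearman rho| threshold above which a feature is considered volume-redundant
VOLUME_CORRELATION_LIMIT = 0.5


# ---------------------------------------------------------------------------
# redundancy clustering
# ---------------------------------------------------------------------------

def cluster_representatives(
    features: pd.DataFrame, height: float = 0.3
) -> tuple[list[str], dict[str, list[str]]]:
    """Complete-linkage clustering on 1 - |Spearman rho|, cut at ``height``.

    Each cluster is represented by the feature with the highest mean
    absolute Spearman correlation to its co-members (singletons represent
    themselves; ties resolve by feature-name order).
    """
    sd = features.std(axis=0, ddof=0)
    zero = list(sd.index[sd == 0])
    if zero:
        warnings.warn(f"zero-variance features dropped before clustering: {zero}")
        features = features.drop(columns=zero)
    cols = list(features.columns)
    if not cols:
        raise ModelError("empty feature table")
    if len(cols) == 1:
        return cols, {cols[0]: cols}
    rho = features.corr(method="spearman").to_numpy()
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=height, criterion="distance")
    reps: list[str] = []
    cluster_map: dict[str, list[str]] = {}
    for cl in sorted(set(labels)):
        members = [cols[i] for i in np.where(labels == cl)[0]]
        if len(members) == 1:
            rep = members[0]
        else:
            idx = [cols.index(m) for m in members]
            mean_corr = {
                m: np.abs(rho[cols.index(m), [j for j in idx if j != cols.index(m)]]).mean()
                for m in members
            }
            best = max(mean_corr.values())
            rep = sorted(m for m in members if mean_corr[m] == best)[0]
        reps.append(rep)
        cluster_map[rep] = members
    return reps, cluster_map


def volume_correlation_filter(
    features: pd.DataFrame, volume: pd.Series, limit: float = VOLUME_CORRELATION_LIMIT
) -> list[str]:
    """Features with |Spearman rho| vs volume above ``limit`` are discarded."""
    keep = []
    for col in features.columns:
        rho = spearmanr(features[col], volume).statistic
        if not np.isfinite(rho) or abs(rho) <= limit:
            keep.append(col)
    return keep


# ---------------------------------------------------------------------------
# MRMR + enhanced Borda
# ---------------------------------------------------------------------------

def _discretise_ef(x: np.ndarray, bins: int = 4) -> np.ndarray:
    """Equal-frequency binning for mutual information on continuous data."""
    x = np.asarray(x, dtype=float)
    if np.unique(x).size <= bins:
        _, inv = np.unique(x, return_inverse=True)
        return inv
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    return float(mutual_info_score(a, b))


def mrmr_rank(
    X: pd.DataFrame, y: np.ndarray, n_select: int | None = None, bins: int = 4
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance ranking (quotient form).

    Relevance and redundancy are mutual information on equal-frequency
    4-bin discretised variables; the next feature maximises
    relevance / mean redundancy to the already selected set.  Ties break by
    feature-name order.
    """
    cols = list(X.columns)
    if len(cols) < 1:
        raise ModelError("empty feature table")
    if n_select is None:
        n_select = len(cols)
    if n_select > len(cols):
        warnings.warn("n_select exceeds available features; truncated")
        n_select = len(cols)
    yd = _discretise_ef(np.asarray(y), bins) if np.asarray(y).dtype.kind == "f" else np.asarray(y)
    xd = {c: _discretise_ef(X[c].to_numpy(), bins) for c in cols}
    relevance = {c: _mi(xd[c], yd) for c in cols}
    selected: list[str] = []
    remaining = sorted(cols)
    pair_mi: dict[tuple[str, str], float] = {}
    while remaining and len(selected) < n_select:
        best_name, best_score = None, -np.inf
        for c in remaining:
            if selected:
                reds = []
                for s in selected:
                    key = (c, s) if c < s else (s, c)
                    if key not in pair_mi:
                        pair_mi[key] = _mi(xd[c], xd[s])
                    reds.append(pair_mi[key])
                red = float(np.mean(reds))
                score = relevance[c] / max(red, 1e-12)
            else:
                score = relevance[c]
            if score > best_score:  # ties keep earlier (name-sorted) candidate
                best_name, best_score = c, score
        selected.append(best_name)
        remaining.remove(best_name)
    return selected


@dataclass
class RankingTable:
    """Aggregated feature ranking across repeated CV folds."""

    table: pd.DataFrame  # columns: occurrence, borda, final_rank
    fold_sizes: list[int]
    median_size: int

    def top(self, n: int | None = None) -> list[str]:
        n = n if n is not None else self.median_size
        ordered = self.table.sort_values("final_rank").index
        return list(ordered[:n])


def enhanced_borda_scores(
    fold_selections: list[list[str]], n_folds: int | None = None
) -> dict[str, float]:
    """Occurrence-weighted normalised Borda aggregation.

    For feature f selected at rank r in a fold with M selected features the
    fold contributes ``(M - r + 1) / M``; the score is the sum over folds
    divided by the total number of folds (folds not selecting f contribute 0).
    """
    if n_folds is None:
        n_folds = len(fold_selections)
    scores: dict[str, float] = {}
    for chosen in fold_selections:
        m = len(chosen)
        for rank, name in enumerate(chosen, start=1):
            scores[name] = scores.get(name, 0.0) + (m - rank + 1) / m
    return {name: s / n_folds for name, s in scores.items()}


def _median_half_up(values: list[int]) -> int:
    med = float(np.median(values))
    return max(1, int(np.floor(med + 0.5)))


def _make_folds(y, reps: int, folds: int, seed: int, stratify: bool):
    rng = np.random.default_rng(seed)
    n = len(y)
    for rep in range(reps):
        rs = int(rng.integers(0, 2**31 - 1))
        if stratify:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(np.zeros(n), y)
        else:
            splitter = KFold(n_splits=folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(np.zeros(n))
        for train_idx, _ in split_iter:
            yield train_idx


def cv_rank_aggregate(
    X: pd.DataFrame,
    y,
    task: str = "classification",
    time=None,
    event=None,
    reps: int = 33,
    folds: int = 3,
    seed: int = 0,
    s_max: int = 10,
    horizon: float = 24.0,
    forced: tuple[str, ...] = (),
) -> RankingTable:
    """Enhanced-Borda rank aggregation over repeated cross-validation.

    Per fold: MRMR ranking plus an inner-CV search over model sizes
    1..``s_max`` (AUC for classification, concordance for survival).  The
    enhanced Borda score of feature f is
    ``sum over folds selecting f of (M_fold - rank_f + 1) / M_fold``,
    divided by the number of folds — normalised Borda weighted by occurrence.
    The final model size is the half-up-rounded median of per-fold sizes.
    ``forced`` features bypass selection and are excluded from the ranking.
    """
    free_cols = [c for c in X.columns if c not in forced]
    Xf = X[free_cols]
    if task == "survival":
        if time is None or event is None:
            raise ModelError("survival ranking needs time and event")
        # relevance target: event observed within the horizon
        y_sel = ((np.asarray(time) <= horizon) & (np.asarray(event) == 1)).astype(int)
        strat = y_sel
    else:
        y_sel = np.asarray(y)
        strat = y_sel
    s_max = min(s_max, len(free_cols))
    n_folds_total = reps * folds
    occurrence = {c: 0 for c in free_cols}
    fold_selections: list[list[str]] = []
    fold_sizes: list[int] = []
    rng = np.random.default_rng(seed + 1)
    for train_idx in _make_folds(strat, reps, folds, seed, stratify=True):
        Xt = Xf.iloc[train_idx]
        yt = y_sel[train_idx]
        ranking = mrmr_rank(Xt, yt)
        size = _inner_size_search(
            X.iloc[train_idx], yt, ranking, task, s_max,
            time=None if time is None else np.asarray(time)[train_idx],
            event=None if event is None else np.asarray(event)[train_idx],
            forced=forced, seed=int(rng.integers(0, 2**31 - 1)),
        )
        fold_sizes.append(size)
        chosen = ranking[:size]
        fold_selections.append(chosen)
        for name in chosen:
            occurrence[name] += 1
    borda = enhanced_borda_scores(fold_selections, n_folds_total)
    score = pd.Series({c: borda.get(c, 0.0) for c in free_cols})
    table = pd.DataFrame(
        {
            "occurrence": pd.Series(occurrence),
            "borda": score,
        }
    ).sort_values(["borda", "occurrence"], ascending=False, kind="stable")
    # deterministic tie-break by name within equal scores
    table = table.sort_values("borda", ascending=False, kind="stable")
    table["final_rank"] = np.arange(1, len(table) + 1)
    return RankingTable(table, fold_sizes, _median_half_up(fold_sizes))


def _inner_size_search(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    ranking: list[str],
    task: str,
    s_max: int,
    time=None,
    event=None,
    forced: tuple[str, ...] = (),
    seed: int = 0,
    inner_folds: int = 3,
) -> int:
    """Inner-CV grid over model sizes; returns the best size (ties -> smaller)."""
    best_size, best_score = 1, -np.inf
    n = len(X_train)
    if task == "classification":
        splitter = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(np.zeros(n), y_train))
    else:
        splitter = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(np.zeros(n)))
    for size in range(1, s_max + 1):
        feats = list(forced) + ranking[:size]
        scores = []
        for tr, te in splits:
            try:
                if task == "classification":
                    if len(np.unique(y_train[tr])) < 2 or len(np.unique(y_train[te])) < 2:
                        continue
                    beta, intercept, _ = _irls_logistic(
                        X_train[feats].to_numpy()[tr], y_train[tr], penalty=0.01
                    )
                    lin = X_train[feats].to_numpy()[te] @ beta + intercept
                    scores.append(roc_auc_score(y_train[te], lin))
                else:
                    cph = CoxPHFitter(penalizer=0.01)
                    df = X_train[feats].iloc[tr].copy()
                    df["time"], df["event"] = time[tr], event[tr]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cph.fit(df, duration_col="time", event_col="event")
                    risk = cph.predict_partial_hazard(X_train[feats].iloc[te]).to_numpy()
                    scores.append(concordance_index(time[te], -risk, event[te]))
            except Exception:
                continue
        if scores:
            score = float(np.mean(scores))
            if score > best_score + 1e-12:
                best_size, best_score = size, score
    return best_size


# ---------------------------------------------------------------------------
# logistic regression by IRLS with ridge penalty
# ---------------------------------------------------------------------------

def _irls_logistic(
    X: np.ndarray, y: np.ndarray, penalty: float, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, float, np.ndarray]:
    """Ridge-penalised logistic fit; returns (beta, intercept, covariance).

    The intercept is unpenalised.  Covariance is the inverse of the
    penalised Fisher information (Wald approximation).
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.diag([0.0] + [penalty] * p)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        grad = Xd.T @ (y - mu) - pen @ beta
        hess = Xd.T @ (Xd * w[:, None]) + pen
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular Hessian in logistic IRLS: {exc}")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
        if np.max(np.abs(beta)) > 1e6:
            raise ModelError("logistic coefficients diverging (perfect separation?)")
    cov = np.linalg.inv(hess)
    return beta[1:], float(beta[0]), cov


@dataclass
class FittedModel:
    """Results object: estimates, uncertainties and stored transforms.

    ``coefficients`` are on the transformed (YJ + z) scale.  For Cox models
    there is no intercept and ``hazard_ratios`` = exp(beta); ``baseline`` is
    the Breslow cumulative baseline hazard needed for calibration.
    """

    model_kind: str  # "logistic_ova" | "cox"
    features: list[str]
    coefficients: pd.Series
    transform_params: TransformParams
    intercept: float | None = None
    conf_int: pd.DataFrame | None = None
    p_values: pd.Series | None = None
    std_errors: pd.Series | None = None
    forced: list[str] = field(default_factory=list)
    cutoff: float | None = None
    risk_threshold: float | None = None
    penalty: float = 0.0
    provenance: dict = field(default_factory=dict)
    baseline: pd.DataFrame | None = None  # cumulative baseline hazard (Cox)
    _lifelines: object | None = None

    @property
    def hazard_ratios(self) -> pd.Series:
        if self.model_kind != "cox":
            raise ModelError("hazard ratios only defined for Cox models")
        return np.exp(self.coefficients)

    # -- prediction ---------------------------------------------------------
    def predict(self, raw_features: pd.DataFrame) -> pd.Series:
        """Probability (logistic) or relative risk exp(beta'z) (Cox) from raw
        feature values; stored transforms are applied first."""
        missing = [f for f in self.features if f not in raw_features.columns]
        if missing:
            raise ModelError(f"missing model features: {missing}")
        z = apply_transforms(raw_features[self.features], self.transform_params)
        lin = z.to_numpy() @ self.coefficients.loc[self.features].to_numpy()
        if self.model_kind == "logistic_ova":
            lin = lin + (self.intercept or 0.0)
            return pd.Series(1.0 / (1.0 + np.exp(-lin)), index=raw_features.index)
        return pd.Series(np.exp(lin), index=raw_features.index)

    def predict_survival(self, raw_features: pd.DataFrame, t: float) -> pd.Series:
        """S(t | z) = exp(-H0(t) * exp(beta'z)) from the Breslow baseline."""
        if self.model_kind != "cox" or self.baseline is None:
            raise ModelError("survival prediction needs a fitted Cox baseline")
        risk = self.predict(raw_features)
        h0 = float(np.interp(t, self.baseline.index, self.baseline.iloc[:, 0]))
        return np.exp(-h0 * risk)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        rows = {}
        for f in self.features:
            beta = self.coefficients[f]
            row = {"coef": beta}
            if self.model_kind == "cox":
                row["HR"] = float(np.exp(beta))
            if self.conf_int is not None:
                row["ci_low"], row["ci_high"] = self.conf_int.loc[f]
            if self.p_values is not None:
                row["p"] = self.p_values[f]
            tp = self.transform_params.table.loc[f]
            row.update(
                {"lambda": tp["lam"], "z_shift": tp["shift"], "z_scale": tp["scale"]}
            )
            rows[f] = row
        if self.intercept is not None:
            rows["(intercept)"] = {"coef": self.intercept}
        return pd.DataFrame.from_dict(rows, orient="index")

    # -- persistence --------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.model_kind,
            "features": self.features,
            "transforms": self.transform_params.to_dict(),
            "coefficients": {f: float(self.coefficients[f]) for f in self.features},
            "intercept": self.intercept,
            "forced": self.forced,
            "cutoff": self.cutoff,
            "risk_threshold": self.risk_threshold,
            "penalty": self.penalty,
            "provenance": self.provenance,
        }
        if self.baseline is not None:
            payload["baseline"] = {
                "time": [float(t) for t in self.baseline.index],
                "cumhaz": [float(v) for v in self.baseline.iloc[:, 0]],
            }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        baseline = None
        if "baseline" in payload:
            baseline = pd.DataFrame(
                {"cumhaz": payload["baseline"]["cumhaz"]},
                index=payload["baseline"]["time"],
            )
        return cls(
            model_kind=payload["kind"],
            features=list(payload["features"]),
            coefficients=pd.Series(payload["coefficients"]),
            transform_params=TransformParams.from_dict(payload["transforms"]),
            intercept=payload.get("intercept"),
            forced=list(payload.get("forced", [])),
            cutoff=payload.get("cutoff"),
            risk_threshold=payload.get("risk_threshold"),
            penalty=payload.get("penalty", 0.0),
            provenance=payload.get("provenance", {}),
            baseline=baseline,
        )


class LogisticOVA:
    """One-versus-all ridge logistic model on transformed features.

    ``X`` is the *transformed* design (z-scores); the transform parameters
    are attached so the fitted results can consume raw features.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        labels: pd.Series | np.ndarray,
        positive_class,
        transform_params: TransformParams,
    ) -> None:
        self.X = X
        y = np.asarray(labels)
        self.y = (y == positive_class).astype(float)
        self.positive_class = positive_class
        self.transform_params = transform_params.subset(list(X.columns))
        if self.y.sum() in (0, len(self.y)):
            raise ModelError("both classes must be present")

    def fit(
        self,
        penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
        seed: int = 0,
    ) -> FittedModel:
        """Grid-search the ridge penalty by inner 3-fold AUC, then refit."""
        best_pen, best_auc = penalty_grid[0], -np.inf
        Xv = self.X.to_numpy(dtype=float)
        if len(penalty_grid) > 1:
            splitter = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
            splits = list(splitter.split(Xv, self.y))
            for pen in penalty_grid:
                aucs = []
                for tr, te in splits:
                    try:
                        beta, b0, _ = _irls_logistic(Xv[tr], self.y[tr], pen)
                        lin = Xv[te] @ beta + b0
                        if len(np.unique(self.y[te])) == 2:
                            aucs.append(roc_auc_score(self.y[te], lin))
                    except ModelError:
                        aucs.append(-np.inf)
                score = float(np.mean(aucs)) if aucs else -np.inf
                if score > best_auc + 1e-12:
                    best_pen, best_auc = pen, score
        try:
            beta, intercept, cov = _irls_logistic(Xv, self.y, best_pen)
        except ModelError:
            fallback = min(p for p in penalty_grid if p > 0)
            warnings.warn(
                f"penalty {best_pen} failed (separation?); refitting with {fallback}"
            )
            best_pen = fallback
            beta, intercept, cov = _irls_logistic(Xv, self.y, best_pen)
        se = np.sqrt(np.diag(cov))
        names = list(self.X.columns)
        coef = pd.Series(beta, index=names)
        se_s = pd.Series(se[1:], index=names)
        zstat = coef / se_s
        pvals = pd.Series(2 * norm.sf(np.abs(zstat)), index=names)
        ci = pd.DataFrame(
            {
                "ci_low": coef - 1.959963984540054 * se_s,
                "ci_high": coef + 1.959963984540054 * se_s,
            }
        )
        return FittedModel(
            model_kind="logistic_ova",
            features=names,
            coefficients=coef,
            transform_params=self.transform_params,
            intercept=intercept,
            conf_int=ci,
            p_values=pvals,
            std_errors=se_s,
            penalty=best_pen,
            provenance={"positive_class": str(self.positive_class)},
        )


class CoxPH:
    """Cox proportional hazards model (Efron ties, Breslow baseline)."""

    def __init__(
        self,
        X: pd.DataFrame,
        time,
        event,
        transform_params: TransformParams,
        forced: tuple[str, ...] = (),
    ) -> None:
        self.X = X
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.transform_params = transform_params.subset(list(X.columns))
        self.forced = list(forced)
        if self.event.sum() == 0:
            raise ModelError("no events observed; Cox model undefined")
        if self.event.sum() < 10:
            warnings.warn(
                f"only {int(self.event.sum())} events; estimates will be unstable"
            )

    def fit(
        self,
        penalty_grid: tuple[float, ...] = (0.0,),
        seed: int = 0,
    ) -> FittedModel:
        best_pen = penalty_grid[0]
        if len(penalty_grid) > 1:
            best_c = -np.inf
            splitter = KFold(n_splits=3, shuffle=True, random_state=seed)
            splits = list(splitter.split(self.X))
            for pen in penalty_grid:
                cs = []
                for tr, te in splits:
                    try:
                        cph = self._fit_lifelines(self.X.iloc[tr], self.time[tr], self.event[tr], pen)
                        risk = cph.predict_partial_hazard(self.X.iloc[te]).to_numpy()
                        cs.append(concordance_index(self.time[te], -risk, self.event[te]))
                    except Exception:
                        continue
                score = float(np.mean(cs)) if cs else -np.inf
                if score > best_c + 1e-12:
                    best_pen, best_c = pen, score
        cph = self._fit_lifelines(self.X, self.time, self.event, best_pen)
        coef = cph.params_.copy()
        coef.index = list(self.X.columns)
        ci = cph.confidence_intervals_.copy()
        ci.columns = ["ci_low", "ci_high"]
        ci.index = list(self.X.columns)
        pvals = cph.summary["p"].copy()
        pvals.index = list(self.X.columns)
        se = cph.standard_errors_.copy()
        se.index = list(self.X.columns)
        baseline = cph.baseline_cumulative_hazard_.copy()
        return FittedModel(
            model_kind="cox",
            features=list(self.X.columns),
            coefficients=coef,
            transform_params=self.transform_params,
            conf_int=ci,
            p_values=pvals,
            std_errors=se,
            forced=self.forced,
            penalty=best_pen,
            baseline=baseline,
            _lifelines=cph,
        )

    @staticmethod
    def _fit_lifelines(X: pd.DataFrame, time, event, penalty: float) -> CoxPHFitter:
        df = X.copy()
        df["time"] = time
        df["event"] = event
        cph = CoxPHFitter(penalizer=penalty, baseline_estimation_method="breslow")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:
            raise ModelError(f"Cox partial-likelihood fit failed: {exc}")
        return cph


def fit_logistic_ova(
    X: pd.DataFrame,
    labels,
    positive_class,
    transform_params: TransformParams,
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
    seed: int = 0,
) -> FittedModel:
    """Functional wrapper over :class:`LogisticOVA`."""
    return LogisticOVA(X, labels, positive_class, transform_params).fit(penalty_grid, seed)


def fit_cox(
    X: pd.DataFrame,
    time,
    event,
    transform_params: TransformParams,
    forced: tuple[str, ...] = (),
    penalty_grid: tuple[float, ...] = (0.0,),
    seed: int = 0,
) -> FittedModel:
    """Functional wrapper over :class:`CoxPH`."""
    return CoxPH(X, time, event, transform_params, forced).fit(penalty_grid, seed)


def predict(model: FittedModel, raw_features: pd.DataFrame) -> pd.Series:
    """Apply a stored model to raw feature values."""
    return model.predict(raw_features)
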