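"""Performance, stratification and calibration statistics.

Discrimination is summarised by the AUC (classification) and Harrell's
C-index (survival), with percentile bootstrap confidence intervals (600
resamples by default).  Calibration uses the Hosmer-Lemeshow test for
probabilities and the Greenwood-Nam-d'Agostino test at a fixed horizon for
survival models.  Risk stratification fits an optimised threshold on the
discovery cohort only and applies it frozen to validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _harrell_c
from scipy import stats

from .errors import ModelError

DEFAULT_N_BOOT = 600


@dataclass
class EvalReport:
    """Bootstrap summary of one metric."""

    metric: str
    point: float  # median over bootstraps
    ci_low: float
    ci_high: float
    n_bootstraps: int
    aux: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstraps": self.n_bootstraps,
            **{k: v for k, v in self.aux.items() if np.isscalar(v)},
        }


@dataclass
class StratificationRule:
    """Risk threshold learned on the discovery cohort."""

    threshold: float
    source: str = "discovery"


def _bootstrap_metric(fn, n: int, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = []
    attempts = 0
    while len(out) < n_boot and attempts < 20 * n_boot:
        idx = rng.integers(0, n, size=n)
        attempts += 1
        val = fn(idx)
        if val is not None and np.isfinite(val):
            out.append(val)
    return np.asarray(out)


def _summarise(name: str, values: np.ndarray, n_boot: int, **aux) -> EvalReport:
    lo, med, hi = np.percentile(values, [2.5, 50, 97.5])
    return EvalReport(name, float(med), float(lo), float(hi), n_boot, dict(aux))


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC == mid-rank Mann-Whitney statistic."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(
    scores, labels, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> EvalReport:
    """AUC with percentile bootstrap CI over patients."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ModelError("AUC needs both classes")

    def one(idx):
        y = labels[idx]
        if y.min() == y.max():
            return None
        return _auc(scores[idx], y)

    values = _bootstrap_metric(one, len(scores), n_boot, seed)
    return _summarise("auc", values, n_boot, observed=_auc(scores, labels))


def _f1(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> float:
    pred = scores > cutoff
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def f1_reference_value(prevalence: float) -> float:
    """Expected f1 of the best label-independent rule (predict always
    positive): 2*pi / (1 + pi) for prevalence pi."""
    return 2 * prevalence / (1 + prevalence)


def f1_with_cutoff(
    scores,
    labels,
    mode: str = "fit",
    cutoff: float | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[float, EvalReport]:
    """Cutoff-optimised f1 with bootstrap CI.

    Fit mode scans the observed-score midpoints: eligible cutoffs have
    median bootstrap f1 above the random-model reference 2*pi/(1+pi); among
    them the one with the highest CI lower bound wins.  Apply mode reuses a
    stored cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    n = len(scores)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    if mode == "apply":
        if cutoff is None:
            raise ModelError("apply mode needs a stored cutoff")
        vals = np.array([_f1(scores[i], labels[i], cutoff) for i in boot_idx])
        return cutoff, _summarise(
            "f1", vals, n_boot, cutoff=cutoff, observed=_f1(scores, labels, cutoff)
        )
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ModelError("cannot place a cutoff: all scores identical")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    ref = f1_reference_value(labels.mean())
    boots = np.empty((len(candidates), n_boot))
    for b, idx in enumerate(boot_idx):
        s, y = scores[idx], labels[idx]
        for c, cut in enumerate(candidates):
            boots[c, b] = _f1(s, y, cut)
    medians = np.median(boots, axis=1)
    lowers = np.percentile(boots, 2.5, axis=1)
    eligible = medians > ref
    flagged = not eligible.any()
    pool = np.where(eligible)[0] if not flagged else np.arange(len(candidates))
    if flagged:
        warnings.warn("no cutoff with median f1 above the reference value")
    best = pool[np.argmax(lowers[pool])]
    cut = float(candidates[best])
    report = _summarise(
        "f1",
        boots[best],
        n_boot,
        cutoff=cut,
        reference=ref,
        eligible=bool(not flagged),
        observed=_f1(scores, labels, cut),
    )
    return cut, report


def concordance(
    risk, time, event, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> EvalReport:
    """Harrell's C (higher risk should mean earlier event; risk ties count 1/2)."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    try:
        observed = _harrell_c(time, -risk, event)
    except ZeroDivisionError:
        raise ModelError("no comparable pairs")

    def one(idx):
        try:
            return _harrell_c(time[idx], -risk[idx], event[idx])
        except ZeroDivisionError:
            return None

    values = _bootstrap_metric(one, len(risk), n_boot, seed)
    return _summarise("c_index", values, n_boot, observed=float(observed))


def hosmer_lemeshow(probabilities, outcomes, g: int = 10) -> tuple[float, float]:
    """HL decile-of-risk calibration test; returns (chi2, p) with df = g - 2.

    Probability ties stay in one group; groups whose expected count is
    degenerate are merged with a neighbour.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if g < 2 or len(p) < 2 * g:
        raise ModelError("need g >= 2 and n >= 2g for the HL test")
    try:
        groups = pd.qcut(p, q=g, duplicates="drop", labels=False)
        groups = np.nan_to_num(np.asarray(groups, dtype=float), nan=0.0).astype(int)
    except ValueError:
        groups = np.zeros(len(p), dtype=int)
    chi2 = 0.0
    used = 0
    merged = 0
    pending_o = pending_e = pending_n = 0.0
    for grp in np.unique(groups):
        sel = groups == grp
        n_g = sel.sum() + pending_n
        obs = y[sel].sum() + pending_o
        exp = p[sel].sum() + pending_e
        var = exp * (1 - exp / n_g)
        if var <= 1e-12:  # degenerate expectation: merge into the next group
            pending_o, pending_e, pending_n = obs, exp, n_g
            merged += 1
            continue
        pending_o = pending_e = pending_n = 0.0
        chi2 += (obs - exp) ** 2 / var
        used += 1
    if merged:
        warnings.warn(f"{merged} degenerate HL groups merged")
    df = used - 2
    if df < 1:
        return float(chi2), 1.0
    return float(chi2), float(stats.chi2.sf(chi2, df))


def _km_at(time: np.ndarray, event: np.ndarray, horizon: float) -> tuple[float, float]:
    """Kaplan-Meier survival and Greenwood variance at ``horizon``."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    s = float(kmf.predict(horizon))
    # Greenwood: Var = S^2 * sum d/(n(n-d)) over event times <= horizon
    tab = kmf.event_table
    tab = tab[tab.index <= horizon]
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    ok = (d > 0) & (n > d)
    gsum = float((d[ok] / (n[ok] * (n[ok] - d[ok]))).sum())
    return s, s**2 * gsum


def gnd_calibration(
    predicted_survival,
    time,
    event,
    groups=None,
    n_groups: int = 10,
    horizon: float = 24.0,
) -> tuple[float, float, pd.DataFrame]:
    """Greenwood-Nam-d'Agostino calibration test at ``horizon``.

    ``predicted_survival``: model survival probability at the horizon per
    patient.  Patients are grouped by predicted risk deciles unless
    ``groups`` is given; groups with fewer than 2 events by the horizon are
    merged with the neighbouring group.  Returns (chi2, p, per-group table).
    """
    s_pred = np.asarray(predicted_survival, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if not ((time <= horizon) & (event == 1)).any():
        raise ModelError("no events before the calibration horizon")
    if groups is None:
        groups = pd.qcut(s_pred, q=n_groups, duplicates="drop", labels=False)
    groups = np.asarray(groups)
    order = np.unique(groups)
    if len(order) < 2:
        raise ModelError("GND test needs at least 2 risk groups")
    # merge groups until each has >= 2 events by the horizon and a
    # non-degenerate Greenwood variance (the KM tail artifact of a small
    # group whose last at-risk patient has an event yields S = 0, var = 0)
    merged_groups = []
    bucket: list[int] = []
    for grp in order:
        bucket.append(grp)
        sel = np.isin(groups, bucket)
        n_ev = int(((time <= horizon) & (event == 1) & sel).sum())
        if n_ev < 2:
            continue
        s_obs, var = _km_at(time[sel], event[sel], horizon)
        if var > 1e-10:
            merged_groups.append(tuple(bucket))
            bucket = []
    if bucket:
        if merged_groups:
            merged_groups[-1] = merged_groups[-1] + tuple(bucket)
        else:
            raise ModelError("fewer than 2 events at the horizon in every group")
    if len(merged_groups) < 2:
        raise ModelError("GND test undefined with a single group after merging")
    rows = []
    chi2 = 0.0
    for bucket in merged_groups:
        sel = np.isin(groups, bucket)
        s_obs, var = _km_at(time[sel], event[sel], horizon)
        s_exp = float(s_pred[sel].mean())
        if var <= 1e-12:
            var = max(var, 1e-12)
        chi2 += (s_obs - s_exp) ** 2 / var
        rows.append(
            {"group": bucket[0], "n": int(sel.sum()), "observed": s_obs, "expected": s_exp}
        )
    df = len(merged_groups) - 1
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), p, pd.DataFrame(rows)


def km_logrank(time, event, group) -> tuple[dict, float, float]:
    """Kaplan-Meier curves per group + log-rank test (chi2, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    curves = {}
    for g in np.unique(group):
        sel = group == g
        if not sel.any():
            raise ModelError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=str(g))
        curves[g] = kmf
    if len(curves) < 2:
        raise ModelError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(time, group, event)
    return curves, float(res.test_statistic), float(res.p_value)


def stratification_threshold(
    risk,
    time,
    event,
    mode: str = "fit",
    rule: StratificationRule | None = None,
) -> tuple[StratificationRule, float]:
    """Risk threshold optimised on discovery; frozen for validation.

    Fit mode scans midpoints of observed risks between the 10th and 90th
    percentiles and keeps the one minimising the discovery log-rank p
    (ties -> smallest threshold).  Apply mode splits at the stored
    threshold and reports the log-rank p of that split.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if mode == "apply":
        if rule is None:
            raise ModelError("apply mode needs a stored rule")
        groups = (risk > rule.threshold).astype(int)
        if groups.min() == groups.max():
            warnings.warn("threshold puts every patient in one group")
            return rule, 1.0
        _, _, p = km_logrank(time, event, groups)
        return rule, p
    if np.unique(risk).size < 2:
        raise ModelError("all risks equal; no threshold possible")
    lo, hi = np.percentile(risk, [10, 90])
    uniq = np.unique(risk)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = mids[(mids >= lo) & (mids <= hi)]
    if candidates.size == 0:
        candidates = np.array([float(np.median(risk))])
    best_p, best_t = np.inf, float(candidates[0])
    for t in candidates:
        groups = (risk > t).astype(int)
        if groups.min() == groups.max():
            continue
        _, _, p = km_logrank(time, event, groups)
        if p < best_p:  # strict: ties keep the smallest threshold
            best_p, best_t = p, float(t)
    return StratificationRule(best_t), float(best_p)


def schoenfeld_ph_test(
    cox_results, X: pd.DataFrame, time, event
) -> pd.DataFrame:
    """Grambsch-Therneau proportional-hazards test (KM time transform).

    Scaled Schoenfeld residuals are regressed on the Kaplan-Meier-transformed
    event times; returns a per-covariate chi2/p table plus a GLOBAL row.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    d = int(event.sum())
    if d <= X.shape[1]:
        raise ModelError("fewer events than covariates; PH test undefined")
    cph = getattr(cox_results, "_lifelines", None)
    if cph is None:
        raise ModelError("needs results from a fitted CoxPH model")
    df = X.copy().reset_index(drop=True)
    df["time"] = time
    df["event"] = event
    resid = cph.compute_residuals(df, kind="schoenfeld")
    # order residual rows by their subject's event time
    subj = resid.index.get_level_values(0) if isinstance(resid.index, pd.MultiIndex) else resid.index
    order = np.argsort(time[np.asarray(subj, dtype=int)], kind="stable")
    resid = resid.iloc[order]
    event_times = np.sort(time[event == 1])
    # KM transform g(t) = 1 - S_KM(t-) on the full sample
    kmf = KaplanMeierFitter().fit(time, event)
    surv = kmf.survival_function_["KM_estimate"]
    g = 1.0 - np.interp(event_times, surv.index.to_numpy(), surv.to_numpy())
    z = g - g.mean()
    s = resid[list(X.columns)].to_numpy()  # d x p, ordered by event time
    V = cph.variance_matrix_.to_numpy()
    # scaled residuals s* = d V s; test statistic per Grambsch-Therneau:
    # T_j = [sum z s*_j]^2 / (d V_jj sum z^2),  global u*' (d sum z^2 V)^-1 u*
    u = s.T @ z
    u_star = d * V @ u
    sz2 = float((z**2).sum())
    rows = {}
    for j, name in enumerate(X.columns):
        chi2 = u_star[j] ** 2 / (d * V[j, j] * sz2)
        rows[name] = {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, 1)), "df": 1}
    chi2_g = float(u_star @ np.linalg.solve(d * sz2 * V, u_star))
    rows["GLOBAL"] = {
        "chi2": chi2_g,
        "p": float(stats.chi2.sf(chi2_g, X.shape[1])),
        "df": X.shape[1],
    }
    return pd.DataFrame.from_dict(rows, orient="index")
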