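"""Estimation and metric primitives: clustered/stratified Cox, Fine-Gray,
proportional-hazards diagnostics, cumulative incidence, Harrell's C, and
IPCW time-varying AUC.

Marginal and stratified Cox models are fitted with lifelines (Efron ties;
pair-clustered sandwich variance via ``cluster_col``).  Fine-Gray regression
is the package's own IPCW-weighted Breslow solver (:mod:`twinsurv._finegray`).
Outcomes are DataFrames with columns ``time`` (> 0) and ``event``
(0 censored, 1 event of interest, 2 competing death), indexed by subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from sksurv.metrics import concordance_index_censored

from ._finegray import censoring_survival, fit_fine_gray_engine

__all__ = [
    "CoxFit",
    "FineGrayFit",
    "PhTestResult",
    "ConcordanceResult",
    "AucCurve",
    "CifCurve",
    "fit_cox",
    "fit_stratified_cox",
    "fit_fine_gray",
    "ph_test",
    "cumulative_incidence",
    "harrells_c",
    "time_varying_auc",
]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray  # log hazard ratios
    robust_se: np.ndarray
    naive_se: np.ndarray
    n_events: int
    ties_method: str = "efron"
    converged: bool = True
    loglik: float | None = None
    loglik_null: float | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.robust_se

    @property
    def p_value(self) -> np.ndarray:
        z = self.wald_z
        p = 2.0 * stats.norm.sf(np.abs(z))
        return np.where(np.isfinite(z), p, np.nan)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": self.hr,
                "robust_se": self.robust_se,
                "p": self.p_value,
            },
            index=self.names,
        )


@dataclass
class FineGrayFit(CoxFit):
    ties_method: str = "breslow"
    censoring_weights_model: str = "overall Kaplan-Meier"
    event_times: np.ndarray = field(default_factory=lambda: np.array([]))
    baseline_cumhaz: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def shr(self) -> np.ndarray:
        return np.exp(self.coef)

    def cif(self, t: float, x: np.ndarray) -> float:
        """Model-based cause-1 cumulative incidence at time t for covariates x."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        lam0 = self.baseline_cumhaz[idx] if idx >= 0 else 0.0
        return 1.0 - np.exp(-lam0 * np.exp(np.asarray(x, float) @ self.coef))


@dataclass
class PhTestResult:
    names: list[str]
    statistic: np.ndarray
    p_value: np.ndarray
    time_transform: str = "km"


@dataclass
class ConcordanceResult:
    c_index: float
    n_concordant: int
    n_discordant: int
    n_tied: int

    @property
    def n_comparable(self) -> int:
        return self.n_concordant + self.n_discordant + self.n_tied


@dataclass
class AucCurve:
    horizons: np.ndarray
    auc: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    weighting: str = "IPCW (censoring Kaplan-Meier); competing events as controls"


@dataclass
class CifCurve:
    times: np.ndarray  # step locations (event times), increasing
    cif: np.ndarray  # right-continuous step values

    def at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        vals = np.where(idx >= 0, self.cif[np.clip(idx, 0, None)], 0.0)
        return vals


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _validate(outcomes: pd.DataFrame, X: pd.DataFrame) -> None:
    if not outcomes.index.equals(X.index):
        bad = outcomes.index.symmetric_difference(X.index).tolist()
        raise ValueError(f"outcomes and covariates misaligned on ids: {bad[:10]}")
    if not np.all(np.isfinite(X.to_numpy(dtype=float))):
        raise ValueError("covariates must be finite")


def _score_sign_at_null(time, delta, x) -> float:
    """Sign of the partial-likelihood score at beta=0 for one covariate."""
    order = np.argsort(-time, kind="stable")
    t, d, xs = time[order], delta[order], x[order]
    csum = np.cumsum(xs)
    cnt = np.arange(1, len(xs) + 1)
    u = float(np.sum((xs - csum / cnt)[d]))
    return np.sign(u) if u != 0 else 1.0


def _flagged_fit(names, time, delta, X, n_events) -> CoxFit:
    coef = np.array(
        [
            _score_sign_at_null(time, delta, X[:, j]) * np.inf
            for j in range(X.shape[1])
        ]
    )
    nan = np.full(X.shape[1], np.nan)
    return CoxFit(
        names=list(names), coef=coef, robust_se=nan, naive_se=nan,
        n_events=n_events, converged=False,
    )


# --------------------------------------------------------------------------
# model fits
# --------------------------------------------------------------------------

def fit_cox(
    outcomes: pd.DataFrame,
    X: pd.DataFrame,
    cluster: np.ndarray | pd.Series | None = None,
    event_of_interest: int = 1,
) -> CoxFit:
    """Marginal Cox model with Efron ties and cluster-robust sandwich variance.

    Competing deaths are treated as censoring on the cause-specific hazard
    scale.  A monotone partial likelihood (perfect separation) yields a
    flagged fit with infinite coefficients rather than an exception.
    """
    _validate(outcomes, X)
    time = outcomes["time"].to_numpy(dtype=float)
    delta = (outcomes["event"].to_numpy() == event_of_interest)
    n_events = int(delta.sum())
    if n_events < 1:
        raise ValueError("no events of interest")
    Xa = X.to_numpy(dtype=float)
    if np.any(Xa.std(axis=0) == 0):
        bad = X.columns[np.flatnonzero(Xa.std(axis=0) == 0)].tolist()
        raise ValueError(f"covariates with zero variance carry no information: {bad}")

    df = X.copy()
    df["__time"] = time
    df["__event"] = delta.astype(int)
    if cluster is None:
        cluster = np.arange(len(df))
    df["__cluster"] = np.asarray(cluster)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="__time",
                event_col="__event",
                cluster_col="__cluster",
                fit_options={"precision": 1e-9, "max_steps": 500},
            )
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return _flagged_fit(X.columns, time, delta, Xa, n_events)

    coef = cph.params_.to_numpy()
    robust_se = cph.standard_errors_.to_numpy()
    if np.any(np.abs(coef) > 15):  # practically monotone likelihood
        return _flagged_fit(X.columns, time, delta, Xa, n_events)
    return CoxFit(
        names=list(X.columns),
        coef=coef,
        robust_se=robust_se,
        naive_se=np.full(len(coef), np.nan),
        n_events=n_events,
    )


def _paired_conditional_cox(time, delta, Xa, strata, names) -> CoxFit:
    """Exact stratified partial likelihood when every stratum has <= 2 members.

    For a twin pair the stratified Cox contribution reduces to a softmax over
    the two members at the first failure time (Breslow for a within-pair tie),
    so the fit is a small Newton iteration over closed-form terms — orders of
    magnitude faster than a generic stratified solver at thousands of pairs.
    """
    A_rows, B_rows = [], []
    order = np.argsort(strata, kind="stable")
    s_sorted = strata[order]
    boundaries = np.flatnonzero(
        np.r_[True, s_sorted[1:] != s_sorted[:-1], True]
    )
    for k in range(len(boundaries) - 1):
        idx = order[boundaries[k]:boundaries[k + 1]]
        if len(idx) != 2:
            continue  # singleton stratum: risk set of one carries no information
        i, j = idx
        if time[i] > time[j]:
            i, j = j, i
        if time[i] < time[j]:
            if delta[i]:
                A_rows.append(Xa[i]); B_rows.append(Xa[j])
        else:  # tied within pair: Breslow gives one term per event
            if delta[i]:
                A_rows.append(Xa[i]); B_rows.append(Xa[j])
            if delta[j]:
                A_rows.append(Xa[j]); B_rows.append(Xa[i])
    if not A_rows:
        raise ValueError("no informative strata (within-pair discordance required)")
    A = np.asarray(A_rows)
    B = np.asarray(B_rows)
    D = A - B
    if np.allclose(D, 0):
        raise ValueError("no informative strata (within-pair discordance required)")

    p = A.shape[1]
    beta = np.zeros(p)

    def loglik(b):
        # log softmax of the failing member within the pair
        return float(np.sum(-np.log1p(np.exp(-D @ b))))

    converged = False
    with np.errstate(over="ignore"):
        for _ in range(60):
            eta = D @ beta
            pA = 1.0 / (1.0 + np.exp(-eta))
            grad = D.T @ (1.0 - pA)
            w = pA * (1.0 - pA)
            hess = -(D * w[:, None]).T @ D
            try:
                step = np.linalg.solve(hess, -grad)
            except np.linalg.LinAlgError:
                return _flagged_fit(names, time, delta, Xa, int(delta.sum()))
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                converged = True
                break
        if np.max(np.abs(beta)) > 15:
            return _flagged_fit(names, time, delta, Xa, int(delta.sum()))
        eta = D @ beta
        pA = 1.0 / (1.0 + np.exp(-eta))
        w = pA * (1.0 - pA)
        info = (D * w[:, None]).T @ D
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    return CoxFit(
        names=list(names), coef=beta, robust_se=se, naive_se=se,
        n_events=int(delta.sum()), ties_method="breslow",
        converged=converged, loglik=loglik(beta), loglik_null=loglik(np.zeros(p)),
    )


def fit_stratified_cox(
    outcomes: pd.DataFrame,
    X: pd.DataFrame,
    strata: np.ndarray | pd.Series,
    event_of_interest: int = 1,
) -> CoxFit:
    """Cox model with stratum-specific baseline hazards (matched analysis).

    Only strata with at least one event and within-stratum covariate
    variation contribute; with none, the matched design carries no
    information and an error is raised.  Pair-sized strata (the cotwin
    design) use an exact closed-form conditional likelihood; larger strata
    fall back to the generic lifelines solver.
    """
    _validate(outcomes, X)
    strata = np.asarray(strata)
    time = outcomes["time"].to_numpy(dtype=float)
    delta = outcomes["event"].to_numpy() == event_of_interest
    Xa = X.to_numpy(dtype=float)

    counts = pd.Series(strata).value_counts()
    if counts.max() <= 2:
        return _paired_conditional_cox(time, delta, Xa, strata, X.columns)

    informative = 0
    for s in pd.unique(strata):
        m = strata == s
        if delta[m].any() and np.any(Xa[m].std(axis=0) > 0):
            informative += 1
    if informative == 0:
        raise ValueError("no informative strata (within-pair discordance required)")

    df = X.copy()
    df["__time"] = time
    df["__event"] = delta.astype(int)
    df["__stratum"] = strata
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="__time",
                event_col="__event",
                strata="__stratum",
                fit_options={"precision": 1e-9, "max_steps": 500},
            )
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return _flagged_fit(X.columns, time, delta, Xa, int(delta.sum()))
    coef = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    if np.any(np.abs(coef) > 15):
        return _flagged_fit(X.columns, time, delta, Xa, int(delta.sum()))
    return CoxFit(
        names=list(X.columns), coef=coef, robust_se=se, naive_se=se,
        n_events=int(delta.sum()),
    )


def fit_fine_gray(
    outcomes: pd.DataFrame,
    X: pd.DataFrame,
    cluster: np.ndarray | pd.Series | None = None,
) -> FineGrayFit:
    """Fine-Gray subdistribution hazards regression with pair-clustered variance."""
    _validate(outcomes, X)
    ev = outcomes["event"].to_numpy()
    if not np.isin(ev, (0, 1, 2)).all():
        raise ValueError("event codes must be in {0, 1, 2}")
    res = fit_fine_gray_engine(
        outcomes["time"].to_numpy(dtype=float),
        ev,
        X.to_numpy(dtype=float),
        cluster=None if cluster is None else np.asarray(cluster),
    )
    return FineGrayFit(
        names=list(X.columns),
        coef=res.coef,
        robust_se=np.sqrt(np.diag(res.cov)),
        naive_se=np.sqrt(np.diag(res.naive_cov)),
        n_events=res.n_events,
        converged=res.converged,
        event_times=res.event_times,
        baseline_cumhaz=res.baseline_cumhaz,
    )


def ph_test(
    outcomes: pd.DataFrame,
    X: pd.DataFrame,
    event_of_interest: int = 1,
    time_transform: str = "km",
) -> PhTestResult:
    """Grambsch-Therneau score test on scaled Schoenfeld residuals."""
    _validate(outcomes, X)
    delta = outcomes["event"].to_numpy() == event_of_interest
    if delta.sum() < 2:
        raise ValueError("proportional-hazards test requires at least 2 events")
    df = X.copy()
    df["__time"] = outcomes["time"].to_numpy(dtype=float)
    df["__event"] = delta.astype(int)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="__time", event_col="__event")
        res = proportional_hazard_test(cph, df, time_transform=time_transform)
    summ = res.summary
    stat = summ["test_statistic"].to_numpy(dtype=float)
    p = summ["p"].to_numpy(dtype=float)
    return PhTestResult(
        names=list(summ.index.get_level_values(0)) if summ.index.nlevels > 1
        else list(summ.index),
        statistic=stat,
        p_value=p,
        time_transform=time_transform,
    )


# --------------------------------------------------------------------------
# nonparametric estimators and metrics
# --------------------------------------------------------------------------

def cumulative_incidence(outcomes: pd.DataFrame, cause: int = 1) -> CifCurve:
    """Aalen-Johansen cumulative incidence for one cause.

    CIF_c(t) = sum over event times u <= t of S(u-) d_c(u)/n(u), with S the
    all-cause Kaplan-Meier.  With no censoring this is the empirical
    subdistribution function.
    """
    if len(outcomes) == 0:
        raise ValueError("empty outcomes")
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=int)
    n = len(time)
    uniq = np.unique(time)
    s_prev = 1.0
    cif = 0.0
    times_out, cif_out = [], []
    for tk in uniq:
        at_risk = int(np.sum(time >= tk))
        here = time == tk
        d_all = int(np.sum(here & (event > 0)))
        d_c = int(np.sum(here & (event == cause)))
        if d_c and at_risk:
            cif += s_prev * d_c / at_risk
            times_out.append(tk)
            cif_out.append(cif)
        if d_all and at_risk:
            s_prev *= 1.0 - d_all / at_risk
    if not times_out:
        return CifCurve(times=np.array([np.inf]), cif=np.array([0.0]))
    return CifCurve(times=np.asarray(times_out), cif=np.asarray(cif_out))


def harrells_c(
    times: np.ndarray, events: np.ndarray, scores: np.ndarray
) -> ConcordanceResult:
    """Harrell's concordance over comparable pairs; score ties count 0.5."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    scores = np.asarray(scores, float)
    if not (len(times) == len(events) == len(scores)):
        raise ValueError("times, events and scores must have equal length")
    cindex, conc, disc, tied_risk, _tied_time = concordance_index_censored(
        events, times, scores
    )
    return ConcordanceResult(
        c_index=float(cindex),
        n_concordant=int(conc),
        n_discordant=int(disc),
        n_tied=int(tied_risk),
    )


def time_varying_auc(
    outcomes: pd.DataFrame,
    scores: np.ndarray,
    horizons,
    event_of_interest: int = 1,
) -> AucCurve:
    """Cumulative-cases/dynamic-controls AUC(t) with IPCW.

    Cases at horizon t are subjects with the event of interest by t; controls
    are subjects still event-free at t plus subjects with a competing event
    by t (known never to develop the event of interest).  Case and
    competing-control weights are 1/G(T_i-), event-free controls 1/G(t),
    with G the censoring Kaplan-Meier.  The CI is a Hanley-McNeil normal
    approximation on IPCW-effective case/control counts.
    """
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=int)
    scores = np.asarray(scores, float)
    horizons = np.atleast_1d(np.asarray(horizons, float))
    if np.any(horizons > time.max()):
        raise ValueError("horizons must lie within observed follow-up")
    g_minus = censoring_survival(time, event)
    g_own = g_minus(time)

    aucs, lo, hi = [], [], []
    for t in horizons:
        case = (event == event_of_interest) & (time <= t)
        ctrl_free = time > t
        ctrl_compete = (event == 2) & (event_of_interest != 2) & (time <= t)
        ctrl = ctrl_free | ctrl_compete
        if case.sum() == 0 or ctrl.sum() == 0:
            aucs.append(np.nan); lo.append(np.nan); hi.append(np.nan)
            continue
        w_case = 1.0 / g_own[case]
        gt = float(g_minus(np.array([np.nextafter(t, np.inf)]))[0])
        w_ctrl = np.where(ctrl_free[ctrl], 1.0 / gt, 1.0 / g_own[ctrl])
        sc, st = scores[case], scores[ctrl]
        gt_mat = (sc[:, None] > st[None, :]).astype(float)
        gt_mat += 0.5 * (sc[:, None] == st[None, :])
        wmat = w_case[:, None] * w_ctrl[None, :]
        auc = float((wmat * gt_mat).sum() / wmat.sum())
        n1 = float(w_case.sum() ** 2 / np.sum(w_case**2))
        n2 = float(w_ctrl.sum() ** 2 / np.sum(w_ctrl**2))
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (
            auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)
        ) / (n1 * n2)
        se = np.sqrt(max(var, 0.0))
        aucs.append(auc)
        lo.append(max(0.0, auc - 1.96 * se))
        hi.append(min(1.0, auc + 1.96 * se))
    return AucCurve(
        horizons=horizons,
        auc=np.asarray(aucs),
        ci_lower=np.asarray(lo),
        ci_upper=np.asarray(hi),
    )
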