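"""Fine-Gray subdistribution hazards regression via IPCW-weighted Cox.

Subjects who fail from the competing cause remain in the cause-1 risk set
with time-varying inverse-probability-of-censoring weights
w_i(t) = G(t-)/G(T_i-), where G is the Kaplan-Meier estimator of the
censoring distribution (overall, not covariate-stratified).  Estimation is a
Newton-Raphson maximisation of the weighted Breslow partial likelihood; the
variance is a cluster sandwich over weighted score residuals, treating the
censoring weights as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def censoring_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier of the censoring distribution; returns G(t-) evaluator.

    Censorings (event == 0) are the "events" here; failures of any cause are
    treated as censored observations of the censoring time.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    surv = []
    g = 1.0
    n_at_risk = n
    counts_end = np.append(start[1:], n)
    for k, tk in enumerate(uniq):
        block = slice(start[k], counts_end[k])
        d_cens = int(np.sum(e[block] == 0))
        if d_cens and n_at_risk > 0:
            g *= 1.0 - d_cens / n_at_risk
        surv.append(g)
        n_at_risk -= counts_end[k] - start[k]
    uniq = np.asarray(uniq)
    surv = np.asarray(surv)

    def g_minus(ts: np.ndarray) -> np.ndarray:
        """Left limit G(t-): value of G just before each query time."""
        idx = np.searchsorted(uniq, np.asarray(ts, float), side="left") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return np.maximum(out, 1e-12)

    return g_minus


@dataclass
class FineGrayEngineResult:
    coef: np.ndarray
    cov: np.ndarray  # cluster-sandwich covariance
    naive_cov: np.ndarray
    loglik: float
    n_events: int
    converged: bool
    event_times: np.ndarray  # distinct cause-1 times
    baseline_cumhaz: np.ndarray  # Breslow cumulative subdistribution hazard


def fit_fine_gray_engine(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    cluster: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> FineGrayEngineResult:
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if not np.any(event == 1):
        raise ValueError("no cause-1 events: Fine-Gray model is not estimable")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("covariate with zero variance carries no information")

    g_minus = censoring_survival(time, event)
    t_events = np.unique(time[event == 1])
    K = len(t_events)
    # d[k]: multiplicity (Breslow ties); D: n x K indicator of failing at t_k
    D = (event == 1)[:, None] & (time[:, None] == t_events[None, :])
    d = D.sum(axis=0).astype(float)

    # weight matrix W[i, k]: subject i's IPCW weight in the risk set at t_k
    g_at_events = g_minus(t_events)  # G(t_k-)
    g_at_own = g_minus(time)  # G(T_i-)
    under_obs = time[:, None] >= t_events[None, :]
    past_compete = ((event == 2)[:, None]) & (time[:, None] < t_events[None, :])
    W = under_obs.astype(float) + past_compete * (
        g_at_events[None, :] / g_at_own[:, None]
    )

    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        r = np.exp(eta - eta.max())
        wr = W * r[:, None]
        S0 = wr.sum(axis=0)
        S1 = wr.T @ X
        xbar = S1 / S0[:, None]  # K x p
        U = (D.sum(axis=1) @ X) - d @ xbar
        # information: sum_k d_k (S2/S0 - xbar xbar')
        I = np.zeros((p, p))
        for k in range(K):
            Xc = X - xbar[k]
            I += d[k] * (Xc.T @ (wr[:, k][:, None] * Xc)) / S0[k]
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            raise ValueError("singular information matrix in Fine-Gray fit")
        # step-halving on the exact log-likelihood
        ll_cur = _loglik(beta, X, W, D, d)
        alpha = 1.0
        for _h in range(30):
            cand = beta + alpha * step
            if _loglik(cand, X, W, D, d) >= ll_cur - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        if np.max(np.abs(alpha * step)) < tol:
            converged = True
            break

    eta = X @ beta
    r = np.exp(eta - eta.max())
    wr = W * r[:, None]
    S0 = wr.sum(axis=0)
    xbar = (wr.T @ X) / S0[:, None]
    I = np.zeros((p, p))
    for k in range(K):
        Xc = X - xbar[k]
        I += d[k] * (Xc.T @ (wr[:, k][:, None] * Xc)) / S0[k]
    naive_cov = np.linalg.inv(I)

    # score residuals: A[i,k] = dN_i(t_k) - w_ik r_i dLam_k
    dlam = d / S0
    A = D.astype(float) - wr * dlam[None, :]
    resid = X * A.sum(axis=1)[:, None] - A @ xbar  # n x p
    if cluster is None:
        cluster = np.arange(n)
    _, codes = np.unique(np.asarray(cluster), return_inverse=True)
    n_cl = codes.max() + 1
    Uc = np.zeros((n_cl, p))
    np.add.at(Uc, codes, resid)
    meat = Uc.T @ Uc
    cov = naive_cov @ meat @ naive_cov

    # scale-corrected baseline (exp shift cancelled): recompute S0 exactly
    S0_exact = (W * np.exp(X @ beta)[:, None]).sum(axis=0)
    baseline_cumhaz = np.cumsum(d / S0_exact)
    return FineGrayEngineResult(
        coef=beta,
        cov=cov,
        naive_cov=naive_cov,
        loglik=_loglik(beta, X, W, D, d),
        n_events=int(d.sum()),
        converged=converged,
        event_times=t_events,
        baseline_cumhaz=baseline_cumhaz,
    )


def _loglik(beta, X, W, D, d):
    eta = X @ beta
    S0 = (W * np.exp(eta - eta.max())[:, None]).sum(axis=0)
    # the max-shift adds d.sum()*max(eta) to both terms; keep it consistent
    event_term = float(np.sum(eta[D.any(axis=1)]) - d.sum() * eta.max())
    return event_term - float(d @ np.log(S0))
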