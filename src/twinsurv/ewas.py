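"""Per-CpG dual-model survival screen with FDR control and the dual p-rule.

Each CpG is tested twice against time to the event of interest: a marginal
Cox model (cause-specific hazard scale, competing deaths censored) and a
Fine-Gray model (subdistribution/risk scale), both with pair-clustered
sandwich variance.  Benjamini-Hochberg FDR is applied separately per scale;
a CpG is significant when FDR < 0.05 on both scales AND its unadjusted
p-values fall below the dual threshold (1e-7 at genome scale) on both
scales.  The proportional-hazards assumption is then checked, on the Cox
scale, for the significant CpGs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import survival

logger = logging.getLogger(__name__)

__all__ = ["EwasConfig", "bh_adjust", "run_ewas", "select_markers"]


@dataclass(frozen=True)
class EwasConfig:
    fdr_threshold: float = 0.05
    dual_p_threshold: float = 1e-7
    ph_alpha: float = 0.05
    event_of_interest: int = 1

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "dual_p_threshold", "ph_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ewas(
    residuals: pd.DataFrame,
    outcomes: pd.DataFrame,
    cohort: pd.DataFrame,
    config: EwasConfig = EwasConfig(),
) -> pd.DataFrame:
    """Screen every CpG with paired Cox and Fine-Gray fits.

    Returns one row per CpG (ordered by Fine-Gray p-value) with columns
    cpg_id, hr, hr_p, shr, shr_p, fdr_hr, fdr_shr, ph_p, significant, ph_ok.
    ``ph_p``/``ph_ok`` are populated only for significant CpGs.
    """
    if residuals.shape[1] == 0:
        raise ValueError("empty residual matrix")
    if not residuals.index.equals(outcomes.index) or not residuals.index.equals(
        cohort.index
    ):
        bad = (
            residuals.index.symmetric_difference(outcomes.index)
            .union(residuals.index.symmetric_difference(cohort.index))
            .tolist()
        )
        raise ValueError(f"misaligned sample ids: {bad[:10]}")
    cluster = cohort["pair_id"].to_numpy()

    rows = []
    for j, cpg in enumerate(residuals.columns):
        X = residuals.iloc[:, [j]]
        try:
            cfit = survival.fit_cox(
                outcomes, X, cluster=cluster,
                event_of_interest=config.event_of_interest,
            )
            hr, hr_p = float(cfit.hr[0]), float(cfit.p_value[0])
            if not cfit.converged:
                hr_p = np.nan
        except ValueError:
            hr, hr_p = np.nan, np.nan
        try:
            gfit = survival.fit_fine_gray(outcomes, X, cluster=cluster)
            shr, shr_p = float(gfit.shr[0]), float(gfit.p_value[0])
            if not gfit.converged:
                shr_p = np.nan
        except ValueError:
            shr, shr_p = np.nan, np.nan
        rows.append((cpg, hr, hr_p, shr, shr_p))
        if (j + 1) % 200 == 0:
            logger.info("EWAS screen: %d/%d CpGs done", j + 1, residuals.shape[1])

    table = pd.DataFrame(rows, columns=["cpg_id", "hr", "hr_p", "shr", "shr_p"])
    for scale in ("hr", "shr"):
        p = table[f"{scale}_p"].to_numpy()
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = bh_adjust(p[ok])
        table[f"fdr_{scale}"] = q

    sig = (
        (table["fdr_hr"] < config.fdr_threshold)
        & (table["fdr_shr"] < config.fdr_threshold)
        & (table["hr_p"] < config.dual_p_threshold)
        & (table["shr_p"] < config.dual_p_threshold)
    ).fillna(False)
    table["significant"] = sig.to_numpy()

    ph_p = np.full(len(table), np.nan)
    for i in np.flatnonzero(table["significant"].to_numpy()):
        cpg = table.at[i, "cpg_id"]
        try:
            res = survival.ph_test(
                outcomes,
                residuals[[cpg]],
                event_of_interest=config.event_of_interest,
            )
            ph_p[i] = float(res.p_value[0])
        except ValueError:
            ph_p[i] = np.nan
    table["ph_p"] = ph_p
    table["ph_ok"] = np.where(
        table["significant"], ph_p >= config.ph_alpha, False
    )

    table = table.sort_values(
        "shr_p", kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return table


def select_markers(table: pd.DataFrame, config: EwasConfig = EwasConfig()) -> list[str]:
    """Significant CpGs that also pass the proportional-hazards check."""
    keep = table[(table["significant"]) & (table["ph_ok"])]
    return keep["cpg_id"].tolist()
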