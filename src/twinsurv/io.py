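"""File contracts: delimited-text tables shared by all pipeline stages.

Methylation matrices travel as (optionally gzipped) TSV with CpGs as rows,
samples as columns and ``NA`` for missing values; phenotype and outcome
tables as CSV with fixed column names.  Readers validate schemas and name
offending rows; writers never mutate their inputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_methylation",
    "read_methylation",
    "write_phenotypes",
    "read_phenotypes",
    "write_outcomes",
    "read_outcomes",
]

PHENOTYPE_COLUMNS = [
    "pair_id", "zygosity", "sex", "age_at_entry", "dataset",
    "frac_monocytes", "frac_lymphocytes", "frac_eosinophils",
    "plate", "position",
]


def write_methylation(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a samples-x-CpGs matrix as CpGs-x-samples TSV (NA = missing).

    Gzipped output pins the gzip header mtime to zero so identical matrices
    produce byte-identical files (the reproducibility manifest hashes them).
    """
    compression = (
        {"method": "gzip", "mtime": 0} if str(path).endswith(".gz") else None
    )
    matrix.T.to_csv(
        path, sep="\t", na_rep="NA", index_label="cpg_id", compression=compression
    )


def read_methylation(path: str | Path, beta_range: bool = True) -> pd.DataFrame:
    """Read a CpGs-x-samples TSV back to samples-x-CpGs.

    ``beta_range=False`` skips the [0,1] check — residual matrices travel in
    the same dialect but are unbounded standardised values.
    """
    df = pd.read_csv(path, sep="\t", index_col="cpg_id", na_values=["NA"])
    out = df.T
    out.index.name = "individual_id"
    if beta_range:
        vals = out.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"beta value out of [0,1] at sample {out.index[i]!r}, "
                f"CpG {out.columns[j]!r}"
            )
    return out


def write_phenotypes(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index_label="individual_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="individual_id")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if not df["zygosity"].isin(["MZ", "DZ"]).all():
        bad = df.index[~df["zygosity"].isin(["MZ", "DZ"])][0]
        raise ValueError(f"invalid zygosity for individual {bad!r}")
    return df


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes.to_csv(path, index_label="individual_id")


def read_outcomes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="individual_id")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"outcome table missing column {col!r}")
    bad = ~df["event"].isin([0, 1, 2])
    if bad.any():
        raise ValueError(
            f"invalid event code {df.loc[bad, 'event'].iloc[0]!r} "
            f"for individual {df.index[bad][0]!r}"
        )
    if (df["time"] <= 0).any():
        raise ValueError(
            f"nonpositive follow-up time for individual "
            f"{df.index[df['time'] <= 0][0]!r}"
        )
    df["event"] = df["event"].astype(int)
    return df
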