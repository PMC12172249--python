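"""Design-matrix assembly from phenotype covariates."""

from __future__ import annotations

import numpy as np
import pandas as pd


def covariate_design(phen: pd.DataFrame, covariates: list[str]):
    """Build (X, names) with an intercept from phenotype columns.

    ``sex`` is coded male=1; categorical columns (``seq_prep``,
    ``site_of_onset``, ``diagnosis``...) become treatment dummies dropping
    the first level in sorted order. Rows must already be complete-case.
    """
    cols = [np.ones(len(phen))]
    names = ["intercept"]
    for cov in covariates:
        s = phen[cov]
        if s.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values; complete-case first")
        if cov == "sex":
            cols.append((s == "male").to_numpy(float))
            names.append("sex_male")
        elif s.dtype.kind in "fiu" or cov in ("age_years", "age_at_onset_years"):
            cols.append(s.to_numpy(float))
            names.append(cov)
        else:
            levels = sorted(s.unique())
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names


def complete_case(phen: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Drop rows with missing values in any of the given columns."""
    return phen.dropna(subset=[c for c in columns if c in phen.columns])
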