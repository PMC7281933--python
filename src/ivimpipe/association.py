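"""Regional medians of IVIM maps regressed against clinical covariates.

Once the group comparison has fixed a region of interest (e.g., the
intersection of significant clusters), each subject contributes one median
parameter value inside that region, and these are correlated with clinical
covariates (cognitive domain Z-scores, disease activity).  Pearson
correlation with the two-sided t-transform p-value is primary because the
downstream report is a linear regression line; Spearman is available as an
option.  Unadjusted p-values are flagged at 0.05 (significant) and 0.1
(trend); a Benjamini-Hochberg column is always emitted alongside.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    parameter: str
    covariate: str
    n: int
    r: float
    p: float
    slope: float
    intercept: float


def regional_median(map3d: np.ndarray, mask: np.ndarray) -> float:
    """Median of masked voxel values; NaN (invalid-fit) voxels are excluded.

    Even counts use the mean of the central pair (numpy convention).
    """
    m = np.asarray(map3d, dtype=float)
    eff = np.asarray(mask, dtype=bool) & np.isfinite(m)
    if not eff.any():
        raise ValueError("empty effective mask: no valid voxels in region")
    return float(np.median(m[eff]))


def correlate(
    values: np.ndarray,
    covariate: np.ndarray,
    parameter: str = "",
    covariate_name: str = "",
    method: str = "pearson",
) -> AssociationResult:
    """Correlation and regression line between per-subject scalars.

    Missing values are dropped pairwise (logged); at least 3 complete pairs
    are required for a defined p-value.  Zero variance in either variable is
    an error (r undefined).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("values and covariate have different lengths")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int(x.size - keep.sum())
    if dropped:
        logger.info(
            "correlate(%s, %s): dropped %d incomplete pairs", parameter, covariate_name, dropped
        )
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    fit = stats.linregress(x, y)
    if method == "pearson":
        r, p = float(fit.rvalue), float(fit.pvalue)
    elif method == "spearman":
        r, p = (float(v) for v in stats.spearmanr(x, y))
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return AssociationResult(
        parameter=parameter,
        covariate=covariate_name,
        n=int(x.size),
        r=r,
        p=p,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def run_association_battery(
    subject_maps: dict[str, dict[str, np.ndarray]],
    region_mask: np.ndarray,
    cohort: pd.DataFrame,
    parameters: tuple[str, ...] = ("vbw", "d", "dstar", "flow"),
    covariates: tuple[str, ...] | None = None,
    group: str | None = "patient",
    method: str = "pearson",
) -> pd.DataFrame:
    """One correlation per parameter x covariate pair over a fixed region.

    ``subject_maps`` maps subject_id -> {parameter -> 3-D map}.  The region
    mask must come from an upstream stage (it is never chosen here).  By
    default only the patient group enters, matching a case-only clinical
    correlation design; pass ``group=None`` for everyone.
    """
    if covariates is None:
        covariates = tuple(
            c for c in cohort.columns if c not in ("subject_id", "group")
        )
    for c in covariates:
        if c not in cohort.columns:
            raise KeyError(f"covariate {c!r} not found in cohort table")
    rows = cohort if group is None else cohort[cohort["group"] == group]
    if len(rows) < 3:
        raise ValueError("fewer than 3 subjects selected for association")
    medians = {
        p: np.array(
            [regional_median(subject_maps[sid][p], region_mask) for sid in rows["subject_id"]]
        )
        for p in parameters
    }
    out = []
    for p in parameters:
        for c in covariates:
            res = correlate(
                medians[p],
                rows[c].to_numpy(dtype=float),
                parameter=p,
                covariate_name=c,
                method=method,
            )
            out.append(
                {
                    "parameter": p,
                    "covariate": c,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                    "slope": res.slope,
                    "intercept": res.intercept,
                }
            )
    table = pd.DataFrame(out)
    from statsmodels.stats.multitest import multipletests

    table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    table["sig_p05"] = table["p"] < 0.05
    table["trend_p10"] = table["p"] < 0.1
    return table[
        ["parameter", "covariate", "n", "r", "p", "p_bh", "slope", "intercept", "sig_p05", "trend_p10"]
    ]
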