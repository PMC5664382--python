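"""Cold-pattern questionnaire scoring and association statistics.

The cold pattern score (CPS) sums eight questionnaire items (aversion
to cold, preference for heat, cold abdomen, cold hands/feet, cold
sensation in the body, pale face, drinking warm water, clear urine),
each rated 1-4, so attainable scores span 8-32; higher means a more
advanced cold pattern.

Associations between facial color features and the CPS are assessed
per region by ordinary least squares (CPS ~ L* + a* + b* + sex + age)
and, per region x channel x questionnaire item, by partial correlation
adjusted for sex and age (Pearson correlation of the two residual
vectors after regressing each variable on the covariates plus an
intercept).  Sex is coded 0 = male, 1 = female; age in years,
uncentred.  Raw two-sided p-values are reported; an optional
Benjamini-Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError, DataError

ITEM_NAMES = (
    "aversion_to_cold",
    "preference_for_heat",
    "cold_abdomen",
    "cold_hands_feet",
    "cold_sensation_in_body",
    "pale_face",
    "drink_warm_water",
    "clear_urine",
)

CPS_MIN, CPS_MAX = 8, 32

SEX_CODES = {"male": 0, "female": 1}


@dataclass(frozen=True)
class QuestionnaireResponse:
    subject_id: str
    items: tuple
    sex: str
    age: float

    def __post_init__(self):
        items = tuple(int(v) for v in self.items)
        if len(items) != 8:
            raise DataError(f"expected 8 items, got {len(items)}")
        bad = [v for v in items if v not in (1, 2, 3, 4)]
        if bad:
            raise DataError(f"item values outside 1..4: {bad}")
        object.__setattr__(self, "items", items)
        if self.sex not in SEX_CODES:
            raise DataError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class CPS:
    subject_id: str
    score: int

    def __post_init__(self):
        if not CPS_MIN <= self.score <= CPS_MAX:
            raise DataError(
                f"CPS {self.score} outside the attainable range "
                f"{CPS_MIN}..{CPS_MAX}")


@dataclass(frozen=True)
class RegressionResult:
    region: str
    coefficients: dict      # term -> B
    p_values: dict          # term -> two-sided p
    r_squared: float
    adjusted_r_squared: float
    n: int


@dataclass(frozen=True)
class PartialCorrelationResult:
    region: str
    channel: str
    item: str
    partial_rho: float
    p_value: float


def compute_cps(response: QuestionnaireResponse) -> CPS:
    """CPS = sum of the eight 1-4 items."""
    return CPS(response.subject_id, int(sum(response.items)))


def ols_fit(y, predictors: pd.DataFrame, region: str = "") -> RegressionResult:
    """OLS with intercept; two-sided t-test p-values; adjusted R^2.

    Raises :class:`CollinearityError` naming the offending columns when
    the design (with intercept) is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise DataError(f"need n > {p + 1} observations for {p} predictors, "
                        f"got n = {n}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        offenders = _collinear_columns(design.to_numpy(), design.columns)
        raise CollinearityError(offenders)
    fit = sm.OLS(y, design).fit()
    coefs = dict(fit.params)
    pvals = dict(fit.pvalues)
    coefs["intercept"] = coefs.pop("const")
    pvals["intercept"] = pvals.pop("const")
    return RegressionResult(
        region=region,
        coefficients={k: float(v) for k, v in coefs.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj),
        n=n,
    )


def _collinear_columns(design: np.ndarray, names) -> list:
    """Columns beyond the numerical rank, via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [str(names[i]) for i in sorted(piv[rank:])]


def partial_correlation(x, y, covariates=None) -> tuple:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on the covariates plus an intercept
    by least squares; rho is the Pearson correlation of the residuals
    and the p-value comes from t = rho*sqrt((n-k-2)/(1-rho^2)) on
    n-k-2 degrees of freedom (k = number of covariates).  With no
    covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise DataError("x and y must have equal length")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 2:
        raise DataError(f"need n > {k + 2} observations, got {n}")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    tol_x = 1e-10 * max(1.0, float(np.linalg.norm(x)))
    tol_y = 1e-10 * max(1.0, float(np.linalg.norm(y)))
    if sx < tol_x or sy < tol_y:
        raise DataError("zero residual variance; partial correlation undefined")
    rho = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if 1.0 - rho * rho <= 0.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df)
    return rho, float(p)


def _join_tables(features: pd.DataFrame, questionnaire: pd.DataFrame):
    """Wide per-subject table (region x channel columns) joined 1:1."""
    feat = features.copy()
    feat["subject_id"] = feat["subject_id"].astype(str)
    q = questionnaire.copy()
    q["subject_id"] = q["subject_id"].astype(str)

    fids = set(feat["subject_id"])
    qids = set(q["subject_id"])
    if fids != qids:
        missing = sorted(fids.symmetric_difference(qids))
        raise DataError(f"subject ids do not join 1:1; unmatched: {missing}")
    if q["subject_id"].duplicated().any():
        dups = sorted(q.loc[q["subject_id"].duplicated(), "subject_id"])
        raise DataError(f"duplicate questionnaire rows for subjects: {dups}")

    wide = feat.pivot(index="subject_id", columns="region",
                      values=["L_star", "a_star", "b_star"])
    q = q.set_index("subject_id").loc[wide.index]
    return wide, q


def run_association(features: pd.DataFrame, questionnaire: pd.DataFrame,
                    bh_adjust: bool = False) -> tuple:
    """Per-region regressions and per-region/channel/item partial correlations.

    ``features`` is the long-format color table (subject_id, region,
    L_star, a_star, b_star, ...); ``questionnaire`` has subject_id, sex,
    age, item1..item8.  Rows with any missing value are dropped listwise.
    Returns two tidy DataFrames mirroring a region x term coefficient
    table and a region x channel x item partial-correlation table, with
    significance flags at p < 0.05 and p < 0.01.
    """
    wide, q = _join_tables(features, questionnaire)

    item_cols = [f"item{i}" for i in range(1, 9)]
    for col in item_cols + ["sex", "age"]:
        if col not in q.columns:
            raise DataError(f"questionnaire table lacks column '{col}'")
    responses = [
        QuestionnaireResponse(sid, tuple(row[item_cols]), row["sex"], row["age"])
        for sid, row in q.iterrows()
    ]
    cps = np.array([compute_cps(r).score for r in responses], dtype=float)
    sex01 = q["sex"].map(SEX_CODES).to_numpy(dtype=float)
    age = q["age"].to_numpy(dtype=float)

    regions = sorted(wide["L_star"].columns)
    reg_rows, pc_rows = [], []
    for region in regions:
        block = pd.DataFrame({
            "L_star": wide[("L_star", region)],
            "a_star": wide[("a_star", region)],
            "b_star": wide[("b_star", region)],
            "sex": sex01,
            "age": age,
        })
        keep = block.notna().all(axis=1) & np.isfinite(cps)
        if keep.sum() <= block.shape[1] + 1:
            raise DataError(f"region '{region}': too few complete subjects "
                            f"({int(keep.sum())})")
        res = ols_fit(cps[keep.to_numpy()], block[keep.to_numpy()], region=region)
        for term in ("L_star", "a_star", "b_star", "sex", "age", "intercept"):
            reg_rows.append({
                "region": region, "term": term,
                "B": res.coefficients[term], "p_value": res.p_values[term],
                "r_squared": res.r_squared,
                "adjusted_r_squared": res.adjusted_r_squared, "n": res.n,
            })
        covs = np.column_stack([sex01, age])[keep.to_numpy()]
        for channel in ("L_star", "a_star", "b_star"):
            xv = block.loc[keep, channel].to_numpy()
            for i, item in enumerate(ITEM_NAMES):
                yv = q.loc[keep.to_numpy(), f"item{i + 1}"].to_numpy(dtype=float)
                rho, p = partial_correlation(xv, yv, covs)
                pc_rows.append({
                    "region": region, "channel": channel, "item": item,
                    "partial_rho": rho, "p_value": p, "n": int(keep.sum()),
                })

    reg = pd.DataFrame(reg_rows)
    pc = pd.DataFrame(pc_rows)
    if bh_adjust:
        pc["p_adjusted"] = multipletests(pc["p_value"], method="fdr_bh")[1]
        pflag = pc["p_adjusted"]
    else:
        pflag = pc["p_value"]
    pc["significant_05"] = pflag < 0.05
    pc["significant_01"] = pflag < 0.01
    reg["significant_05"] = reg["p_value"] < 0.05
    reg["significant_01"] = reg["p_value"] < 0.01
    return reg, pc
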