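"""Mixed-effects group contrasts, LRTs, family-wise FDR and hurdle models.

Every feature is tested with a null / main-effect / interaction model
triplet sharing covariates (age centred at 50, sex, group) and a random
intercept for site; likelihood-ratio p-values are FDR-adjusted within
fixed family sizes (spectral 180, spindle 14, WESI 10, transition 25).
Transition counts are gated by prevalence into not-modelled / hurdle /
GLMM routes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

AGE_CENTER = 50.0

FAMILY_SIZES = {"spectral": 180, "spindle": 14, "wesi": 10, "transition": 25}

NULL_FORMULA = "value ~ age_c * sex_male"
MAIN_FORMULA = "value ~ age_c * sex_male + group_insomnia"
INTERACTION_FORMULA = "value ~ age_c * sex_male * group_insomnia"

PREVALENCE_LOW = 0.015
PREVALENCE_HIGH = 0.985


def prepare_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Add the numeric covariates the model formulas expect."""
    out = df.copy()
    out["age_c"] = out["age"] - AGE_CENTER
    out["sex_male"] = (out["sex"] == "male").astype(float)
    out["group_insomnia"] = (out["group"] == "insomnia").astype(float)
    return out


@dataclass
class ModelTriplet:
    null: object
    main: object
    interaction: object
    route: str  # "mixed" or "ols"


@dataclass
class ComparisonResult:
    feature: str
    family: str
    lrt_stat: float
    p_raw: float
    p_adj: float = np.nan
    interaction_p_raw: float = np.nan
    group_estimate: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    family_n: int = 0
    significant: bool = False
    route: str = ""


@dataclass
class HurdleResult:
    route: str  # "not-modelled" | "hurdle" | "glmm"
    prevalence: float
    zero_params: pd.Series | None = None
    zero_pvalues: pd.Series | None = None
    count_params: pd.Series | None = None
    count_pvalues: pd.Series | None = None
    lrt_stat: float = np.nan
    lrt_df: int = 0
    p_raw: float = np.nan
    extra: dict = field(default_factory=dict)


def _fit_one(formula: str, data: pd.DataFrame, mixed: bool):
    if mixed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            model = smf.mixedlm(formula, data=data, groups=data["site"])
            fit = model.fit(reml=False)
            if not np.isfinite(fit.llf):
                raise ValueError("mixed fit produced non-finite log-likelihood")
            return fit
    return smf.ols(formula, data=data).fit()


def fit_model_triplet(data: pd.DataFrame, drop_subject_re: bool = True) -> ModelTriplet:
    """Fit null/main/interaction models for one feature.

    ``data`` needs columns value, age, sex, group, site.  With a single
    site (or a failed mixed fit) the triplet degrades to plain ML
    least-squares, recorded in ``route``.  A per-subject random
    intercept with one observation per subject is unidentifiable and is
    dropped by default.
    """
    df = prepare_metadata(data).dropna(subset=["value"])
    for g in ("insomnia", "non-insomnia"):
        if (df["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {g}")
    mixed = df["site"].nunique() > 1
    try:
        fits = [
            _fit_one(f, df, mixed)
            for f in (NULL_FORMULA, MAIN_FORMULA, INTERACTION_FORMULA)
        ]
        route = "mixed" if mixed else "ols"
    except Exception:
        fits = [
            _fit_one(f, df, mixed=False)
            for f in (NULL_FORMULA, MAIN_FORMULA, INTERACTION_FORMULA)
        ]
        route = "ols"
    return ModelTriplet(null=fits[0], main=fits[1], interaction=fits[2], route=route)


def likelihood_ratio_test(nested_fit, fuller_fit, df_diff: int) -> tuple[float, float]:
    """Chi-squared LRT on the fixed-effect df difference (ML fits)."""
    if df_diff <= 0:
        raise ValueError("fuller model must add fixed-effect parameters")
    stat = max(2.0 * (fuller_fit.llf - nested_fit.llf), 0.0)
    return stat, float(sps.chi2.sf(stat, df_diff))


def fdr_adjust(pvalues, family_size: int) -> np.ndarray:
    """Benjamini-Hochberg with ranks computed as if ``family_size`` tests ran.

    Tests not carried out are treated as non-significant placeholders
    (p = 1), the conservative convention for a family declared larger
    than the tests actually run.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if family_size < len(p):
        raise ValueError("family_size smaller than the number of tests")
    padded = np.concatenate([p, np.ones(family_size - len(p))])
    _, adj, _, _ = multipletests(padded, method="fdr_bh")
    return adj[: len(p)]


def compare_feature(
    data: pd.DataFrame, feature: str, family: str, drop_subject_re: bool = True
) -> ComparisonResult:
    """Full null-vs-main (and main-vs-interaction) comparison for one feature."""
    triplet = fit_model_triplet(data, drop_subject_re=drop_subject_re)
    stat, p = likelihood_ratio_test(triplet.null, triplet.main, df_diff=1)
    _, p_int = likelihood_ratio_test(triplet.main, triplet.interaction, df_diff=3)
    est = float(triplet.main.params.get("group_insomnia", np.nan))
    try:
        ci = triplet.main.conf_int().loc["group_insomnia"]
        ci_low, ci_high = float(ci[0]), float(ci[1])
    except (KeyError, IndexError):
        ci_low = ci_high = np.nan
    return ComparisonResult(
        feature=feature, family=family, lrt_stat=stat, p_raw=p,
        interaction_p_raw=p_int, group_estimate=est,
        ci_low=ci_low, ci_high=ci_high,
        family_n=FAMILY_SIZES.get(family, 0), route=triplet.route,
    )


def compare_family(feature_frames: dict[str, pd.DataFrame], family: str) -> pd.DataFrame:
    """Run :func:`compare_feature` over a family and FDR-adjust within it."""
    results = [compare_feature(df, name, family) for name, df in feature_frames.items()]
    if results:
        adj = fdr_adjust([r.p_raw for r in results], FAMILY_SIZES[family])
        for r, a in zip(results, adj):
            r.p_adj = float(a)
            r.significant = bool(a < 0.05)
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------- transitions

def route_transition_model(counts: np.ndarray) -> str:
    """Prevalence gating: <1.5% not-modelled, 1.5-98.5% hurdle, else GLMM."""
    counts = np.asarray(counts)
    if len(counts) < 1:
        raise ValueError("need at least one recording")
    prevalence = float((counts > 0).mean())
    if prevalence < PREVALENCE_LOW:
        return "not-modelled"
    if prevalence <= PREVALENCE_HIGH:
        return "hurdle"
    return "glmm"


def _glm_formulas(df: pd.DataFrame) -> tuple[str, str]:
    site_term = " + C(site)" if df["site"].nunique() > 1 else ""
    null = "age_c * sex_male" + site_term
    main = "age_c * sex_male + group_insomnia" + site_term
    return null, main


def _fit_binomial(endog, df: pd.DataFrame, rhs: str):
    exog = patsy.dmatrix("1 + " + rhs, df, return_type="dataframe")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        fit.llf  # force lazy evaluation while warnings are suppressed
        return fit


def fit_hurdle(counts: np.ndarray, totals: np.ndarray, metadata: pd.DataFrame) -> HurdleResult:
    """Two-part model: zero-vs-nonzero logistic + binomial count part.

    The count part models non-zero counts out of the subject's total
    transitions from the source stage with a logit link.  The LRT
    statistic is the sum of the two parts' null-vs-main statistics
    (df = 2).  Site enters as fixed dummies standing in for the random
    intercept when several sites are present.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    df = prepare_metadata(metadata).reset_index(drop=True)
    occurred = counts > 0
    assert occurred.any() and not occurred.all(), "hurdle requires mixed occurrence"
    null_rhs, main_rhs = _glm_formulas(df)

    zero_null = _fit_binomial(occurred.astype(float), df, null_rhs)
    zero_main = _fit_binomial(occurred.astype(float), df, main_rhs)

    sub = df[occurred].reset_index(drop=True)
    k = counts[occurred]
    n = np.maximum(totals[occurred], k)
    endog = np.column_stack([k, n - k])
    count_null = _fit_binomial(endog, sub, _glm_formulas(sub)[0])
    count_main = _fit_binomial(endog, sub, _glm_formulas(sub)[1])

    stat = max(2.0 * (zero_main.llf - zero_null.llf), 0.0) + max(
        2.0 * (count_main.llf - count_null.llf), 0.0
    )
    p = float(sps.chi2.sf(stat, 2))
    return HurdleResult(
        route="hurdle",
        prevalence=float(occurred.mean()),
        zero_params=pd.Series(zero_main.params),
        zero_pvalues=pd.Series(zero_main.pvalues),
        count_params=pd.Series(count_main.params),
        count_pvalues=pd.Series(count_main.pvalues),
        lrt_stat=stat, lrt_df=2, p_raw=p,
    )


def fit_glmm_transition(counts: np.ndarray, totals: np.ndarray, metadata: pd.DataFrame) -> HurdleResult:
    """Binomial GLM on counts/totals for near-ubiquitous transitions."""
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    df = prepare_metadata(metadata).reset_index(drop=True)
    usable = totals > 0
    df, counts, totals = df[usable].reset_index(drop=True), counts[usable], totals[usable]
    endog = np.column_stack([counts, np.maximum(totals - counts, 0)])
    null_rhs, main_rhs = _glm_formulas(df)
    fit_null = _fit_binomial(endog, df, null_rhs)
    fit_main = _fit_binomial(endog, df, main_rhs)
    stat = max(2.0 * (fit_main.llf - fit_null.llf), 0.0)
    return HurdleResult(
        route="glmm",
        prevalence=float((counts > 0).mean()),
        count_params=pd.Series(fit_main.params),
        count_pvalues=pd.Series(fit_main.pvalues),
        lrt_stat=stat, lrt_df=1, p_raw=float(sps.chi2.sf(stat, 1)),
    )


def transition_significance(result: HurdleResult, p_adj: float, alpha: float = 0.05) -> bool:
    """Adjusted LRT p < alpha AND >= 1 individually significant group coefficient."""
    if not (p_adj < alpha):
        return False
    for pvals in (result.zero_pvalues, result.count_pvalues):
        if pvals is not None and "group_insomnia" in pvals.index:
            if pvals["group_insomnia"] < alpha:
                return True
    return False


def analyze_transitions(
    count_matrix: pd.DataFrame, total_matrix: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Route + fit + FDR for every transition column.

    ``count_matrix`` has one column per transition (e.g. ``W->N1``) and
    one row per subject; ``total_matrix`` the matching source-stage
    totals.
    """
    rows = []
    fits: dict[str, HurdleResult] = {}
    for col in count_matrix.columns:
        counts = count_matrix[col].to_numpy()
        totals = total_matrix[col].to_numpy()
        route = route_transition_model(counts)
        if route == "not-modelled":
            fits[col] = HurdleResult(route=route, prevalence=float((counts > 0).mean()))
        elif route == "hurdle":
            fits[col] = fit_hurdle(counts, totals, metadata)
        else:
            fits[col] = fit_glmm_transition(counts, totals, metadata)
    modelled = [c for c in count_matrix.columns if fits[c].route != "not-modelled"]
    adj = fdr_adjust([fits[c].p_raw for c in modelled], FAMILY_SIZES["transition"])
    adj_map = dict(zip(modelled, adj))
    for col in count_matrix.columns:
        r = fits[col]
        p_adj = adj_map.get(col, np.nan)
        sig = transition_significance(r, p_adj) if r.route != "not-modelled" else False
        group_est = np.nan
        for params in (r.zero_params, r.count_params):
            if params is not None and "group_insomnia" in params.index:
                group_est = float(params["group_insomnia"])
                break
        rows.append(
            {
                "feature": col, "family": "transition", "route": r.route,
                "prevalence": r.prevalence, "lrt_stat": r.lrt_stat,
                "p_raw": r.p_raw, "p_adj": p_adj,
                "group_estimate": group_est, "significant": sig,
                "family_n": FAMILY_SIZES["transition"],
            }
        )
    return pd.DataFrame(rows)
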