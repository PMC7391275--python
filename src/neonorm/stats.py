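"""The statistical battery relating atypicality indices to covariates.

Implements the analysis blocks run on the atypicality table:

* Spearman rank correlation (t-approximation p; exact permutation p for
  n <= 9) of each index with gestational age at birth and with the three
  outcome composite scores, per group;
* Mann–Whitney U group comparison (normal approximation with tie and
  continuity correction) reported jointly with the Vargha–Delaney A
  probability-of-superiority effect size, A = (#{x>y} + ½#{x=y})/(n_x n_y);
* Bonferroni–Holm step-down correction within each analysis family;
* multiple linear regression of an outcome on an index plus GA at birth,
  sex, head motion and deprivation score, with case-resampling bootstrap
  95% CIs for the adjusted R² (1000 replications) and an out-of-bag
  bootstrap estimate of prediction adjusted R² (100 resamples);
* an influential-observation sensitivity rerun that standardizes an index
  (sample SD), drops |Z| > 3.1 observations and recomputes the
  correlation.

Standard tests delegate to scipy.stats / statsmodels; the effect size,
exact small-sample permutation p, bootstrap procedures and battery
orchestration are implemented here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests

from neonorm.errors import ConfigurationError, DegenerateDataError, InputError

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("fa_plus", "fa_minus", "md_plus", "md_minus")
OUTCOME_COLUMNS = ("outcome_cognitive", "outcome_language", "outcome_motor")
COVARIATE_COLUMNS = ("ga_birth", "sex", "motion", "imd")


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, effect size and sample sizes."""

    label: str
    statistic: float
    p_value: float
    effect: float
    effect_name: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise InputError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# rank statistics


def spearman(
    x: np.ndarray, y: np.ndarray, method: str = "t", label: str = ""
) -> TestResult:
    """Spearman rank correlation (Pearson on mid-ranks).

    ``method='t'`` uses the t approximation for the two-sided p;
    ``method='exact'`` enumerates all permutations (only for n <= 9).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise InputError("spearman needs equal-length inputs with n >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InputError("missing values: drop pairwise before calling")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    if method == "exact":
        if x.size > 9:
            raise ConfigurationError("exact permutation p limited to n <= 9")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    return TestResult(
        label=label, statistic=float(rho), p_value=float(p),
        effect=float(rho), effect_name="rho", n=(int(x.size),),
    )


def vargha_delaney_a(x: np.ndarray, y: np.ndarray) -> float:
    """A = P(X > Y) + ½P(X = Y), estimated by full pair enumeration."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float((gt + 0.5 * eq) / (x.size * y.size))


def mann_whitney(x: np.ndarray, y: np.ndarray, label: str = "") -> TestResult:
    """Two-sided Mann–Whitney U with mid-rank ties; A as the effect size.

    The U statistic is U_x = #{x_i > y_j} + ½ #{x_i = y_j}; the p-value
    uses the normal approximation with tie and continuity correction
    (appropriate at the cohort sizes this battery targets).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise InputError("both groups need at least 2 observations")
    a = vargha_delaney_a(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        # every observation tied: no evidence either way
        return TestResult(
            label=label, statistic=float(x.size * y.size) / 2.0,
            p_value=1.0, effect=0.5, effect_name="A",
            n=(int(x.size), int(y.size)),
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(
        label=label, statistic=float(res.statistic), p_value=float(res.pvalue),
        effect=a, effect_name="A", n=(int(x.size), int(y.size)),
    )


def holm_correct(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni–Holm step-down adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, reject


# ---------------------------------------------------------------------------
# linear models


@dataclass
class LinearModelResult:
    """OLS fit with bootstrap uncertainty for the adjusted R²."""

    label: str
    params: pd.Series
    p_values: pd.Series
    r2: float
    adj_r2: float
    f_statistic: float
    f_dof: tuple[int, int]
    f_p_value: float
    residual_normality: tuple[str, float]       # (test name, p)
    heteroscedasticity: tuple[str, float]       # (test name, p)
    adj_r2_ci: tuple[float, float] | None = None
    adj_r2_draws: np.ndarray | None = None
    prediction_adj_r2: float | None = None
    n: int = 0


def _design(predictors: pd.DataFrame) -> pd.DataFrame:
    X = sm.add_constant(predictors.astype(np.float64), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear columns by dropping one at a time
        bad = [
            c for c in predictors.columns
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank
        ]
        raise InputError(f"rank-deficient design; collinear columns: {bad}")
    return X


def fit_linear_model(
    outcome: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    label: str = "",
) -> LinearModelResult:
    """OLS with per-term t p-values, adjusted R² and an overall F test.

    Residual diagnostics (Shapiro–Wilk normality, Breusch–Pagan
    heteroscedasticity) are reported alongside, never used as gates.
    """
    y = np.asarray(outcome, dtype=np.float64)
    n, p = len(y), predictors.shape[1]
    if n <= p + 1:
        raise InputError(f"n = {n} too small for {p} predictors")
    X = _design(predictors)
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    sw_p = float(sps.shapiro(resid).pvalue) if 3 <= n <= 5000 else float("nan")
    bp_p = float(het_breuschpagan(resid, X.to_numpy())[1])
    return LinearModelResult(
        label=label,
        params=fit.params,
        p_values=fit.pvalues,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_dof=(int(fit.df_model), int(fit.df_resid)),
        f_p_value=float(fit.f_pvalue),
        residual_normality=("shapiro-wilk", sw_p),
        heteroscedasticity=("breusch-pagan", bp_p),
        n=n,
    )


def _adj_r2(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    n = y.size
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1.0 - ss_res / ss_tot
    if n - n_params - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def bootstrap_ci_adj_r2(
    outcome: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    truncate_at_zero: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Case-resampling percentile bootstrap CI for the adjusted R².

    Singular resamples are redrawn (and counted); more than 10% singular
    draws aborts. ``truncate_at_zero`` optionally floors negative draws
    at 0 before taking percentiles (off by default).
    """
    y = np.asarray(outcome, dtype=np.float64)
    Xfull = _design(predictors).to_numpy()
    n, k = Xfull.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    draws = np.empty(reps)
    n_singular = 0
    for r in range(reps):
        while True:
            idx = rng.integers(0, n, n)
            Xb = Xfull[idx]
            if np.linalg.matrix_rank(Xb) == k:
                break
            n_singular += 1
            if n_singular > 0.1 * reps:
                raise InputError(
                    "more than 10% of bootstrap resamples were singular"
                )
        yb = y[idx]
        beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        draws[r] = _adj_r2(yb, Xb @ beta, k - 1)
    if n_singular:
        logger.info("redrew %d singular bootstrap resamples", n_singular)
    used = np.maximum(draws, 0.0) if truncate_at_zero else draws
    lo = float(np.percentile(used, 100 * (1 - level) / 2))
    hi = float(np.percentile(used, 100 * (1 + level) / 2))
    return lo, hi, draws


def bootstrap_prediction_r2(
    outcome: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    resamples: int = 100,
    seed: int = 0,
) -> float:
    """Mean out-of-bag adjusted R² over bootstrap refits.

    Each resample fits OLS on the bootstrap rows and evaluates the
    adjusted R² of its predictions on the out-of-bag rows; resamples with
    an empty out-of-bag set (or singular design) are redrawn and logged.
    """
    y = np.asarray(outcome, dtype=np.float64)
    Xfull = _design(predictors).to_numpy()
    n, k = Xfull.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    vals = np.empty(resamples)
    n_redrawn = 0
    for r in range(resamples):
        while True:
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size > k and np.linalg.matrix_rank(Xfull[idx]) == k:
                break
            n_redrawn += 1
            if n_redrawn > 10 * resamples:
                raise InputError("could not draw usable bootstrap resamples")
        beta, *_ = np.linalg.lstsq(Xfull[idx], y[idx], rcond=None)
        vals[r] = _adj_r2(y[oob], Xfull[oob] @ beta, k - 1)
    if n_redrawn:
        logger.info("redrew %d unusable bootstrap resamples", n_redrawn)
    return float(vals.mean())


def sensitivity_rerun(
    index_values: np.ndarray,
    outcome: np.ndarray,
    threshold: float = 3.1,
    label: str = "",
) -> tuple[TestResult, TestResult, list[int]]:
    """Rerun a correlation after dropping influential index observations.

    The index is standardized across subjects (sample SD, n−1) and
    observations with |Z| > ``threshold`` are removed; the Spearman test
    is recomputed. Returns (full, trimmed, dropped row positions).
    """
    x = np.asarray(index_values, dtype=np.float64)
    y = np.asarray(outcome, dtype=np.float64)
    if x.size < 5:
        raise InputError("need at least 5 subjects")
    full = spearman(x, y, label=f"{label} (full)")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant index: cannot standardize")
    z = (x - x.mean()) / sd
    keep = np.abs(z) <= threshold
    dropped = np.flatnonzero(~keep).tolist()
    if keep.sum() == 0:
        raise InputError("all observations dropped by the |Z| screen")
    trimmed = spearman(x[keep], y[keep], label=f"{label} (trimmed)")
    return full, trimmed, dropped


# ---------------------------------------------------------------------------
# the full battery


@dataclass
class BatteryConfig:
    alpha: float = 0.05
    bootstrap_reps: int = 1000
    prediction_resamples: int = 100
    seed: int = 0
    truncate_ci_at_zero: bool = False
    sensitivity_threshold: float = 3.1


@dataclass
class BatteryReport:
    """Structured result of the full battery: tests, models, warnings."""

    tests: pd.DataFrame
    models: dict[str, LinearModelResult] = field(default_factory=dict)
    sensitivity: dict[str, tuple[TestResult, TestResult, list[int]]] = field(
        default_factory=dict
    )
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.tests.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _safe_spearman(
    x: np.ndarray, y: np.ndarray, label: str, report: "BatteryReport"
) -> TestResult:
    """Spearman that degrades to an undefined-correlation row on constants."""
    try:
        return spearman(x, y, label=label)
    except DegenerateDataError:
        msg = f"{label}: constant input, correlation undefined"
        logger.warning(msg)
        report.warnings.append(msg)
        return TestResult(
            label=label, statistic=float("nan"), p_value=float("nan"),
            effect=float("nan"), effect_name="rho", n=(int(len(x)),),
        )


def _family_rows(
    results: list[TestResult], family: str, group: str, alpha: float
) -> list[dict]:
    p = np.array([r.p_value for r in results])
    defined = ~np.isnan(p)
    adjusted = np.full(p.size, np.nan)
    reject = np.zeros(p.size, dtype=bool)
    if defined.any():
        # undefined tests do not count toward the family size
        adjusted[defined], reject[defined] = holm_correct(p[defined], alpha)
    rows = []
    for r, p_adj, rej in zip(results, adjusted, reject):
        rows.append(
            {
                "family": family,
                "test": r.label,
                "group": group,
                "statistic": r.statistic,
                "effect": r.effect,
                "effect_name": r.effect_name,
                "n": "x".join(str(v) for v in r.n),
                "p_raw": r.p_value,
                "p_holm": p_adj,
                "reject": bool(rej),
            }
        )
    return rows


def run_full_battery(
    table: pd.DataFrame, config: BatteryConfig = BatteryConfig()
) -> BatteryReport:
    """Run every test block on a joined atypicality + covariate table.

    Families (each Holm-corrected separately): the four group
    comparisons; the four GA correlations per group; the index × outcome
    correlation grid per group. Indices whose outcome correlation
    survives Holm in the atypical group are followed up with the
    adjusted regression model (index + GA + sex + motion + IMD), its
    bootstrap CIs and prediction R², and the influential-observation
    sensitivity rerun.
    """
    report = BatteryReport(tests=pd.DataFrame())
    rows: list[dict] = []
    groups = {g: table[table["group"] == g] for g in ("normative", "atypical")}

    # family 1: group comparisons (atypical vs normative) per index
    comps = []
    for idx in INDEX_COLUMNS:
        comps.append(
            mann_whitney(
                groups["atypical"][idx].to_numpy(),
                groups["normative"][idx].to_numpy(),
                label=f"{idx} atypical>normative",
            )
        )
    rows += _family_rows(comps, "group_difference", "both", config.alpha)

    # family 2: GA correlations per group
    for gname, g in groups.items():
        res = [
            _safe_spearman(
                g["ga_birth"].to_numpy(), g[idx].to_numpy(),
                f"{idx} vs ga_birth", report,
            )
            for idx in INDEX_COLUMNS
        ]
        rows += _family_rows(res, "ga_correlation", gname, config.alpha)

    # family 3: index × outcome grid per group
    outcome_rows: dict[str, list[dict]] = {}
    for gname, g in groups.items():
        res = []
        for idx in INDEX_COLUMNS:
            for out in OUTCOME_COLUMNS:
                if out not in g.columns or g[out].isna().all():
                    msg = f"outcome {out} missing; test skipped for {gname}"
                    logger.warning(msg)
                    report.warnings.append(msg)
                    continue
                sub = g[[idx, out]].dropna()
                res.append(
                    _safe_spearman(
                        sub[idx].to_numpy(), sub[out].to_numpy(),
                        f"{idx} vs {out}", report,
                    )
                )
        fam = _family_rows(res, "outcome_correlation", gname, config.alpha)
        outcome_rows[gname] = fam
        rows += fam

    # stage 2: regressions + sensitivity for surviving atypical correlations
    atyp = groups["atypical"]
    for row in outcome_rows.get("atypical", []):
        if not row["reject"]:
            continue
        idx, out = row["test"].split(" vs ")
        sub = atyp[[idx, out, *COVARIATE_COLUMNS]].dropna()
        label = f"{out} ~ {idx} + ga + sex + motion + imd"
        predictors = sub[[idx, *COVARIATE_COLUMNS]]
        model = fit_linear_model(sub[out].to_numpy(), predictors, label=label)
        lo, hi, draws = bootstrap_ci_adj_r2(
            sub[out].to_numpy(), predictors,
            reps=config.bootstrap_reps, seed=config.seed,
            truncate_at_zero=config.truncate_ci_at_zero,
        )
        model.adj_r2_ci = (lo, hi)
        model.adj_r2_draws = draws
        model.prediction_adj_r2 = bootstrap_prediction_r2(
            sub[out].to_numpy(), predictors,
            resamples=config.prediction_resamples, seed=config.seed,
        )
        report.models[label] = model
        try:
            report.sensitivity[row["test"]] = sensitivity_rerun(
                sub[idx].to_numpy(), sub[out].to_numpy(),
                threshold=config.sensitivity_threshold, label=row["test"],
            )
        except DegenerateDataError as err:
            msg = f"sensitivity rerun for {row['test']} skipped: {err}"
            logger.warning(msg)
            report.warnings.append(msg)

    report.tests = pd.DataFrame(rows)
    return report
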