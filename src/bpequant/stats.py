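"""Matched case-control statistics for BPE measures.

The centrepiece is :class:`ConditionalLogit`, a 1:1 conditional logistic
regression fitted by Newton's method on within-pair covariate differences:
for pair j with case covariates x1 and control covariates x0, the
conditional likelihood contribution is

    exp(b'x1) / (exp(b'x1) + exp(b'x0)) = sigmoid(b'(x1 - x0)),

i.e. an intercept-free binary logistic model on the differences.  Odds
ratios are reported per configurable increments (by convention 200 cm^3 for
|BPE| and |FGT|, 20 percentage points for BPE%/FGT%), with Wald standard
errors from the observed information.

Around it sit the rest of the analysis battery: Spearman correlation,
Benjamini-Hochberg FDR adjustment, unconditional logistic regression with
log-likelihoods exposed for nested likelihood-ratio tests, the
Mann-Whitney AUC estimator, and DeLong's paired test for correlated AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import CohortValidationError

__all__ = [
    "OR_INCREMENTS",
    "ConditionalLogit",
    "ConditionalLogitResults",
    "UnconditionalLogitFit",
    "RocComparison",
    "PairedTResult",
    "spearman",
    "bh_fdr",
    "unconditional_logistic",
    "roc_auc",
    "delong_test",
    "lr_test",
    "paired_t",
    "pair_differences",
    "select_breast",
]

#: default odds-ratio reporting increments by measure kind
OR_INCREMENTS = {
    "bpe_cm3": 200.0,  # cm^3
    "fgt_cm3": 200.0,
    "bpe_pct": 20.0,  # percentage points
    "fgt_pct": 20.0,
}


def default_increment(name: str) -> float:
    for prefix, inc in OR_INCREMENTS.items():
        if name.startswith(prefix):
            return inc
    return 1.0


# ---------------------------------------------------------------------------
# cohort helpers
# ---------------------------------------------------------------------------

def select_breast(cohort: pd.DataFrame, comparison: str = "A") -> pd.DataFrame:
    """Resolve per-breast columns according to the comparison policy.

    Comparison A uses the contralateral breast of both cases and controls;
    Comparison B swaps in the benign-lesion breast for controls.  Returns a
    copy with un-suffixed measure columns (``bpe_pct_sub1`` etc.).
    """
    if comparison not in ("A", "B"):
        raise ValueError(f"comparison must be 'A' or 'B', got {comparison!r}")
    out = cohort.copy()
    bases = ["breast_cm3", "fgt_cm3", "fgt_pct"] + [
        f"{m}_sub{k}" for m in ("bpe_cm3", "bpe_pct") for k in (1, 2, 3)
    ]
    is_control = out["group"] == "control"
    for base in bases:
        vals = out[f"{base}_contra"].to_numpy(dtype=float).copy()
        if comparison == "B":
            vals[is_control] = out.loc[is_control, f"{base}_benign"].to_numpy(dtype=float)
        out[base] = vals
    return out


def pair_differences(cohort: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Case-minus-control differences of ``columns``, one row per pair.

    ``cohort`` must contain resolved (un-suffixed) measure columns, e.g.
    from :func:`select_breast`.
    """
    diffs = []
    for pair_id, grp in cohort.groupby("pair_id", sort=True):
        cases = grp[grp["group"] == "case"]
        ctrls = grp[grp["group"] == "control"]
        if len(cases) != 1 or len(ctrls) != 1:
            raise CohortValidationError(
                f"pair {pair_id!r} must have exactly one case and one control "
                f"(found {len(cases)} case(s), {len(ctrls)} control(s))"
            )
        diffs.append(
            cases[columns].to_numpy(dtype=float)[0] - ctrls[columns].to_numpy(dtype=float)[0]
        )
    return np.asarray(diffs)


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ConditionalLogitResults:
    """Fit results of a 1:1 conditional logistic regression.

    Coefficients are stored per natural unit of each covariate; odds ratios
    are additionally reported per the configured increments.
    """

    model: "ConditionalLogit" = field(repr=False)
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    flags: tuple[str, ...]
    n_pairs_used: int
    iterations: int

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided Wald p-values."""
        return pd.Series(
            2.0 * scipy.stats.norm.sf(np.abs(self.tvalues)), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def or_per_increment(self, alpha: float = 0.05) -> pd.DataFrame:
        """Odds ratios (with CIs) per the model's reporting increments."""
        if "separation" in self.flags:
            raise ValueError("separation detected: odds ratios are not identified")
        inc = pd.Series(self.model.increments, index=self.params.index, dtype=float)
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "increment": inc,
                "odds_ratio": np.exp(self.params * inc),
                "ci_lower": np.exp(ci["lower"] * inc),
                "ci_upper": np.exp(ci["upper"] * inc),
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            "Conditional logistic regression (1:1 matched pairs)",
            f"  pairs used: {self.n_pairs_used}   log-likelihood: {self.llf:.4f}",
            f"  converged: {self.converged}   flags: {', '.join(self.flags) or 'none'}",
            f"  {'covariate':<22}{'coef':>10}{'se':>10}{'p':>10}{'OR/incr':>12}",
        ]
        ors = None
        if "separation" not in self.flags:
            ors = self.or_per_increment()
        for name in self.params.index:
            or_s = f"{ors.loc[name, 'odds_ratio']:.3f}" if ors is not None else "--"
            lines.append(
                f"  {name:<22}{self.params[name]:>10.5f}{self.bse[name]:>10.5f}"
                f"{self.pvalues[name]:>10.4f}{or_s:>12}"
            )
        return "\n".join(lines)


class ConditionalLogit:
    """1:1 conditional logistic regression on within-pair differences.

    Parameters
    ----------
    diffs : ndarray, shape (n_pairs, k)
        Case-minus-control covariate differences.
    names : list of str
        Covariate names (first is conventionally the exposure).
    increments : sequence of float, optional
        Reporting increment per covariate; defaults from the name prefix
        (200 cm^3 for volume measures, 20 points for percentages).
    """

    def __init__(self, diffs, names, increments=None):
        self.diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
        if self.diffs.ndim != 2:
            raise ValueError("diffs must be 2D (n_pairs, k)")
        self.names = list(names)
        if len(self.names) != self.diffs.shape[1]:
            raise ValueError("names length must match number of covariates")
        if increments is None:
            increments = [default_increment(n) for n in self.names]
        self.increments = [float(i) for i in increments]

    @classmethod
    def from_cohort(cls, cohort, exposure, covariates=(), comparison="A", increments=None):
        """Build the model from a cohort table (see :func:`select_breast`)."""
        resolved = select_breast(cohort, comparison)
        cols = [exposure, *covariates]
        return cls(pair_differences(resolved, cols), cols, increments)

    def loglike(self, beta) -> float:
        """Conditional log-likelihood sum_j log sigmoid(b'd_j)."""
        eta = self.diffs @ np.asarray(beta, dtype=float)
        return float(-np.sum(np.logaddexp(0.0, -eta)))

    def fit(self, maxiter: int = 100, gtol: float = 1e-8) -> ConditionalLogitResults:
        """Newton-Raphson with step-halving on standardized covariates.

        Convergence: gradient max-norm below ``gtol``.  Separation is
        flagged when standardized coefficients diverge; all-zero difference
        columns are flagged flat and pinned at zero.
        """
        d = self.diffs
        n, k = d.shape
        flags: list[str] = []

        scale = d.std(axis=0, ddof=0)
        flat = scale == 0
        zero_cols = np.array([np.all(d[:, j] == 0) for j in range(k)])
        if zero_cols.any():
            flags.append("flat")
        scale = np.where(scale == 0, 1.0, scale)
        ds = d / scale  # standardized for stable Newton steps
        active = ~zero_cols

        beta = np.zeros(k)
        it = 0
        converged = False
        if active.any():
            da = ds[:, active]
            b = np.zeros(active.sum())
            ll = -n * np.log(2.0)
            for it in range(1, maxiter + 1):
                eta = da @ b
                p = expit(eta)
                grad = da.T @ (1.0 - p)
                if np.max(np.abs(grad)) < gtol:
                    converged = True
                    break
                w = p * (1.0 - p)
                hess = (da * w[:, None]).T @ da
                try:
                    step = np.linalg.solve(hess, grad)
                except np.linalg.LinAlgError:
                    flags.append("singular_information")
                    break
                # step halving on the conditional log-likelihood
                t = 1.0
                ll_new = -np.sum(np.logaddexp(0.0, -(da @ (b + t * step))))
                while ll_new < ll and t > 1e-10:
                    t /= 2.0
                    ll_new = -np.sum(np.logaddexp(0.0, -(da @ (b + t * step))))
                b = b + t * step
                ll = ll_new
                if np.max(np.abs(b)) > 30.0:  # standardized scale: separation
                    flags.append("separation")
                    break
            beta[active] = b / scale[active]

        # monotone likelihood: every informative pair fitted at probability ~1
        eta = d @ beta
        p = expit(eta)
        informative_rows = np.any(d != 0, axis=1)
        if (
            "separation" not in flags
            and informative_rows.any()
            and np.all(p[informative_rows] > 1.0 - 1e-6)
        ):
            flags.append("separation")

        # observed information on the natural scale for Wald SEs
        w = p * (1.0 - p)
        info = (d * w[:, None]).T @ d
        bse = np.full(k, np.nan)
        if active.any() and "separation" not in flags:
            try:
                cov = np.linalg.inv(info[np.ix_(active, active)])
                bse[active] = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                flags.append("singular_information")

        informative = int(np.count_nonzero(np.any(d != 0, axis=1)))
        return ConditionalLogitResults(
            model=self,
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(bse, index=self.names),
            llf=self.loglike(beta),
            converged=converged and "separation" not in flags,
            flags=tuple(dict.fromkeys(flags)),
            n_pairs_used=informative,
            iterations=it,
        )


# ---------------------------------------------------------------------------
# correlations, FDR, simple tests
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PairedTResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_t(case_values, control_values) -> PairedTResult:
    """Two-sided paired t-test on case-minus-control differences."""
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        return PairedTResult(t=np.nan, p=np.nan, df=n - 1, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(t=float(t), p=float(p), df=n - 1)


# ---------------------------------------------------------------------------
# unconditional logistic regression, AUC, DeLong, LRT
# ---------------------------------------------------------------------------

@dataclass
class UnconditionalLogitFit:
    """Unconditional logistic fit with log-likelihood and fitted probabilities."""

    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    llf: float
    fitted: np.ndarray
    converged: bool
    nobs: int

    @property
    def df_model(self) -> int:
        return len(self.predictors)


def unconditional_logistic(records: pd.DataFrame, predictors, outcome: str = "group"):
    """Fit case/control status on ``predictors`` by maximum likelihood.

    ``records[outcome]`` is "case"/"control" or 0/1.  An intercept is always
    included; an empty predictor list gives the intercept-only model.
    Separation or non-convergence is flagged via ``converged=False``.
    """
    predictors = list(predictors)
    y = records[outcome]
    if y.dtype == object:
        y = (y == "case").astype(float)
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(
        records[predictors].astype(float), has_constant="add"
    ) if predictors else pd.DataFrame({"const": np.ones(len(records))}, index=records.index)
    converged = True
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params, bse, llf, fitted = res.params, res.bse, res.llf, np.asarray(res.predict())
    except (PerfectSeparationError, np.linalg.LinAlgError):
        converged = False
        params = pd.Series(np.nan, index=X.columns)
        bse = pd.Series(np.nan, index=X.columns)
        llf, fitted = np.nan, np.full(len(y), np.nan)
    return UnconditionalLogitFit(
        predictors=tuple(predictors),
        params=params,
        bse=bse,
        llf=float(llf),
        fitted=fitted,
        converged=converged,
        nobs=len(y),
    )


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC estimator; ties credited 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class RocComparison:
    """Paired DeLong comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float
    degenerate: bool = False


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components V10 (per case) and V01 (per control)."""
    cases = scores[y]
    ctrls = scores[~y]
    psi = (cases[:, None] > ctrls[None, :]).astype(float)
    psi += 0.5 * (cases[:, None] == ctrls[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_test(scores_a, scores_b, labels) -> RocComparison:
    """DeLong's test for two correlated AUCs measured on the same subjects."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have identical shape")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    m = int(y.sum())
    n = int((~y).sum())
    v10a, v01a = _placements(a, y)
    v10b, v01b = _placements(b, y)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return RocComparison(
            auc_a, auc_b, cov[0, 0], cov[1, 1], cov[0, 1], z=0.0, p=1.0, degenerate=True
        )
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return RocComparison(auc_a, auc_b, cov[0, 0], cov[1, 1], cov[0, 1], z=float(z), p=float(p))


def lr_test(nested: UnconditionalLogitFit, full: UnconditionalLogitFit):
    """Likelihood-ratio test of nested unconditional logistic fits."""
    if not set(nested.predictors) <= set(full.predictors):
        raise ValueError("models are not nested")
    if nested.nobs != full.nobs:
        raise ValueError("models were fitted on different record counts")
    df = full.df_model - nested.df_model
    if df <= 0:
        raise ValueError("full model must add at least one predictor")
    chi2 = max(0.0, 2.0 * (full.llf - nested.llf))
    p = float(scipy.stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p
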