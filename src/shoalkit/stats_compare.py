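"""Line-versus-control comparisons respecting the replicate-line design.

Replicate selection lines — not trials — are the units of independent
evolution, so every inferential path here keeps the line as the clustering
unit: the mixed model puts a random intercept on each replicate line and
refers the regime contrast to a t distribution on Satterthwaite-style
effective degrees of freedom (between-line information is scarce, so a
normal reference would overstate certainty);
count responses use a Poisson GEE with exchangeable correlation within
lines, reported as incidence-rate ratios; and the permutation test
reassigns whole line labels between regimes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .io_model import ValidationError

__all__ = [
    "ContrastResult",
    "compare_lines",
    "line_permutation_test",
    "adjusted_contrasts",
    "satterthwaite_df",
]


def satterthwaite_df(
    var_between: float, var_within_line_mean: float, n_lines: int, n_obs: int
) -> float:
    """Welch-Satterthwaite degrees of freedom for a regime contrast.

    The variance of a line-mean contrast mixes a between-line component
    (``n_lines - 2`` df) with a within-line component carried by the
    residual (``n_obs - n_lines`` df); the effective df interpolates
    between the two according to the estimated variance shares, so a
    design dominated by between-line variance is judged on few df and one
    with negligible line variance on many.
    """
    a = max(float(var_between), 0.0)
    b = max(float(var_within_line_mean), 0.0)
    df_a = max(n_lines - 2, 1)
    df_b = max(n_obs - n_lines, 1)
    if a + b <= 0:
        return float(df_b)
    return float((a + b) ** 2 / (a * a / df_a + b * b / df_b))


@dataclass
class ContrastResult:
    """A polarization-vs-control contrast for one response variable."""

    response: str
    estimate: float
    ci_low: float
    ci_high: float
    pvalue: float
    method: str  # "mixed_model" | "poisson_gee" | "line_permutation"
    n_obs: int
    n_lines: int
    scale: str = "difference"  # "difference" (identity) or "ratio" (IRR)
    extra: dict = field(default_factory=dict)


def _check_design(df: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in ("line", "replicate", response):
        if col not in df.columns:
            raise ValidationError(f"summaries lack column {col!r}")
    df = df.dropna(subset=[response]).copy()
    df["line"] = pd.Categorical(df["line"], categories=["control", "polarization"])
    if df["line"].isna().any():
        raise ValidationError("line must be 'polarization' or 'control'")
    df["line_id"] = df["line"].astype(str) + ":" + df["replicate"].astype(str)
    return df


def compare_lines(
    summaries: pd.DataFrame,
    response: str,
    family: str = "gaussian",
    covariates: list[str] | None = None,
    method: str = "mixed",
) -> ContrastResult:
    """Regime contrast for one response from a table of trial summaries.

    ``summaries`` needs columns ``line`` (polarization/control),
    ``replicate`` (index of the replicate line within its regime) and the
    response; optional ``covariates`` (e.g. treatment, presentation order,
    body size) enter as fixed effects.

    - ``family="gaussian"``: identity scale.  ``method="mixed"`` fits a
      random-intercept-per-line LMM (REML) and refers the contrast to a t
      distribution on Satterthwaite degrees of freedom;
      ``method="fixed"`` is the fixed-effects fallback with the
      within-regime replicate index as crossed dummies.
    - ``family="poisson"``: log-link GEE with exchangeable correlation
      within replicate lines; the estimate is the incidence-rate ratio.
    """
    covariates = covariates or []
    df = _check_design(summaries, response)
    n_lines = df["line_id"].nunique()
    reps = df.groupby("line", observed=True)["replicate"].nunique()
    if method == "mixed" and (reps < 2).any():
        raise ValidationError(
            "mixed model needs >= 2 replicate lines per regime; "
            "use line_permutation_test instead"
        )
    rhs = " + ".join(["line"] + covariates)
    dof = max(n_lines - 2, 1)
    term = "line[T.polarization]"

    if family == "gaussian":
        if method == "mixed":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(f"{response} ~ {rhs}", df, groups=df["line_id"]).fit(
                    reml=True
                )
            m = len(df) / n_lines
            dof = satterthwaite_df(
                float(np.asarray(fit.cov_re)[0, 0]),
                float(fit.scale) / m,
                n_lines,
                len(df),
            )
        elif method == "fixed":
            fit = smf.ols(f"{response} ~ {rhs} + C(replicate)", df).fit()
            dof = float(fit.df_resid)
        else:
            raise ValidationError(f"unknown method {method!r}")
        coef = float(fit.params[term])
        se = float(fit.bse[term])
        tval = coef / se if se > 0 else np.inf * np.sign(coef or 1)
        pvalue = float(2 * stats.t.sf(abs(tval), dof)) if np.isfinite(tval) else 0.0
        half = stats.t.ppf(0.975, dof) * se
        if not np.isfinite(half):
            half = 0.0
        return ContrastResult(
            response, coef, coef - half, coef + half, pvalue,
            "mixed_model" if method == "mixed" else "fixed_effects",
            len(df), n_lines, "difference",
            {"se": se, "df": dof},
        )
    if family == "poisson":
        model = smf.gee(
            f"{response} ~ {rhs}",
            groups=df["line_id"],
            data=df,
            family=sm.families.Poisson(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit()
        coef = float(fit.params[term])
        se = float(fit.bse[term])
        tval = coef / se if se > 0 else np.inf * np.sign(coef or 1)
        pvalue = float(2 * stats.t.sf(abs(tval), dof)) if np.isfinite(tval) else 0.0
        half = stats.t.ppf(0.975, dof) * se
        mu = np.asarray(fit.fittedvalues)
        resp = df[response].to_numpy(dtype=float)
        dispersion = float(np.mean((resp - mu) ** 2 / np.maximum(mu, 1e-12)))
        return ContrastResult(
            response, float(np.exp(coef)),
            float(np.exp(coef - half)), float(np.exp(coef + half)),
            pvalue, "poisson_gee", len(df), n_lines, "ratio",
            {"log_irr": coef, "se": se, "df": dof, "dispersion": dispersion},
        )
    raise ValidationError(f"unknown family {family!r}")


def line_permutation_test(
    summaries: pd.DataFrame,
    response: str,
    B: int = 999,
    seed: int | None = None,
) -> ContrastResult:
    """Design-respecting permutation test of the regime contrast.

    The statistic is the difference of regime means of *replicate-line
    means* (each line contributes once, since trials within a line are
    pseudo-replicates).  Line labels are reassigned between regimes:
    exhaustively when the number of assignments is at most 1000, else by B
    Monte-Carlo draws with ``p = (1 + #{|T*| >= |T|}) / (1 + B)``.  The
    reported interval is a t interval on the line means (df = n_lines - 2).
    """
    df = _check_design(summaries, response)
    line_means = df.groupby(["line_id", "line"], observed=True)[response].mean().reset_index()
    labels = (line_means["line"] == "polarization").to_numpy()
    values = line_means[response].to_numpy(dtype=float)
    n_lines = len(values)
    n_pol = int(labels.sum())
    if n_lines < 3:
        raise ValidationError("permutation test needs at least 3 replicate lines")
    if B < 99:
        warnings.warn(f"B={B} gives a very coarse permutation p-value", stacklevel=2)

    def statistic(mask: np.ndarray) -> float:
        return float(values[mask].mean() - values[~mask].mean())

    observed = statistic(labels)
    n_assign = comb(n_lines, n_pol)
    if n_assign <= 1000:
        perm = np.array(
            [
                statistic(np.isin(np.arange(n_lines), idx))
                for idx in itertools.combinations(range(n_lines), n_pol)
            ]
        )
        pvalue = float(np.mean(np.abs(perm) >= np.abs(observed) - 1e-12))
        exact = True
        n_draws = n_assign
    else:
        rng = np.random.default_rng(seed)
        perm = np.empty(B)
        idx = np.arange(n_lines)
        for b in range(B):
            rng.shuffle(idx)
            mask = np.zeros(n_lines, dtype=bool)
            mask[idx[:n_pol]] = True
            perm[b] = statistic(mask)
        pvalue = float((1 + np.sum(np.abs(perm) >= np.abs(observed) - 1e-12)) / (1 + B))
        exact = False
        n_draws = B

    pol = values[labels]
    con = values[~labels]
    se = float(
        np.sqrt(
            pol.var(ddof=1) / len(pol) + con.var(ddof=1) / len(con)
        )
    ) if min(len(pol), len(con)) > 1 else 0.0
    half = stats.t.ppf(0.975, max(n_lines - 2, 1)) * se
    return ContrastResult(
        response, observed, observed - half, observed + half, pvalue,
        "line_permutation", len(df), n_lines, "difference",
        {"exact": exact, "n_permutations": int(n_draws)},
    )


def adjusted_contrasts(
    summaries: pd.DataFrame,
    response: str,
    between: str = "line",
    within: str | None = "treatment",
) -> pd.DataFrame:
    """Tukey-adjusted pairwise ``between``-group contrasts of a response.

    Groups are the crossing of ``between`` with ``within`` (when given);
    all pairwise comparisons are adjusted family-wise with the Tukey HSD
    studentised-range method, and the rows comparing ``between`` levels at
    the same ``within`` level are returned (with the within level
    labelled).  With only two groups the adjustment reduces to the plain
    two-sample case.  Adjusted p-values never fall below unadjusted ones.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = summaries.dropna(subset=[response]).copy()
    if within is not None and within in df.columns and df[within].nunique() > 1:
        group = df[between].astype(str) + "|" + df[within].astype(str)
    else:
        within = None
        group = df[between].astype(str) + "|"
    tukey = pairwise_tukeyhsd(df[response].to_numpy(dtype=float), group.to_numpy())
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    lev1 = table["group1"].str.split("|", expand=True)
    lev2 = table["group2"].str.split("|", expand=True)
    keep = lev1[1] == lev2[1]
    out = table[keep].copy()
    out["within_level"] = lev1.loc[keep, 1]
    out["group1"] = lev1.loc[keep, 0]
    out["group2"] = lev2.loc[keep, 0]
    out = out.rename(columns={"p-adj": "pvalue_adj", "meandiff": "estimate"})
    return out.reset_index(drop=True)
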