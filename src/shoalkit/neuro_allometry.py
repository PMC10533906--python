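"""Brain and brain-region allometry with selection-line contrasts.

Each of the 11 parcellated regions is modelled on the log scale against
the log volume of the *rest of the brain* (whole brain minus the region of
interest) with selection regime as fixed effect and a random intercept per
replicate selection line; the whole-brain model uses log standard length
as the covariate instead.  Working on logs makes the regime contrast a
volume *ratio* (reported as a percent difference), which is scale
equivariant: multiplying every volume by a constant changes nothing.

The study's fully multivariate Bayesian model (with an LKJ prior on the
residual correlation matrix) is approximated here by the simpler
frequentist route: per-region residual vectors after removing covariate,
regime and replicate effects, then their plain correlation matrix.  This
is an approximation, not a reproduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .io_model import BRAIN_REGIONS, BrainVolumeTable, ValidationError

__all__ = [
    "AllometryResult",
    "rest_of_brain",
    "fit_region_model",
    "fit_all_regions",
    "residual_correlations",
]


@dataclass
class AllometryResult:
    """Selection-line contrast for one region (or the whole brain).

    ``ratio`` is the multiplicative polarization/control volume difference
    at fixed covariate (``exp`` of the regime coefficient on the log
    scale); ``percent_diff`` is ``(ratio - 1) * 100``.
    """

    region: str
    ratio: float
    ci_low: float
    ci_high: float
    percent_diff: float
    slope: float  # log-log covariate slope
    pvalue: float
    method: str  # "mixed" or "fixed"
    n_per_line: dict
    converged: bool
    residual_normal: bool


def _prep(table: BrainVolumeTable) -> pd.DataFrame:
    df = table.data.copy()
    df["line"] = pd.Categorical(df["line"], categories=["control", "polarization"])
    df["line_id"] = df["line"].astype(str) + ":" + df["replicate"].astype(str)
    return df


def rest_of_brain(table: BrainVolumeTable, region: str) -> np.ndarray:
    """Per-fish whole-brain volume excluding the region of interest."""
    if region not in BRAIN_REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    rest = (table.data["whole_brain"] - table.data[region]).to_numpy(dtype=float)
    if not (rest > 0).all():
        raise ValidationError(f"region {region} volume not below whole-brain volume")
    return rest


def fit_region_model(
    table: BrainVolumeTable,
    region: str | None = None,
    method: str = "mixed",
) -> AllometryResult:
    """Fit the allometric line-contrast model for one region.

    ``region=None`` fits the whole-brain model (log whole-brain volume vs
    log standard length).  ``method="mixed"`` uses a linear mixed model
    with a random intercept per replicate selection line, with the regime
    contrast referred to a t distribution on Satterthwaite effective
    degrees of freedom (between-line information is what identifies it);
    ``method="fixed"`` is the fixed-effects fallback with the within-regime
    replicate index as crossed dummies.  A singular or non-converged mixed
    fit is reported in the diagnostics, never silently replaced.
    """
    df = _prep(table)
    if region is None:
        y = np.log(df["whole_brain"].to_numpy(dtype=float))
        x = np.log(df["standard_length"].to_numpy(dtype=float))
        name = "whole_brain"
    else:
        y = np.log(df[region].to_numpy(dtype=float))
        x = np.log(rest_of_brain(table, region))
        name = region
    df = df.assign(log_y=y, log_x=x)
    n_per_line = df.groupby("line", observed=True).size().to_dict()
    if min(n_per_line.values(), default=0) < 2:
        warnings.warn("fewer than 2 fish in a selection regime", stacklevel=2)
    n_reps = df.groupby("line", observed=True)["replicate"].nunique()
    if (n_reps < 2).any():
        warnings.warn("fewer than 2 replicate lines per regime", stacklevel=2)

    if method == "mixed":
        model = smf.mixedlm("log_y ~ log_x + line", df, groups=df["line_id"])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = model.fit(reml=True)
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        converged = bool(getattr(fit, "converged", True)) and not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        # a boundary collapse can zero out every parameter; that is a
        # failed fit even when the optimizer claims success
        if abs(float(fit.params["Intercept"])) < 1e-10 and abs(
            float(fit.params["line[T.polarization]"])
        ) < 1e-12:
            converged = False
        coef = float(fit.params["line[T.polarization]"])
        se = float(fit.bse["line[T.polarization]"])
        slope = float(fit.params["log_x"])
        try:
            resid = np.asarray(fit.resid)
        except ValueError:
            # zero line variance makes BLUP prediction singular; fall back
            # to marginal (fixed-effects) residuals for the diagnostics
            resid = df["log_y"].to_numpy() - np.asarray(model.exog) @ np.asarray(
                fit.fe_params
            )
        from .stats_compare import satterthwaite_df

        n_lines = df["line_id"].nunique()
        dof = satterthwaite_df(
            float(np.asarray(fit.cov_re)[0, 0]),
            float(fit.scale) / max(len(df) / n_lines, 1.0),
            n_lines,
            len(df),
        )
        tval = coef / se if se > 0 else np.inf * np.sign(coef or 1)
        pvalue = float(2 * stats.t.sf(abs(tval), dof)) if np.isfinite(tval) else 0.0
        half = stats.t.ppf(0.975, dof) * se
    elif method == "fixed":
        model = smf.ols("log_y ~ log_x + line + C(replicate)", df)
        fit = model.fit()
        converged = True
        coef = float(fit.params["line[T.polarization]"])
        se = float(fit.bse["line[T.polarization]"])
        slope = float(fit.params["log_x"])
        resid = np.asarray(fit.resid)
        dof = int(fit.df_resid)
        pvalue = float(fit.pvalues["line[T.polarization]"])
        half = stats.t.ppf(0.975, max(dof, 1)) * se
    else:
        raise ValidationError(f"unknown method {method!r}")

    if not np.isfinite(half):
        half = 0.0
    resid_normal = True
    if len(resid) >= 8 and np.std(resid) > 0:
        resid_normal = bool(stats.shapiro(resid).pvalue > 0.01)
    return AllometryResult(
        region=name,
        ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - half)),
        ci_high=float(np.exp(coef + half)),
        percent_diff=float((np.exp(coef) - 1.0) * 100.0),
        slope=slope,
        pvalue=pvalue,
        method=method,
        n_per_line={str(k): int(v) for k, v in n_per_line.items()},
        converged=converged,
        residual_normal=resid_normal,
    )


def fit_all_regions(table: BrainVolumeTable, method: str = "mixed") -> pd.DataFrame:
    """Line contrasts for all 11 regions, with Holm-adjusted p-values alongside.

    The per-region tests are reported unadjusted (as in the study design)
    with the Holm family-wise adjustment carried in a separate column.
    """
    results = [fit_region_model(table, region, method) for region in BRAIN_REGIONS]
    frame = pd.DataFrame([vars(r) for r in results])
    from statsmodels.stats.multitest import multipletests

    frame["pvalue_holm"] = multipletests(frame["pvalue"].fillna(1.0), method="holm")[1]
    return frame


def residual_correlations(table: BrainVolumeTable) -> pd.DataFrame:
    """Region-by-region correlation of allometric model residuals.

    For each region, residuals of OLS log(volume) on log(rest of brain),
    regime and replicate dummies; the matrix of their pairwise Pearson
    correlations approximates the residual correlation structure of the
    multivariate model.  Symmetric with unit diagonal by construction.
    """
    df = _prep(table)
    # one intercept per replicate selection line (line:replicate) removes the
    # regime effect and every between-line shift in one go
    rank = 1 + df["line_id"].nunique()
    if len(df) <= rank:
        raise ValidationError(
            f"need more than {rank} fish to estimate residual correlations"
        )
    resids = {}
    for region in BRAIN_REGIONS:
        sub = df.assign(
            log_y=np.log(df[region].astype(float)),
            log_x=np.log(rest_of_brain(table, region)),
        )
        fit = smf.ols("log_y ~ log_x + C(line_id)", sub).fit()
        resids[region] = np.asarray(fit.resid)
    mat = np.corrcoef(np.column_stack([resids[r] for r in BRAIN_REGIONS]), rowvar=False)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=list(BRAIN_REGIONS), columns=list(BRAIN_REGIONS))
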