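"""Acquisition-setting effects on the VRI and its variability.

Two model families operate on the long-format study table:

* **Mean effects** — a linear mixed model with the VRI (or one of its
  components) as response, the acquisition setting as a categorical fixed
  factor, and nested random intercepts for subject and raster scan within
  subject.  This respects the clustering of the 7 sections inside a scan
  and of the 3 repeated scans inside a subject.

* **Variability** — residuals are formed at three levels: each section
  about its scan mean (within-scan), each scan mean about its repetition
  mean (intra-subject), and each subject mean about the across-subject
  mean (inter-subject).  Under approximate normality the squared residuals
  are Gamma-distributed, so a Gamma GLM with a log link models their mean
  per setting; the reported variability is the square root of the fitted
  mean — a model-based RMS dispersion at that level.

Overall factor significance uses likelihood-ratio tests; pairwise
contrasts are adjusted with the Tukey (studentized-range) method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .synthetic import ScanSlot, art_arm, focus_arm

__all__ = [
    "MixedFit",
    "VariabilityFit",
    "RESIDUAL_LEVELS",
    "apply_exclusions",
    "failure_summary",
    "fit_mean_model",
    "compute_level_residuals",
    "fit_variability",
    "pairwise_compare",
    "boxplot_stats",
    "recover_variance_components",
    "reference_differences",
]

RESIDUAL_LEVELS = ("within_scan", "intra_subject", "inter_subject")

_SCAN_KEY = ["subject", "position", "art", "focus", "repetition"]
_CELL_KEY = ["subject", "position", "art", "focus"]
_SETTING_KEY = ["position", "art", "focus"]

# Each factor is analysed on its own arm of the protocol, holding the other
# acquisition parameters at their reference values.
_ARM_FILTERS = {
    "art": lambda t: (t["position"] == "middle") & (t["focus"] == 0),
    "focus": lambda t: (t["position"] == "middle") & (t["art"] == 100),
    "position": lambda t: (t["art"] == 100) & (t["focus"] == 0),
}


def _measured(table: pd.DataFrame) -> pd.DataFrame:
    return table[(~table["failed"].astype(bool)) & table["vri"].notna()]


def _subset_for_factor(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    if factor not in _ARM_FILTERS:
        raise ValueError(f"factor must be one of {sorted(_ARM_FILTERS)}, got {factor!r}")
    return table[_ARM_FILTERS[factor](table)]


# ---------------------------------------------------------------------------
# Exclusions and failure accounting
# ---------------------------------------------------------------------------


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop under-measured raster scans and repetitions.

    A raster scan (subject x setting x repetition) must provide at least 3
    measured sections, and a subject x setting cell at least 2 surviving
    repetitions; otherwise the scan, or the whole cell, is discarded.
    Failed rows are removed from the returned table.  The log records every
    exclusion.  The operation is idempotent.
    """
    log: list[str] = []
    kept = _measured(table)

    n_dropped_rows = len(table) - len(kept)
    if n_dropped_rows:
        log.append(f"dropped {n_dropped_rows} failed/unmeasured rows")

    scan_sizes = kept.groupby(_SCAN_KEY, sort=False)["vri"].transform("size")
    bad_scans = scan_sizes < 3
    for key, grp in kept[bad_scans].groupby(_SCAN_KEY, sort=False):
        log.append(
            f"excluded raster scan subject={key[0]} setting={key[1]}/ART{key[2]}/"
            f"{key[3]:+d}D repetition={key[4]}: only {len(grp)} of 7 sections measured"
        )
    kept = kept[~bad_scans]

    reps_per_cell = kept.groupby(_CELL_KEY, sort=False)["repetition"].transform("nunique")
    bad_cells = reps_per_cell < 2
    for key, _ in kept[bad_cells].groupby(_CELL_KEY, sort=False):
        log.append(
            f"excluded cell subject={key[0]} setting={key[1]}/ART{key[2]}/"
            f"{key[3]:+d}D: fewer than 2 surviving repetitions"
        )
    kept = kept[~bad_cells]
    return kept.reset_index(drop=True), log


def failure_summary(slots: Sequence[ScanSlot], table: pd.DataFrame) -> pd.DataFrame:
    """Per-arm theoretical counts, failed counts and integer failure rates.

    A slot counts as failed when no successful measurement exists for it in
    the table — whether the measurement failed or the scan was never
    obtained.  Percentages are rounded to the nearest integer percent.
    """
    ok = _measured(table)
    ok_keys = set(zip(ok["subject"], ok["position"], ok["art"], ok["focus"],
                      ok["repetition"], ok["section"]))
    rows = {}
    for arm_name, arm_slots in (("art", art_arm(slots)), ("focus", focus_arm(slots))):
        theoretical = len(arm_slots)
        failed = sum(1 for s in arm_slots if s.key not in ok_keys)
        pct = int(round(100.0 * failed / theoretical)) if theoretical else 0
        rows[arm_name] = dict(theoretical=theoretical, failed=failed, failure_pct=pct)
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Mean-effects mixed model
# ---------------------------------------------------------------------------


@dataclass
class MixedFit:
    """Per-level fixed-effect estimates from the nested mixed model."""

    factor: str
    response: str
    levels: list
    estimates: pd.Series
    se: pd.Series
    cov: pd.DataFrame            # covariance of the per-level estimates
    p_value: float               # overall factor p (likelihood-ratio test)
    var_subject: float
    var_scan: float
    var_residual: float
    df_resid: float
    converged: bool
    notes: list[str] = field(default_factory=list)

    # used by pairwise_compare
    @property
    def contrast_scale(self) -> str:
        return "response"


def _parse_levels(index: Iterable[str], factor: str) -> list:
    out = []
    for name in index:
        lv = name.split("[", 1)[1].rstrip("]")
        try:
            out.append(int(lv))
        except ValueError:
            out.append(lv)
    return out


def fit_mean_model(
    table: pd.DataFrame, factor: str, response: str = "vri"
) -> MixedFit:
    """Mixed model for the effect of one acquisition factor on the response.

    The table is restricted to the factor's protocol arm.  Random
    intercepts: subject, and raster scan nested in subject; estimation by
    REML for reporting, with ML refits for the likelihood-ratio test of the
    factor against the intercept-only model.
    """
    data = _measured(_subset_for_factor(table, factor)).copy()
    if data.empty:
        raise ValueError(f"no measured rows for factor {factor!r}")
    data["scan"] = (
        data["position"].astype(str) + "_" + data["art"].astype(str) + "_"
        + data["focus"].astype(str) + "_" + data["repetition"].astype(str)
    )
    levels_present = sorted(data[factor].unique())
    if len(levels_present) < 2:
        raise ValueError(f"need >= 2 levels of {factor!r}, found {levels_present}")
    if data["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")

    notes: list[str] = []
    cell_means = data.groupby([factor])[response].transform("mean")
    # degenerate (noise-free) input: every observation equals its level mean
    if float(((data[response] - cell_means) ** 2).sum()) < 1e-24:
        est = data.groupby(factor)[response].mean()
        est = est.reindex(levels_present)
        zeros = pd.Series(0.0, index=est.index)
        notes.append("degenerate zero-variance input; estimates are level means")
        return MixedFit(
            factor=factor, response=response, levels=levels_present,
            estimates=est, se=zeros,
            cov=pd.DataFrame(0.0, index=est.index, columns=est.index),
            p_value=float("nan"), var_subject=0.0, var_scan=0.0, var_residual=0.0,
            df_resid=float(len(data) - len(levels_present)),
            converged=True, notes=notes,
        )

    formula = f"{response} ~ 0 + C({factor})"
    vc = {"scan": "0 + C(scan)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups="subject", re_formula="1", vc_formula=vc)
        fit_reml = model.fit(reml=True)
        fit_ml = model.fit(reml=False)
        null_ml = smf.mixedlm(
            f"{response} ~ 1", data, groups="subject", re_formula="1", vc_formula=vc
        ).fit(reml=False)

    converged = bool(getattr(fit_reml, "converged", True))
    if not converged:
        notes.append("REML fit did not converge; estimates reported with warning")

    k = model.k_fe
    fe_names = model.exog_names
    levels = _parse_levels(fe_names, factor)
    est = pd.Series(np.asarray(fit_reml.fe_params), index=levels)
    cov_fe = pd.DataFrame(
        np.asarray(fit_reml.cov_params())[:k, :k], index=levels, columns=levels
    )
    se = pd.Series(np.sqrt(np.clip(np.diag(cov_fe), 0.0, None)), index=levels)

    lr = 2.0 * (fit_ml.llf - null_ml.llf)
    df = len(levels) - 1
    p = float(sps.chi2.sf(max(lr, 0.0), df))

    var_scan = float(np.asarray(fit_reml.vcomp).ravel()[0]) if model.k_vc else 0.0
    return MixedFit(
        factor=factor, response=response, levels=levels,
        estimates=est, se=se, cov=cov_fe, p_value=p,
        var_subject=float(np.asarray(fit_reml.cov_re).ravel()[0]),
        var_scan=var_scan,
        var_residual=float(fit_reml.scale),
        df_resid=float(len(data) - k),
        converged=converged, notes=notes,
    )


# ---------------------------------------------------------------------------
# Residual decomposition
# ---------------------------------------------------------------------------


def compute_level_residuals(
    table: pd.DataFrame, level: str, pool_settings: bool = False
) -> pd.DataFrame:
    """Residuals at one of the three nesting levels.

    within_scan     each measurement about the mean of its raster scan's
                    (available) sections;
    intra_subject   each raster-scan mean about the mean of the repetitions
                    in its subject x setting cell;
    inter_subject   each subject's mean about the across-subject mean,
                    per setting (or pooled over settings when
                    ``pool_settings`` is set).

    Groups with a single member contribute an (exactly zero) residual and
    are flagged ``singleton``.  Exclusions should be applied first.
    """
    if level not in RESIDUAL_LEVELS:
        raise ValueError(f"level must be one of {RESIDUAL_LEVELS}, got {level!r}")
    data = _measured(table)

    if level == "within_scan":
        grp = data.groupby(_SCAN_KEY, sort=False)["vri"]
        out = data[_SCAN_KEY + ["section"]].copy()
        out["residual"] = data["vri"] - grp.transform("mean")
        out["singleton"] = grp.transform("size") == 1
    elif level == "intra_subject":
        scans = (
            data.groupby(_SCAN_KEY, sort=False, as_index=False)["vri"].mean()
        )
        grp = scans.groupby(_CELL_KEY, sort=False)["vri"]
        out = scans[_SCAN_KEY].copy()
        out["residual"] = scans["vri"] - grp.transform("mean")
        out["singleton"] = grp.transform("size") == 1
    else:  # inter_subject
        subj = (
            data.groupby(_CELL_KEY, sort=False, as_index=False)["vri"].mean()
        )
        keys = [] if pool_settings else _SETTING_KEY
        if keys:
            grp = subj.groupby(keys, sort=False)["vri"]
            centred = subj["vri"] - grp.transform("mean")
            sizes = grp.transform("size")
        else:
            centred = subj["vri"] - subj["vri"].mean()
            sizes = pd.Series(len(subj), index=subj.index)
        out = subj[_CELL_KEY].copy()
        out["residual"] = centred
        out["singleton"] = sizes == 1

    out.loc[out["singleton"], "residual"] = 0.0
    out["sq_residual"] = out["residual"] ** 2
    out["level"] = level
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gamma-GLM variability model
# ---------------------------------------------------------------------------


@dataclass
class VariabilityFit:
    """Variability (RMS scale) per factor level from the Gamma GLM."""

    factor: str
    level: str
    levels: list
    variability: pd.Series       # sqrt of fitted mean squared residual
    log_means: pd.Series         # linear-predictor scale (log of mean sq resid)
    cov: pd.DataFrame            # covariance of the log-mean estimates
    p_value: float
    df_resid: float
    n_obs: int
    n_zero_dropped: int
    notes: list[str] = field(default_factory=list)

    @property
    def contrast_scale(self) -> str:
        return "log"

    # pairwise_compare wants estimates on the contrast scale
    @property
    def estimates(self) -> pd.Series:
        return self.log_means


def fit_variability(resid: pd.DataFrame, factor: str) -> VariabilityFit:
    """Gamma GLM (log link) of squared residuals on one acquisition factor.

    The fitted mean squared residual per factor level is reported through
    its square root — the level's RMS variability.  Exact zeros are
    undefined under the Gamma likelihood and are dropped with a logged
    count (they arise only in degenerate, noise-free input).  The overall
    p-value is a likelihood-ratio (scaled-deviance) test against the
    intercept-only model.
    """
    data = _subset_for_factor(resid, factor).copy()
    if "level" in data.columns and data["level"].nunique() > 1:
        raise ValueError("residual table mixes levels; fit one level at a time")
    notes: list[str] = []

    n_zero = int((data["sq_residual"] <= 0).sum())
    if n_zero:
        notes.append(f"dropped {n_zero} exact-zero squared residuals")
        data = data[data["sq_residual"] > 0]
    if data.empty:
        raise ValueError("no positive squared residuals to model")

    levels = sorted(data[factor].unique())
    for lv in levels[:]:
        if not (data.loc[data[factor] == lv, "sq_residual"] > 0).any():
            notes.append(f"level {lv} excluded: all squared residuals zero")
            levels.remove(lv)
    data = data[data[factor].isin(levels)]

    y = data["sq_residual"].to_numpy(float)
    X = pd.get_dummies(pd.Categorical(data[factor], categories=levels), dtype=float)
    X.columns = levels
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = sm.families.Gamma(link=sm.families.links.Log())
            fit = sm.GLM(y, X.to_numpy(), family=fam).fit()
            if len(levels) > 1:
                null = sm.GLM(y, np.ones((len(y), 1)), family=fam).fit()
                lr = (null.deviance - fit.deviance) / fit.scale
                p = float(sps.chi2.sf(max(lr, 0.0), len(levels) - 1))
            else:
                p = float("nan")
        log_means = pd.Series(fit.params, index=levels)
        cov = pd.DataFrame(np.asarray(fit.cov_params()), index=levels, columns=levels)
        df_resid = float(fit.df_resid)
    except ValueError:
        # zero-dispersion boundary (constant squared residuals per level):
        # the saturated one-factor Gamma GLM fits the group means exactly
        notes.append("degenerate dispersion; closed-form group means used")
        group_means = data.groupby(factor)["sq_residual"].mean().reindex(levels)
        log_means = pd.Series(np.log(group_means.to_numpy()), index=levels)
        cov = pd.DataFrame(0.0, index=levels, columns=levels)
        p = float("nan")
        df_resid = float(len(y) - len(levels))
    return VariabilityFit(
        factor=factor,
        level=str(data["level"].iloc[0]) if "level" in data.columns else "",
        levels=levels,
        variability=np.sqrt(np.exp(log_means)),
        log_means=log_means,
        cov=cov,
        p_value=p,
        df_resid=df_resid,
        n_obs=len(y),
        n_zero_dropped=n_zero,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Pairwise contrasts (Tukey)
# ---------------------------------------------------------------------------


def pairwise_compare(fit: MixedFit | VariabilityFit) -> pd.DataFrame:
    """All pairwise level contrasts with Tukey-adjusted p-values.

    The adjustment uses the studentized-range distribution over the complete
    pairwise family of the factor.  For mean fits the contrast is a
    difference on the response scale; for variability fits it is a
    difference of log mean squared residuals (so ``exp(estimate)`` is the
    variance ratio).  With two levels the adjusted p-value reduces to the
    unadjusted two-sided p.
    """
    levels = list(fit.estimates.index)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels to compare")
    df = max(float(fit.df_resid), 1.0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(fit.estimates[a] - fit.estimates[b])
            var = float(fit.cov.loc[a, a] + fit.cov.loc[b, b] - 2 * fit.cov.loc[a, b])
            se = float(np.sqrt(max(var, 0.0)))
            if se == 0:
                stat, p = float("inf") if diff else 0.0, 0.0 if diff else 1.0
            else:
                stat = diff / se
                q = abs(stat) * np.sqrt(2.0)
                p = float(sps.studentized_range.sf(q, k, min(df, 1e6)))
            rows.append(dict(level_a=a, level_b=b, estimate=diff, se=se,
                             statistic=stat, p_tukey=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Descriptive helpers
# ---------------------------------------------------------------------------


def boxplot_stats(values: Iterable[float]) -> dict:
    """Five-number box-plot summary with 1.5 x IQR whiskers.

    Quartiles use linear interpolation; whiskers sit on the most extreme
    data points within ``Q1 - 1.5 IQR`` and ``Q3 + 1.5 IQR``; points beyond
    are flagged as outliers.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo) & (x <= hi)]
    outliers = np.sort(x[(x < lo) | (x > hi)])
    # whiskers never retreat inside the box (Tukey's convention)
    whisker_low = min(float(inside.min()), float(q1))
    whisker_high = max(float(inside.max()), float(q3))
    return dict(
        q1=float(q1), median=float(q2), q3=float(q3), iqr=float(iqr),
        whisker_low=whisker_low, whisker_high=whisker_high,
        outliers=[float(v) for v in outliers], n=int(x.size),
    )


def recover_variance_components(table: pd.DataFrame) -> dict[str, float]:
    """Pooled RMS variability at each nesting level of a study table.

    Runs the three-level residual decomposition over the whole (measured,
    post-exclusion) table and returns, per level, the square root of the
    mean squared residual pooled across settings — the estimator behind the
    Gamma-GLM variability with a single pooled group.  Singleton groups are
    excluded.
    """
    out = {}
    for level in RESIDUAL_LEVELS:
        r = compute_level_residuals(table, level)
        r = r[~r["singleton"]]
        out[level] = float(np.sqrt(r["sq_residual"].mean())) if len(r) else float("nan")
    return out


def reference_differences(
    means: Mapping, reference, ndigits: int | None = None
) -> dict:
    """Differences of per-level estimates from a reference level.

    This is the report generator's level-vs-reference summary (e.g. each
    focus offset against the in-focus condition).  ``ndigits`` optionally
    rounds to the reporting precision.
    """
    if reference not in means:
        raise KeyError(f"reference level {reference!r} not among the estimates")
    ref = means[reference]
    out = {}
    for lv, v in means.items():
        if lv == reference:
            continue
        d = v - ref
        out[lv] = round(d, ndigits) if ndigits is not None else d
    return out
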