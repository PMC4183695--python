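"""Covariate-adjusted mass-univariate regressions with per-dependent FDR.

Each test is an ordinary least-squares regression of one polysomnographic
variable (dependent) on one morphometric variable (independent), with
intracranial volume, age and sex as additive covariates plus an intercept:

    psg ~ 1 + morph + icv + age + sex        (df = n - 5)

Two analysis plans are provided.  The hypothesis plan holds 14 a-priori
tests (slow-wave bands against orbitofrontal/posterior-cingulate/anterior
corpus callosum morphology, total sleep time against hippocampal volumes,
plus a corpus-callosum variant without the ICV covariate restricted to
subjects younger than 40), each evaluated at raw two-tailed p < .05.  The
explorative plan crosses 39 polysomnographic variables with all 174
morphometric variables (6786 regressions) and applies Benjamini-Hochberg
FDR separately within each dependent variable's 174 tests.

Convenience operations cover the residual-method covariate adjustment used
for scatter plots, Fisher's Z mean correlation, and the descriptive ICV
statistics (Pearson ICV-age correlation, two-sample t for ICV by sex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .morphometry import MORPH_COLUMNS

__all__ = [
    "RegressionResult",
    "PlanItem",
    "AnalysisPlan",
    "DEFAULT_COVARIATES",
    "CONTINUITY_VARIABLES",
    "EVENT_VARIABLES",
    "SPECTRAL_VARIABLES",
    "EXPLORATIVE_PSG_VARIABLES",
    "fit_univariate",
    "fdr_adjust",
    "hypothesis_plan",
    "explorative_plan",
    "run_plan",
    "residual_adjust",
    "fisher_mean_correlation",
    "icv_age_correlation",
    "icv_sex_ttest",
    "age_morphometry_correlations",
]

DEFAULT_COVARIATES: tuple[str, ...] = ("icv", "age", "sex")

#: 11 sleep continuity / architecture variables (night 2 in the study design).
CONTINUITY_VARIABLES: tuple[str, ...] = (
    "tst_min",
    "sleep_efficiency_pct",
    "sol_min",
    "spt_min",
    "n_awakenings",
    "waso_min",
    "arousal_index_per_h",
    "pct_spt_n1",
    "pct_spt_n2",
    "pct_spt_sws",
    "pct_spt_rem",
)

#: 8 leg-movement and respiratory variables (night 1 in the study design).
EVENT_VARIABLES: tuple[str, ...] = (
    "leg_movements",
    "leg_movements_arousal",
    "plms",
    "plms_arousal",
    "plms_index",
    "plms_arousal_index",
    "ahi",
    "apnea_index",
)

#: 20 spectral variables: N2 and REM x ten bands.
SPECTRAL_VARIABLES: tuple[str, ...] = tuple(
    f"{stage}_{band}"
    for stage in ("n2", "rem")
    for band in ("total", "delta1", "delta2", "theta", "alpha",
                 "sigma1", "sigma2", "beta1", "beta2", "gamma")
)

#: The 39 dependents of the explorative plan.
EXPLORATIVE_PSG_VARIABLES: tuple[str, ...] = (
    CONTINUITY_VARIABLES + EVENT_VARIABLES + SPECTRAL_VARIABLES
)


@dataclass
class RegressionResult:
    """One dependent-independent regression: slope, t, df, p (+ adjusted p)."""

    dependent: str
    independent: str
    b: float
    t: float
    df: int
    p: float
    n: int
    p_fdr: Optional[float] = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class PlanItem:
    dependent: str
    independent: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    age_max: Optional[float] = None  # restrict to subjects with age < age_max


@dataclass
class AnalysisPlan:
    """A set of regressions plus the multiplicity rule applied to them."""

    mode: str  # 'hypothesis' (raw p at .05) or 'explorative' (BH-FDR per dependent)
    items: list[PlanItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("hypothesis", "explorative"):
            raise ValueError(f"mode must be 'hypothesis' or 'explorative', got {self.mode!r}")

    def __len__(self) -> int:
        return len(self.items)


def fit_univariate(
    y: np.ndarray,
    x: np.ndarray,
    covars: pd.DataFrame | np.ndarray | None,
    dependent: str = "y",
    independent: str = "x",
) -> RegressionResult:
    """OLS of y on [1, x, covariates]; reports the slope of x.

    ``b`` is the non-standardized coefficient of ``x``, ``t = b / SE(b)`` and
    ``p`` is two-tailed from the t distribution with ``df = n - k`` residual
    degrees of freedom (k regressors including the intercept; n - 5 with the
    standard ICV/age/sex covariate set).

    Raises
    ------
    ValueError
        On mismatched lengths, too few observations, or a rank-deficient
        design (e.g. the predictor collinear with a covariate).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covars is None:
        covars = np.empty((y.size, 0))
    cov = np.asarray(covars, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if not (y.shape[0] == x.shape[0] == cov.shape[0]):
        raise ValueError("y, x and covariates must have equal length")
    k = 2 + cov.shape[1]
    if y.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} observations for {k} regressors")

    design = np.column_stack([np.ones(y.shape[0]), x, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design for {dependent!r} ~ {independent!r}: "
            "the predictor is collinear with the intercept or a covariate"
        )
    res = sm.OLS(y, design).fit()
    df = int(res.df_resid)
    b = float(res.params[1])
    if res.ssr <= 0:  # exact fit: zero residual variance, t undefined
        t_stat, p = float("inf") * np.sign(b), 0.0
    else:
        t_stat = float(res.tvalues[1])
        p = float(res.pvalues[1])
    return RegressionResult(
        dependent=dependent, independent=independent,
        b=b, t=t_stat, df=df, p=p, n=int(y.shape[0]),
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    For sorted p(1) <= ... <= p(m): padj(i) = min_{j >= i} min(m p(j) / j, 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fdr_adjust needs at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypothesis_plan() -> AnalysisPlan:
    """The 14 a-priori tests.

    10 tests cross NREM (stage 2) delta1/delta2 power with left/right medial
    orbitofrontal volume, left/right posterior cingulate volume, and anterior
    corpus callosum volume; 2 cross total sleep time with left/right
    hippocampal volume; 2 repeat the corpus-callosum tests without the ICV
    covariate on subjects younger than 40 years.
    """
    slow_bands = ("n2_delta1", "n2_delta2")
    structures = (
        "lh_medialorbitofrontal_volume",
        "rh_medialorbitofrontal_volume",
        "lh_posteriorcingulate_volume",
        "rh_posteriorcingulate_volume",
        "CC_Anterior",
    )
    items = [PlanItem(dep, ind) for dep in slow_bands for ind in structures]
    items += [
        PlanItem("tst_min", "Left-Hippocampus"),
        PlanItem("tst_min", "Right-Hippocampus"),
    ]
    items += [
        PlanItem(dep, "CC_Anterior", covariates=("age", "sex"), age_max=40.0)
        for dep in slow_bands
    ]
    return AnalysisPlan(mode="hypothesis", items=items)


def explorative_plan(
    psg_variables: Sequence[str] = EXPLORATIVE_PSG_VARIABLES,
    morph_variables: Sequence[str] = MORPH_COLUMNS,
) -> AnalysisPlan:
    """All PSG variables crossed with all morphometric variables (39 x 174)."""
    items = [PlanItem(dep, ind) for dep in psg_variables for ind in morph_variables]
    return AnalysisPlan(mode="explorative", items=items)


def run_plan(plan: AnalysisPlan, psg_table: pd.DataFrame, morph_table: pd.DataFrame) -> pd.DataFrame:
    """Run every regression of a plan and apply its multiplicity rule.

    Both tables must be indexed by subject id; ``morph_table`` carries the
    174 morphometric columns plus the covariates (icv, age, sex).  Subjects
    with a missing dependent value (e.g. zero kept REM epochs) are dropped
    for that dependent only, with df reported from the actual n.

    Returns a DataFrame with columns dependent, independent, b, t, df, p, n
    and, in explorative mode, p_fdr adjusted within each dependent variable.
    """
    merged = morph_table.join(psg_table, how="inner", lsuffix="", rsuffix="_psg")
    if merged.empty:
        raise ValueError("psg_table and morph_table share no subject ids")
    missing: set[str] = set()
    for item in plan.items:
        for name in (item.dependent, item.independent, *item.covariates):
            if name not in merged.columns:
                missing.add(name)
    if missing:
        raise KeyError(f"plan variables missing from the tables: {sorted(missing)}")

    rows = []
    for item in plan.items:
        cols = [item.dependent, item.independent, *item.covariates]
        data = merged[cols + (["age"] if "age" not in cols else [])].dropna(
            subset=cols
        )
        if item.age_max is not None:
            data = data[data["age"] < item.age_max]
        if len(data) < 3 + len(item.covariates):
            warnings.warn(
                f"{item.dependent!r} ~ {item.independent!r}: only {len(data)} complete "
                "subjects; reporting NaN",
                stacklevel=2,
            )
            rows.append(
                RegressionResult(item.dependent, item.independent, float("nan"),
                                 float("nan"), 0, float("nan"), len(data)).as_dict()
            )
            continue
        try:
            res = fit_univariate(
                data[item.dependent].to_numpy(),
                data[item.independent].to_numpy(),
                data[list(item.covariates)],
                dependent=item.dependent,
                independent=item.independent,
            )
        except ValueError as exc:
            # e.g. a covariate constant in this (sub)sample -> rank-deficient
            warnings.warn(
                f"{item.dependent!r} ~ {item.independent!r}: {exc}; reporting NaN",
                stacklevel=2,
            )
            rows.append(
                RegressionResult(item.dependent, item.independent, float("nan"),
                                 float("nan"), 0, float("nan"), len(data)).as_dict()
            )
            continue
        rows.append(res.as_dict())
    results = pd.DataFrame(rows)

    if plan.mode == "hypothesis":
        results = results.drop(columns=["p_fdr"])
    if plan.mode == "explorative":
        results["p_fdr"] = np.nan
        for dep, group in results.groupby("dependent"):
            valid = group["p"].notna()
            if valid.any():
                results.loc[group.index[valid], "p_fdr"] = fdr_adjust(
                    group.loc[valid, "p"].to_numpy()
                )
    return results


def residual_adjust(values: np.ndarray, covars: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Residual-method covariate adjustment: OLS residuals plus the grand mean."""
    values = np.asarray(values, dtype=float)
    cov = np.asarray(covars, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != values.shape[0]:
        raise ValueError("values and covariates must have equal length")
    design = np.column_stack([np.ones(values.shape[0]), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    res = sm.OLS(values, design).fit()
    return res.resid + values.mean()


def fisher_mean_correlation(r_values: Sequence[float]) -> float:
    """Mean correlation through Fisher's Z: tanh(mean(atanh(r)))."""
    r = np.asarray(r_values, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    return float(np.tanh(np.arctanh(r).mean()))


def icv_age_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, p) between ICV and age."""
    r, p = scipy.stats.pearsonr(table["icv"], table["age"])
    return float(r), float(p)


def icv_sex_ttest(table: pd.DataFrame) -> tuple[float, int, float]:
    """Two-sample t-test (t, df, p) for ICV by sex (pooled variance)."""
    groups = [g["icv"].to_numpy() for _, g in table.groupby("sex")]
    if len(groups) != 2:
        raise ValueError("sex must take exactly two values")
    t, p = scipy.stats.ttest_ind(*groups)
    df = len(groups[0]) + len(groups[1]) - 2
    return float(t), int(df), float(p)


def age_morphometry_correlations(table: pd.DataFrame) -> dict[str, float]:
    """Fisher-mean correlation of age with all volumes and with all thicknesses."""
    vol_cols = [c for c in MORPH_COLUMNS if not c.endswith("_thickness")]
    thick_cols = [c for c in MORPH_COLUMNS if c.endswith("_thickness")]
    r_vol = [scipy.stats.pearsonr(table[c], table["age"])[0] for c in vol_cols]
    r_thick = [scipy.stats.pearsonr(table[c], table["age"])[0] for c in thick_cols]
    return {
        "volumes": fisher_mean_correlation(r_vol),
        "thicknesses": fisher_mean_correlation(r_thick),
    }
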