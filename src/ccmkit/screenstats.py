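"""Screen-level statistics for ligand and knockdown phenotype tables.

Tables are long-format DataFrames with columns
``knockdown, treatment, metric, replicate, value`` (as produced by
:mod:`ccmkit.simkit` or by collapsing phenometrics output).  The module
provides control normalisation, Dunnett many-to-one comparisons against a
shared control, per-knockdown Student's t-tests against the scrambled
control, PCA of phenotype profiles, and the exact binomial test for
enrichment of condition-specific effect magnitudes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

__all__ = [
    "ScreenDesign", "TestResult", "EnrichmentResult", "PCAResult",
    "normalize_to_control", "dunnett_vs_control", "ttest_vs_control",
    "screen_ttests", "knockdown_effects", "osm_effect_enrichment",
    "phenotype_pca", "results_to_frame",
]


@dataclass(frozen=True)
class ScreenDesign:
    """Which labels act as controls and at what significance level."""

    control_condition: str = "EGF"
    control_knockdown: str = "siSCR"
    alpha: float = 0.05


@dataclass(frozen=True)
class TestResult:
    contrast: tuple          # (group, control)
    metric: str | None
    estimate: float          # group mean - control mean
    p_value: float
    adjusted: bool
    method: str


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the paired effect-magnitude sign test."""

    ratios: pd.Series        # |effect_osm| / |effect_ifng| per knockdown
    n_successes: int         # ratios > 1
    n_used: int
    n_dropped: int
    p_value: float           # one-sided exact binomial, p0 = 0.5


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame            # metric x component, rows orthonormal cols
    scores: pd.DataFrame              # (knockdown, treatment) x component
    treatment_weights: pd.DataFrame   # treatment x component mean score
    variance_explained: np.ndarray
    imputed: list = field(default_factory=list)


def normalize_to_control(table: pd.DataFrame, design: ScreenDesign) -> pd.DataFrame:
    """Divide every score by its treatment x metric control-knockdown mean.

    Control rows normalise to mean 1 within each stratum.  Raises when a
    (treatment, metric) stratum has no control rows or a zero control mean.
    """
    out = table.copy().reset_index(drop=True)
    norm = np.empty(len(out))
    for (tr, me), idx in out.groupby(["treatment", "metric"]).groups.items():
        sub = out.loc[idx]
        ctrl = sub.loc[sub["knockdown"] == design.control_knockdown, "value"]
        if ctrl.empty:
            raise ValueError(f"no control ({design.control_knockdown}) rows for "
                             f"stratum (treatment={tr!r}, metric={me!r})")
        m = ctrl.mean()
        if m == 0:
            raise ValueError(f"zero control mean in stratum ({tr!r}, {me!r})")
        norm[out.index.get_indexer(idx)] = m
    out["value"] = out["value"].to_numpy() / norm
    return out


def _groups_from_mapping(values_by_group, design: ScreenDesign):
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for label, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {label!r} has a single replicate: "
                             "no within-group variance estimate")
    if design.control_condition in groups:
        control = design.control_condition
    elif design.control_knockdown in groups:
        control = design.control_knockdown
    else:
        raise ValueError("no control group present "
                         f"({design.control_condition!r}/{design.control_knockdown!r})")
    treat = {k: v for k, v in groups.items() if k != control}
    if not treat:
        raise ValueError("need at least one non-control group")
    return control, groups[control], treat


def dunnett_vs_control(values_by_group: dict, design: ScreenDesign = ScreenDesign(),
                       metric: str | None = None) -> list[TestResult]:
    """Two-sided Dunnett many-to-one comparisons against the control group.

    Family-wise error is controlled via the multivariate-t critical
    values of Dunnett's procedure (``scipy.stats.dunnett``).  With a
    single comparison the adjusted p-value reduces to the two-sample
    equal-variance t-test p-value.
    """
    control, ctrl_vals, treat = _groups_from_mapping(values_by_group, design)
    all_vals = np.concatenate([ctrl_vals, *treat.values()])
    resid = sum(((v - v.mean()) ** 2).sum() for v in [ctrl_vals, *treat.values()])
    if resid == 0:
        raise ValueError("zero within-group variance in every group: "
                         "Dunnett's test is undefined")
    del all_vals
    labels = sorted(treat)
    res = stats.dunnett(*(treat[l] for l in labels), control=ctrl_vals,
                        alternative="two-sided")
    return [
        TestResult(contrast=(l, control), metric=metric,
                   estimate=float(treat[l].mean() - ctrl_vals.mean()),
                   p_value=float(p), adjusted=True, method="dunnett")
        for l, p in zip(labels, res.pvalue)
    ]


def ttest_vs_control(values_by_group: dict, design: ScreenDesign = ScreenDesign(),
                     metric: str | None = None, equal_var: bool = True) -> list[TestResult]:
    """Two-sided two-sample t-tests of every group against the control.

    Equal-variance (Student) by default, Welch behind ``equal_var=False``.
    P-values are unadjusted and flagged as such.  Zero pooled variance
    with unequal means yields p = 0 with a warning.
    """
    control, ctrl_vals, treat = _groups_from_mapping(values_by_group, design)
    out = []
    for label in sorted(treat):
        v = treat[label]
        est = float(v.mean() - ctrl_vals.mean())
        if np.var(v, ddof=1) == 0 and np.var(ctrl_vals, ddof=1) == 0:
            if est == 0:
                p = 1.0
            else:
                warnings.warn(f"zero pooled variance with unequal means for "
                              f"{label!r}: p reported as 0")
                p = 0.0
        else:
            p = float(stats.ttest_ind(v, ctrl_vals, equal_var=equal_var).pvalue)
        out.append(TestResult(contrast=(label, control), metric=metric,
                              estimate=est, p_value=p, adjusted=False,
                              method="student-t" if equal_var else "welch-t"))
    return out


def screen_ttests(table: pd.DataFrame, design: ScreenDesign = ScreenDesign(),
                  equal_var: bool = True) -> list[TestResult]:
    """t-tests of every knockdown vs the control, per treatment x metric."""
    out = []
    for (tr, me), sub in table.groupby(["treatment", "metric"]):
        groups = {kd: g["value"].to_numpy() for kd, g in sub.groupby("knockdown")}
        results = ttest_vs_control(groups, design, metric=me, equal_var=equal_var)
        out.extend(
            TestResult(contrast=(r.contrast[0], r.contrast[1], tr), metric=r.metric,
                       estimate=r.estimate, p_value=r.p_value,
                       adjusted=False, method=r.method)
            for r in results
        )
    return out


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([
        {"group": r.contrast[0], "control": r.contrast[1],
         "treatment": r.contrast[2] if len(r.contrast) > 2 else None,
         "metric": r.metric, "estimate": r.estimate, "p_value": r.p_value,
         "adjusted": r.adjusted, "method": r.method}
        for r in results
    ])


def knockdown_effects(normalized: pd.DataFrame, design: ScreenDesign = ScreenDesign(),
                      aggregate: str = "euclidean") -> pd.DataFrame:
    """Per-knockdown, per-treatment effect magnitude.

    The effect vector is the deviation of the replicate-mean normalised
    score from 1 across metrics; its magnitude is the Euclidean norm
    (default) or the maximum absolute entry (``aggregate="max"``).
    """
    if aggregate not in ("euclidean", "max"):
        raise ValueError("aggregate must be 'euclidean' or 'max'")
    means = (normalized[normalized["knockdown"] != design.control_knockdown]
             .groupby(["knockdown", "treatment", "metric"])["value"].mean())
    dev = means - 1.0
    agg = (np.sqrt((dev ** 2).groupby(["knockdown", "treatment"]).sum())
           if aggregate == "euclidean"
           else dev.abs().groupby(["knockdown", "treatment"]).max())
    return agg.unstack("treatment")


def osm_effect_enrichment(effect_osm, effect_ifng, p0: float = 0.5) -> EnrichmentResult:
    """One-sided exact binomial test for OSM-dominant effect magnitudes.

    For each knockdown the ratio |effect under OSM| / |effect under IFNG|
    is a success when > 1; under the null, successes are Binomial(n, p0).
    Knockdowns with an IFNG effect of exactly 0 are dropped with a warning.
    """
    osm = pd.Series(effect_osm, dtype=float).abs()
    ifng = pd.Series(effect_ifng, dtype=float).abs()
    common = osm.index.intersection(ifng.index)
    if len(common) < 1:
        raise ValueError("need paired effects for at least one knockdown")
    osm, ifng = osm[common], ifng[common]
    zero = ifng == 0
    if zero.any():
        warnings.warn(f"dropped {int(zero.sum())} knockdown(s) with zero IFNG effect")
    ratios = (osm[~zero] / ifng[~zero]).rename("osm_ifng_ratio")
    successes = int((ratios > 1).sum())
    n = len(ratios)
    p = float(stats.binomtest(successes, n, p0, alternative="greater").pvalue)
    return EnrichmentResult(ratios=ratios, n_successes=successes, n_used=n,
                            n_dropped=int(zero.sum()), p_value=p)


def phenotype_pca(normalized: pd.DataFrame, n_components: int | None = None,
                  replicate_level: bool = False) -> PCAResult:
    """PCA of phenotype profiles across knockdown x treatment conditions.

    Rows are replicate means per (knockdown, treatment) (replicate-level
    rows behind ``replicate_level=True``); columns are metrics, centred
    and unit-scaled.  Missing entries are imputed with the metric mean
    (logged).  Each loading vector is oriented so its largest-magnitude
    entry is positive; per-treatment mean scores summarise how strongly
    each treatment projects on each component.
    """
    index_cols = ["knockdown", "treatment"] + (["replicate"] if replicate_level else [])
    wide = normalized.pivot_table(index=index_cols, columns="metric",
                                  values="value", aggfunc="mean")
    if len(wide) < 2:
        raise ValueError("PCA needs at least 2 rows")
    imputed = []
    for col in wide.columns:
        miss = wide[col].isna()
        if miss.any():
            imputed.extend((i, col) for i in wide.index[miss])
            wide.loc[miss, col] = wide[col].mean()
    if imputed:
        log.info("phenotype_pca: imputed %d missing entries with metric means",
                 len(imputed))

    X = wide.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    k = n_components or min(Z.shape)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)
    comps = pca.components_                    # (k, n_metrics), orthonormal rows
    for i in range(k):                         # deterministic sign convention
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]

    names = [f"PC{i+1}" for i in range(k)]
    loadings = pd.DataFrame(comps.T, index=wide.columns, columns=names)
    score_df = pd.DataFrame(scores, index=wide.index, columns=names)
    tw = score_df.groupby(level="treatment").mean()
    return PCAResult(loadings=loadings, scores=score_df, treatment_weights=tw,
                     variance_explained=pca.explained_variance_ratio_,
                     imputed=imputed)
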