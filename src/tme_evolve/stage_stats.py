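"""Stage-transition differential features, importance, and profile clustering.

For each adjacent stage transition (normal -> hyperplasia -> early adenoma ->
late adenoma -> invasive adenocarcinoma), ROI-level features are compared
between the two stages with the two-sided Wilcoxon rank-sum test.  Only
features present (nonzero by default) in at least a minimum fraction of ROIs
in *both* stages are tested; p-values are adjusted for multiple testing
(Benjamini-Hochberg by default) and converted to a normalized importance

    f_i = (-log p̄_i) / Σ_k (-log p̄_k)

which is nonnegative, sums to 1 over tested features, and is monotone
decreasing in the adjusted p-value.  Summing importances within each catalog
category gives the category's contribution to the transition.  Finally,
per-stage feature means can be z-scored and k-means-clustered into groups of
features sharing a stage-enrichment profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .features import CATEGORIES, FeatureCatalog

__all__ = [
    "TransitionResult",
    "transition_de",
    "feature_importance",
    "category_contribution",
    "cluster_feature_profiles",
]

_P_FLOOR = 1e-300


@dataclass
class TransitionResult:
    """Differential-feature results for one ordered stage transition."""

    transition: tuple[str, str]
    table: pd.DataFrame   # feature, tested, reason, p, p_adj, importance
    min_frac: float
    adjust: str

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["tested"]]


def transition_de(
    features: pd.DataFrame,
    stages: pd.Series,
    pair: tuple[str, str],
    min_frac: float = 0.25,
    adjust: str = "fdr_bh",
    presence: str = "nonzero",
) -> TransitionResult:
    """Wilcoxon rank-sum differential test of every feature between two stages.

    ``features`` is the ROI x feature matrix, ``stages`` maps roi_id ->
    stage.  A feature is tested iff it is present in at least ``min_frac``
    of the ROIs of each stage, where presence means nonzero-and-nonmissing
    (``presence="nonzero"``, default) or just nonmissing
    (``presence="nonmissing"``).  ``adjust`` is a statsmodels multipletests
    method ("fdr_bh" or "bonferroni").
    """
    a, b = pair
    stages = stages.reindex(features.index)
    ra = features[stages == a]
    rb = features[stages == b]
    if len(ra) == 0 or len(rb) == 0:
        raise ValueError(f"empty stage in transition {a}->{b}")
    if len(ra) < 2 or len(rb) < 2:
        raise ValueError(f"transition {a}->{b} needs >= 2 ROIs per stage")

    def present_frac(df: pd.DataFrame) -> pd.Series:
        ok = df.notna()
        if presence == "nonzero":
            ok &= df != 0
        elif presence != "nonmissing":
            raise ValueError("presence must be 'nonzero' or 'nonmissing'")
        return ok.mean(axis=0)

    frac_a, frac_b = present_frac(ra), present_frac(rb)
    testable = (frac_a >= min_frac) & (frac_b >= min_frac)

    rows = []
    pvals = []
    tested_feats = []
    for feat in features.columns:
        if not testable[feat]:
            rows.append({"feature": feat, "tested": False, "reason": "prevalence",
                         "p": np.nan, "p_adj": np.nan, "importance": np.nan})
            continue
        x = ra[feat].dropna().to_numpy()
        y = rb[feat].dropna().to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        tested_feats.append(feat)
        pvals.append(p)
        rows.append({"feature": feat, "tested": True, "reason": "",
                     "p": p, "p_adj": np.nan, "importance": np.nan})

    table = pd.DataFrame(rows).set_index("feature")
    if tested_feats:
        p_adj = multipletests(pvals, method=adjust)[1]
        table.loc[tested_feats, "p_adj"] = p_adj
        table.loc[tested_feats, "importance"] = feature_importance(
            pd.Series(p_adj, index=tested_feats)
        ).to_numpy()
    return TransitionResult(transition=(a, b), table=table.reset_index(),
                            min_frac=min_frac, adjust=adjust)


def feature_importance(adjusted_p: pd.Series | np.ndarray) -> pd.Series:
    """Normalized -log adjusted-p importance: f_i = -log p̄_i / Σ_k -log p̄_k.

    Base-invariant (the base cancels in the ratio); p-values are floored at
    1e-300 to keep the logs finite.  If every p̄ equals 1 the importances are
    undefined and a uniform vector is returned with a warning.
    """
    p = pd.Series(adjusted_p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("adjusted p-values must lie in (0, 1]")
    logs = -np.log(np.maximum(p.to_numpy(), _P_FLOOR))
    total = logs.sum()
    if total == 0:
        warnings.warn("all adjusted p-values are 1; importances set uniform")
        return pd.Series(np.full(len(p), 1.0 / len(p)), index=p.index, name="importance")
    return pd.Series(logs / total, index=p.index, name="importance")


def category_contribution(
    result: TransitionResult, catalog: FeatureCatalog
) -> pd.Series:
    """Per-category sum of feature importances for one transition (sums to 1)."""
    tested = result.tested
    if tested.empty:
        raise ValueError("no tested features; importances undefined")
    cats = tested["feature"].map(catalog.category_of)
    contrib = tested.groupby(cats.to_numpy())["importance"].sum()
    return contrib.reindex(CATEGORIES, fill_value=0.0).rename(
        "->".join(result.transition)
    )


def cluster_feature_profiles(
    stage_means: pd.DataFrame, k: int = 5, seed: int = 0
) -> pd.Series:
    """Group features by their per-stage mean profile.

    ``stage_means`` is feature x stage (stages in progression order).  Rows
    are z-scored across stages (constant rows map to zero) and clustered
    with k-means; group labels 1..k are ordered by the stage at which the
    group's mean profile peaks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(stage_means):
        raise ValueError("k exceeds the number of features")
    X = stage_means.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(Z)
    peaks = km.cluster_centers_.argmax(axis=1)
    order = np.lexsort((np.arange(k), peaks))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return pd.Series(relabel[raw], index=stage_means.index, name="group")
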