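"""Statistical layer: gradient-boosted feature importance, binned
nonparametric group comparisons and max-location histograms.

Importances are impurity-based (from sklearn's
``GradientBoostingRegressor``), summed over indicator columns of each
categorical feature and normalized so the top feature equals 1.  Group
comparisons follow the unconditional nonparametric pipeline:
Kruskal-Wallis omnibus, then pairwise Wilcoxon rank-sum tests with
Bonferroni correction when the omnibus is significant; a normality
diagnostic is reported but never gates the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from .geometry import level_index

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "ImportanceReport",
    "GroupTestReport",
    "feature_importance",
    "bin_numeric",
    "omnibus_and_pairwise",
    "location_histogram",
]

#: The 12 candidate predictors of instrumentation stresses and forces.
FEATURES = [
    "lenke",
    "cobb",
    "pattern",
    "instr_len",
    "apex",
    "apex_rot",
    "upper_cur",
    "lower_cur",
    "uiv",
    "liv",
    "d_ll",
    "d_tk",
]

_LEVEL_FEATURES = {"apex", "upper_cur", "lower_cur", "uiv", "liv"}
_CATEGORICAL = {"lenke", "pattern"}

METRICS = ("max_rod_stress", "max_screw_force")

GB_PARAMS = dict(n_estimators=500, max_depth=3, learning_rate=0.1, loss="squared_error")


@dataclass
class ImportanceReport:
    """Per-feature relative importance, top feature normalized to 1."""

    metric: str
    importances: pd.Series  # indexed by FEATURES, descending
    params: dict
    seed: int
    degenerate: bool = False
    kind: str = "impurity"


def _encode(records: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Design matrix: ordinal columns for levels, indicators for
    categoricals.  Returns X and (feature, column) ownership pairs."""
    cols: list[np.ndarray] = []
    owner: list[tuple[str, int]] = []
    for feat in FEATURES:
        v = records[feat]
        if feat in _LEVEL_FEATURES:
            cols.append(v.map(level_index).to_numpy(float))
            owner.append((feat, 1))
        elif feat in _CATEGORICAL:
            dummies = pd.get_dummies(v)
            cols.extend(dummies[c].to_numpy(float) for c in dummies.columns)
            owner.append((feat, dummies.shape[1]))
        else:
            cols.append(v.to_numpy(float))
            owner.append((feat, 1))
    return np.column_stack(cols), owner


def feature_importance(
    records: pd.DataFrame, metric: str, seed: int = 0, **gb_overrides
) -> ImportanceReport:
    """Gradient-boosted regression of one outcome metric on the 12
    candidate features; impurity importances normalized to the top one."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    data = records[records["feasible"]] if "feasible" in records else records
    if len(data) < 100:
        raise ValueError("need at least 100 records for feature importance")
    y = data[metric].to_numpy(float)
    params = dict(GB_PARAMS, **gb_overrides)
    if np.ptp(y) == 0.0:
        logger.warning("constant metric %s: degenerate importance report", metric)
        return ImportanceReport(
            metric=metric,
            importances=pd.Series(0.0, index=FEATURES),
            params=params,
            seed=seed,
            degenerate=True,
        )
    X, owner = _encode(data)
    model = GradientBoostingRegressor(random_state=seed, **params)
    model.fit(X, y)
    raw = model.feature_importances_
    agg = {}
    pos = 0
    for feat, width in owner:
        agg[feat] = float(raw[pos : pos + width].sum())
        pos += width
    imp = pd.Series(agg)
    top = imp.max()
    imp = imp / top if top > 0 else imp
    return ImportanceReport(
        metric=metric,
        importances=imp.sort_values(ascending=False),
        params=params,
        seed=seed,
    )


def bin_numeric(
    records: pd.DataFrame, feature: str, width: float = 5.0, min_size: int = 3
) -> dict[tuple[float, float], pd.DataFrame]:
    """Group records into half-open bins [k*w, (k+1)*w) of a numeric
    feature; bins with fewer than ``min_size`` records are dropped."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    v = pd.to_numeric(records[feature], errors="coerce")
    if v.isna().any() and not records[feature].isna().any():
        raise TypeError(f"feature {feature!r} is not numeric")
    out: dict[tuple[float, float], pd.DataFrame] = {}
    if records.empty:
        return out
    k = np.floor(v / width)
    for key, grp in records.groupby(k):
        lo = float(key) * width
        if len(grp) < min_size:
            logger.info("bin [%g, %g) dropped: only %d records", lo, lo + width, len(grp))
            continue
        out[(lo, lo + width)] = grp
    return dict(sorted(out.items()))


@dataclass
class GroupTestReport:
    """Omnibus + pairwise nonparametric comparison of groups."""

    factor: str
    omnibus_p: float
    pairwise_p: pd.DataFrame | None  # Bonferroni-adjusted; None if omnibus n.s.
    group_sizes: pd.Series
    normality_p: pd.Series  # diagnostic only
    bin_edges: list | None = None


def omnibus_and_pairwise(
    groups: dict, values: str | None = None, factor: str = "group", alpha: float = 0.05
) -> GroupTestReport:
    """Kruskal-Wallis across groups; pairwise Wilcoxon rank-sum tests with
    Bonferroni correction only when the omnibus test is significant.

    ``groups`` maps label -> 1D array, or label -> DataFrame with the
    ``values`` column naming the metric.
    """
    arrays: dict = {}
    for label, g in groups.items():
        a = np.asarray(g[values] if values is not None else g, float)
        arrays[label] = a[np.isfinite(a)]
    labels = list(arrays)
    if len(labels) < 2 or any(len(a) < 3 for a in arrays.values()):
        raise ValueError("need at least 2 groups of size >= 3")
    _, omnibus_p = stats.kruskal(*arrays.values())
    normality = pd.Series(
        {
            lab: (stats.normaltest(a).pvalue if len(a) >= 20 else np.nan)
            for lab, a in arrays.items()
        }
    )
    pairwise = None
    if omnibus_p < alpha:
        n_pairs = len(labels) * (len(labels) - 1) // 2
        mat = pd.DataFrame(np.nan, index=labels, columns=labels)
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                p = stats.ranksums(arrays[la], arrays[lb]).pvalue
                adj = min(1.0, p * n_pairs)
                mat.loc[la, lb] = adj
                mat.loc[lb, la] = adj
        pairwise = mat
    return GroupTestReport(
        factor=factor,
        omnibus_p=float(omnibus_p),
        pairwise_p=pairwise,
        group_sizes=pd.Series({lab: len(a) for lab, a in arrays.items()}),
        normality_p=normality,
    )


def location_histogram(records: pd.DataFrame, which: str = "stress") -> pd.Series:
    """Frequency of the signed vertebra offset (from the apex) of the
    maximal rod stress or screw-rod force; negative = cranial."""
    col = {"stress": "stress_offset", "force": "force_offset"}.get(which)
    if col is None:
        raise ValueError("which must be 'stress' or 'force'")
    data = records[records["feasible"]] if "feasible" in records else records
    if data.empty:
        raise ValueError("no records")
    counts = data[col].astype(int).value_counts().sort_index()
    counts.name = f"n_{which}"
    return counts


# ---------------------------------------------------------------------------
# Figures (optional rendering layer)
# ---------------------------------------------------------------------------


def plot_metric_by_group(records, group: str, metric: str = "max_rod_stress"):
    """Violin/box distribution of a metric across the levels of a factor."""
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(7, 4))
    sns.boxplot(data=records, x=group, y=metric, ax=ax)
    ax.set_xlabel(group)
    ax.set_ylabel(metric)
    fig.tight_layout()
    return fig


def plot_pvalue_heatmap(report: GroupTestReport):
    """Heatmap of the Bonferroni-adjusted pairwise p-values."""
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(6, 5))
    if report.pairwise_p is None:
        ax.text(0.5, 0.5, f"omnibus p = {report.omnibus_p:.3f} (n.s.)", ha="center")
        ax.set_axis_off()
    else:
        sns.heatmap(report.pairwise_p, annot=True, fmt=".2g", ax=ax, vmin=0, vmax=1)
        ax.set_title(f"{report.factor}: omnibus p = {report.omnibus_p:.2e}")
    fig.tight_layout()
    return fig


def plot_location_histogram(counts: pd.Series):
    """Frequency plot of max-stress / max-force location offsets."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(counts.index.to_numpy(), counts.to_numpy(), color="steelblue")
    ax.set_xlabel("vertebra offset from apex (negative = cranial)")
    ax.set_ylabel("count")
    fig.tight_layout()
    return fig
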