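"""Segmentation metrics, validation statistics, and clonal heritability.

Segmentation accuracy is scored with the Jaccard index and recall;
biological accuracy of vein masks with connected-component counts compared
across models via Tukey's HSD. Digital-versus-manual agreement uses an
ordinary least-squares fit and its coefficient of determination. Broad-sense
heritability H^2 = sigma_G^2 / (sigma_G^2 + sigma_E^2) is estimated from
clonal replicates by one-way random-effects ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import connected_components

__all__ = [
    "SegScore", "HeritabilityResult", "jaccard", "recall", "seg_score",
    "component_count_comparison", "linear_validation", "heritability",
    "mad_filter",
]


@dataclass
class SegScore:
    jaccard: float
    recall: float
    n_components_pred: int
    n_components_truth: int


@dataclass
class HeritabilityResult:
    H2: float
    sigma2_G: float
    sigma2_E: float
    n_genotypes: int
    mean_clones: float


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union; two empty masks are identical (1.0)."""
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    union = np.count_nonzero(pred | truth)
    if union == 0:
        return 1.0
    return np.count_nonzero(pred & truth) / union


def recall(pred: np.ndarray, truth: np.ndarray) -> float:
    """TP / (TP + FN): the probability of detecting a true foreground pixel."""
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    npos = np.count_nonzero(truth)
    if npos == 0:
        raise ValueError("recall undefined for an empty truth mask")
    return np.count_nonzero(pred & truth) / npos


def seg_score(pred: np.ndarray, truth: np.ndarray) -> SegScore:
    return SegScore(
        jaccard=jaccard(pred, truth),
        recall=recall(pred, truth),
        n_components_pred=connected_components(pred)[0],
        n_components_truth=connected_components(truth)[0])


def _cld_letters(names, means, nonsig: np.ndarray) -> dict:
    """Compact letter display over models ordered by mean.

    Models share a letter when they belong to a maximal run (in mean order)
    with no significant pairwise difference inside it.
    """
    order = np.argsort(means)
    runs = []
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and all(
                nonsig[order[a], order[j + 1]] for a in range(i, j + 1)):
            j += 1
        runs.append(list(order[i:j + 1]))
        i += 1 if j == i else j  # allow overlapping runs
        if j > i - 1 and i <= j:
            i = j if runs[-1][-1] != order[-1] else len(order)
    # Absorb runs fully contained in another.
    runs = [r for r in runs
            if not any(set(r) < set(o) for o in runs if o is not r)]
    letters = {n: "" for n in names}
    for k, run in enumerate(runs):
        ch = chr(ord("a") + k)
        for m in run:
            letters[names[m]] += ch
    return letters


def component_count_comparison(masks_by_model: dict) -> pd.DataFrame:
    """Mean component count per model, 95% CI, and Tukey HSD grouping.

    Accepts ``{model_name: [mask, ...]}`` (or lists of precomputed counts).
    Returns one row per model with columns ``mean``, ``ci_low``, ``ci_high``
    and ``group`` (compact letter display at alpha = 0.05).
    """
    from scipy import stats as sps
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(masks_by_model) < 2:
        raise ValueError("need at least 2 models to compare")
    counts = {}
    for name, masks in masks_by_model.items():
        vals = [m if np.isscalar(m) else connected_components(m)[0]
                for m in masks]
        if len(vals) < 2:
            raise ValueError("need at least 2 observations per model")
        counts[name] = np.asarray(vals, dtype=float)
    lengths = {len(v) for v in counts.values()}
    if len(lengths) != 1:
        raise ValueError("models must have equal-length mask lists")

    names = list(counts)
    values = np.concatenate([counts[n] for n in names])
    groups = np.concatenate([[n] * len(counts[n]) for n in names])
    if np.allclose(values.std(), 0.0):
        # Degenerate: identical counts everywhere; single group.
        nonsig = np.ones((len(names), len(names)), dtype=bool)
    else:
        tk = pairwise_tukeyhsd(values, groups, alpha=0.05)
        nonsig = np.ones((len(names), len(names)), dtype=bool)
        res = tk.summary().data[1:]
        pos = {n: i for i, n in enumerate(names)}
        for row in res:
            a, b, reject = row[0], row[1], row[-1]
            if reject:
                nonsig[pos[str(a)], pos[str(b)]] = False
                nonsig[pos[str(b)], pos[str(a)]] = False
    means = np.array([counts[n].mean() for n in names])
    letters = _cld_letters(names, means, nonsig)
    rows = []
    for n in names:
        v = counts[n]
        sem = v.std(ddof=1) / np.sqrt(len(v))
        tcrit = sps.t.ppf(0.975, len(v) - 1) if len(v) > 1 else np.nan
        rows.append({"model": n, "mean": v.mean(),
                     "ci_low": v.mean() - tcrit * sem,
                     "ci_high": v.mean() + tcrit * sem,
                     "group": letters[n]})
    return pd.DataFrame(rows).set_index("model")


def linear_validation(pred, manual):
    """OLS of manual measurements on digital predictions: (R2, slope,
    intercept)."""
    import statsmodels.api as sm

    pred = np.asarray(pred, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if pred.shape != manual.shape or pred.ndim != 1:
        raise ValueError("pred and manual must be equal-length vectors")
    if len(pred) < 3:
        raise ValueError("need at least 3 observations")
    if np.isclose(pred.std(), 0.0):
        raise ValueError("zero variance in predictions")
    model = sm.OLS(manual, sm.add_constant(pred)).fit()
    intercept, slope = model.params
    r2 = model.rsquared
    if not np.isfinite(r2):  # constant response: no variance to explain
        r2 = 0.0
    return float(r2), float(slope), float(intercept)


def mad_filter(values: np.ndarray, threshold: float = 6.0) -> np.ndarray:
    """Boolean keep-mask: drop points whose scaled MAD score exceeds the
    threshold (MAD scaled by 1.4826 for consistency with the normal SD)."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.ones(len(values), dtype=bool)
    score = np.abs(values - med) / (1.4826 * mad)
    return score <= threshold


def heritability(values, genotype_ids, mad_threshold: float | None = None
                 ) -> HeritabilityResult:
    """Broad-sense heritability from clonal replicates.

    One-way random-effects ANOVA with genotype as the grouping factor:
    ``sigma2_E = MS_within`` and ``sigma2_G = max(0, (MS_between -
    MS_within) / k_eff)`` where ``k_eff = (sum k - sum k^2 / sum k) /
    (g - 1)`` is the effective clone number for unbalanced designs. The
    optional MAD pre-filter removes gross outliers before fitting.
    """
    values = np.asarray(values, dtype=float)
    genotype_ids = np.asarray(genotype_ids)
    if len(values) != len(genotype_ids):
        raise ValueError("values and genotype_ids lengths differ")
    if mad_threshold is not None:
        keep = mad_filter(values, mad_threshold)
        values, genotype_ids = values[keep], genotype_ids[keep]
    uniq, inv = np.unique(genotype_ids, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 genotypes")
    k = np.bincount(inv).astype(float)
    if np.max(k) < 2:
        raise ValueError("all genotypes are singletons; variance "
                         "components are not estimable")
    n = len(values)
    grand = values.mean()
    group_means = np.bincount(inv, weights=values) / k
    ss_between = float((k * (group_means - grand) ** 2).sum())
    ss_within = float(((values - group_means[inv]) ** 2).sum())
    ms_between = ss_between / (g - 1)
    ms_within = ss_within / (n - g) if n > g else 0.0
    k_eff = (k.sum() - (k ** 2).sum() / k.sum()) / (g - 1)
    sigma2_e = ms_within
    sigma2_g = max(0.0, (ms_between - ms_within) / k_eff)
    denom = sigma2_g + sigma2_e
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return HeritabilityResult(H2=float(h2), sigma2_G=float(sigma2_g),
                              sigma2_E=float(sigma2_e), n_genotypes=g,
                              mean_clones=float(k.mean()))
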