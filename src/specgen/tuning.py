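"""Neuron selection and specificity / generalization / balance / RSA metrics.

Implements the population tuning measures used to compare IT-cortex
subregions: category- and feature-responsive neuron selection, the
specificity score (mean preferred-category response over the maximum
non-preferred category mean), exemplar- and view-level generalization
(min/max ratio of mean responses, and an SD variant), representational
similarity analysis, selection-threshold sensitivity, and the min-max
normalized balance score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import RecordingTable

__all__ = [
    "TuningScores",
    "RsaScores",
    "BalanceResult",
    "select_category_responsive",
    "select_feature_responsive",
    "specificity_score",
    "generalization_score",
    "generalization_sd",
    "rsm",
    "rsa_scores",
    "threshold_sensitivity",
    "balance_score",
]


@dataclass
class TuningScores:
    specificity: float
    gen_exemplar: float
    gen_view: float
    gen_sd: float
    n_repeats: int
    seed: int


@dataclass
class RsaScores:
    between_category_similarity: float
    within_exemplar_similarity: float
    within_view_similarity: float


@dataclass
class BalanceResult:
    labels: np.ndarray
    normalized_specificity: np.ndarray
    normalized_generalization: np.ndarray
    balance: np.ndarray


def _category_means(rec: RecordingTable) -> pd.DataFrame:
    """Per-neuron mean response to each category (neurons x categories)."""
    meta = rec.metadata
    out = {}
    for cat in rec.design.categories:
        cols = np.flatnonzero((meta["category"] == cat).to_numpy())
        out[cat] = rec.responses[:, cols].mean(axis=1)
    return pd.DataFrame(out)


def select_category_responsive(
    rec: RecordingTable, threshold: float = 2.0, min_neurons: int = 5
) -> dict[str, np.ndarray]:
    """Select neurons whose mean response to one category is at least
    ``threshold`` times the maximum mean response to every other category.

    Categories whose selected-neuron count is not strictly greater than
    ``min_neurons`` are dropped from the result.
    """
    if len(rec.design.categories) < 2:
        raise ValueError("at least two categories are required")
    means = _category_means(rec).to_numpy()  # (neurons, categories)
    out: dict[str, np.ndarray] = {}
    for ci, cat in enumerate(rec.design.categories):
        others = np.delete(means, ci, axis=1)
        selected = means[:, ci] >= threshold * others.max(axis=1)
        ids = np.flatnonzero(selected)
        if ids.size > min_neurons:
            out[cat] = ids
    return out


def select_feature_responsive(
    rec: RecordingTable, feature: str = "spiky", threshold: float = 2.0
) -> np.ndarray:
    """Select neurons whose mean response to flag=1 conditions is at least
    ``threshold`` times the mean response to flag=0 conditions."""
    flags = rec.metadata[feature].to_numpy().astype(bool)
    if flags.all() or (~flags).all():
        raise ValueError(f"both values of {feature!r} must be present")
    pos = rec.responses[:, flags].mean(axis=1)
    neg = rec.responses[:, ~flags].mean(axis=1)
    return np.flatnonzero(pos >= threshold * neg)


def _exemplars_by_category(rec: RecordingTable) -> dict[str, np.ndarray]:
    meta = rec.metadata
    return {
        cat: meta.loc[meta["category"] == cat, "exemplar"].unique()
        for cat in rec.design.categories
    }


def _exemplar_cols(rec: RecordingTable) -> dict[int, np.ndarray]:
    ex = rec.metadata["exemplar"].to_numpy()
    return {e: np.flatnonzero(ex == e) for e in np.unique(ex)}


def specificity_score(
    rec: RecordingTable,
    neurons: np.ndarray,
    preferred_category: str,
    n_repeats: int = 20,
    n_exemplars_per_draw: int | None = None,
    seed: int = 0,
) -> float:
    """Mean preferred-category response over the maximum non-preferred
    category mean, averaged over ``n_repeats`` exemplar subsamples.

    Each repeat draws ``n_exemplars_per_draw`` exemplars (default: the
    smallest category size) without replacement from every category.
    Repeats with a zero denominator are excluded with a warning.
    """
    neurons = np.asarray(neurons)
    if neurons.size == 0:
        raise ValueError("neuron set must be nonempty")
    if preferred_category not in rec.design.categories:
        raise ValueError(f"unknown category {preferred_category!r}")
    rng = np.random.default_rng(seed)
    ex_by_cat = _exemplars_by_category(rec)
    cols_by_ex = _exemplar_cols(rec)
    if n_exemplars_per_draw is None:
        n_exemplars_per_draw = min(len(v) for v in ex_by_cat.values())

    resp = rec.responses[neurons]
    ratios = []
    for _ in range(n_repeats):
        means = {}
        for cat, exemplars in ex_by_cat.items():
            k = min(n_exemplars_per_draw, len(exemplars))
            chosen = rng.choice(exemplars, size=k, replace=False)
            cols = np.concatenate([cols_by_ex[e] for e in chosen])
            means[cat] = resp[:, cols].mean()
        denom = max(v for c, v in means.items() if c != preferred_category)
        if denom <= 0:
            warnings.warn("zero denominator in a specificity repeat; excluded")
            continue
        ratios.append(means[preferred_category] / denom)
    if not ratios:
        raise ValueError("all repeats had a zero denominator")
    return float(np.mean(ratios))


def _gen_ratios_one_repeat(
    resp: np.ndarray,
    exemplars: np.ndarray,
    cols_by_ex: dict[int, np.ndarray],
    level: str,
    view_of_col: np.ndarray,
) -> float | None:
    """Min/max ratio of mean responses at one subsample (None if max = 0)."""
    if level == "exemplar":
        means = np.array([resp[:, cols_by_ex[e]].mean() for e in exemplars])
        if means.max() <= 0:
            return None
        return float(means.min() / means.max())
    # view level: per exemplar, min/max across its views, averaged
    vals = []
    for e in exemplars:
        cols = cols_by_ex[e]
        views = view_of_col[cols]
        vmeans = np.array([resp[:, cols[views == v]].mean() for v in np.unique(views)])
        if vmeans.max() > 0:
            vals.append(vmeans.min() / vmeans.max())
    return float(np.mean(vals)) if vals else None


def generalization_score(
    rec: RecordingTable,
    neurons: np.ndarray,
    preferred_category: str,
    level: str = "exemplar",
    n_repeats: int = 20,
    n_exemplars_per_draw: int | None = None,
    seed: int = 0,
) -> float:
    """Min-to-max ratio of mean responses across exemplars (or views) of the
    preferred category, averaged over exemplar subsamples; 1 = perfectly
    invariant responses. Returns NaN when every repeat is degenerate."""
    if level not in ("exemplar", "view"):
        raise ValueError("level must be 'exemplar' or 'view'")
    neurons = np.asarray(neurons)
    if neurons.size == 0:
        raise ValueError("neuron set must be nonempty")
    rng = np.random.default_rng(seed)
    exemplars = _exemplars_by_category(rec)[preferred_category]
    if len(exemplars) < 2:
        raise ValueError("need at least two exemplars in the preferred category")
    cols_by_ex = _exemplar_cols(rec)
    view_of_col = rec.metadata["view"].to_numpy()
    if n_exemplars_per_draw is None:
        n_exemplars_per_draw = len(exemplars)
    n_draw = max(2, min(n_exemplars_per_draw, len(exemplars)))
    resp = rec.responses[neurons]

    vals = []
    for _ in range(n_repeats):
        chosen = rng.choice(exemplars, size=n_draw, replace=False)
        r = _gen_ratios_one_repeat(resp, chosen, cols_by_ex, level, view_of_col)
        if r is None:
            warnings.warn("zero maximum in a generalization repeat; excluded")
        else:
            vals.append(r)
    return float(np.mean(vals)) if vals else float("nan")


def generalization_sd(
    rec: RecordingTable,
    neurons: np.ndarray,
    preferred_category: str,
    level: str = "exemplar",
) -> float:
    """Population SD (divisor n) of mean responses across exemplars of the
    preferred category (or, per exemplar, across its views, averaged).
    Lower SD = more generalization."""
    neurons = np.asarray(neurons)
    if neurons.size == 0:
        raise ValueError("neuron set must be nonempty")
    exemplars = _exemplars_by_category(rec)[preferred_category]
    cols_by_ex = _exemplar_cols(rec)
    view_of_col = rec.metadata["view"].to_numpy()
    resp = rec.responses[neurons]
    if level == "exemplar":
        means = np.array([resp[:, cols_by_ex[e]].mean() for e in exemplars])
        return float(np.std(means))
    sds = []
    for e in exemplars:
        cols = cols_by_ex[e]
        views = view_of_col[cols]
        vmeans = np.array([resp[:, cols[views == v]].mean() for v in np.unique(views)])
        sds.append(np.std(vmeans))
    return float(np.mean(sds))


def rsm(responses: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between condition response vectors.

    ``responses`` is neurons x conditions; the result is a symmetric
    conditions x conditions matrix with unit diagonal. Rows/columns of
    constant (zero-variance) conditions are reported as NaN.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 2 or responses.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two conditions")
    sd = responses.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(responses, rowvar=False)
    constant = sd == 0
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    valid = ~constant
    r[valid, valid] = 1.0
    return r


def _upper_mean(mat: np.ndarray) -> float:
    iu = np.triu_indices_from(mat, k=1)
    vals = mat[iu]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def rsa_scores(
    rec: RecordingTable,
    neurons: np.ndarray,
    preferred_category: str,
    n_repeats: int = 20,
    n_exemplars_per_draw: int | None = None,
    seed: int = 0,
) -> RsaScores:
    """Population-level specificity and generalization via representational
    similarity.

    * between-category similarity: mean Pearson r between the
      preferred-category average vector and each other category's stimuli
      (lower = more specific);
    * within-exemplar similarity: mean upper triangle of the RSM over
      preferred-category exemplar-average vectors;
    * within-view similarity: per exemplar, mean upper triangle of the RSM
      over its view conditions, averaged over exemplars.

    All three are averaged over ``n_repeats`` exemplar subsamples.
    """
    neurons = np.asarray(neurons)
    if neurons.size == 0:
        raise ValueError("neuron set must be nonempty")
    rng = np.random.default_rng(seed)
    meta = rec.metadata
    resp = rec.responses[neurons]
    ex_by_cat = _exemplars_by_category(rec)
    cols_by_ex = _exemplar_cols(rec)
    if n_exemplars_per_draw is None:
        n_exemplars_per_draw = min(len(v) for v in ex_by_cat.values())

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    between, within_ex, within_view = [], [], []
    pref_ex_all = ex_by_cat[preferred_category]
    n_pref = max(2, min(n_exemplars_per_draw, len(pref_ex_all)))
    for _ in range(n_repeats):
        # between-category: preferred average vs each other category's stimuli
        pref_ex = rng.choice(pref_ex_all, size=n_pref, replace=False)
        pref_cols = np.concatenate([cols_by_ex[e] for e in pref_ex])
        pref_avg = resp[:, pref_cols].mean(axis=1)
        cat_vals = []
        for cat, exemplars in ex_by_cat.items():
            if cat == preferred_category:
                continue
            k = min(n_exemplars_per_draw, len(exemplars))
            chosen = rng.choice(exemplars, size=k, replace=False)
            cols = np.concatenate([cols_by_ex[e] for e in chosen])
            rs = [_corr(pref_avg, resp[:, c]) for c in cols]
            rs = [v for v in rs if not np.isnan(v)]
            if rs:
                cat_vals.append(np.mean(rs))
        if cat_vals:
            between.append(np.mean(cat_vals))

        # within-exemplar: RSM of exemplar-average vectors
        ex_avg = np.stack(
            [resp[:, cols_by_ex[e]].mean(axis=1) for e in pref_ex], axis=1
        )
        within_ex.append(_upper_mean(rsm(ex_avg)))

        # within-view: RSM across each exemplar's views
        vals = []
        view_of_col = meta["view"].to_numpy()
        for e in pref_ex:
            cols = cols_by_ex[e]
            if cols.size >= 2:
                vals.append(_upper_mean(rsm(resp[:, cols])))
        if vals:
            within_view.append(np.nanmean(vals))

    return RsaScores(
        between_category_similarity=float(np.nanmean(between)),
        within_exemplar_similarity=float(np.nanmean(within_ex)),
        within_view_similarity=float(np.nanmean(within_view)),
    )


def threshold_sensitivity(
    rec: RecordingTable,
    thresholds: np.ndarray,
    preferred_category: str | None = None,
    min_neurons: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run selection and all scores at each selection threshold.

    Rows where the selection is empty are reported with NaN scores.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 1):
        raise ValueError("thresholds must be > 1")
    rows = []
    for thr in thresholds:
        sel = select_category_responsive(rec, threshold=thr, min_neurons=min_neurons)
        if preferred_category is None:
            cat = max(sel, key=lambda c: len(sel[c])) if sel else None
        else:
            cat = preferred_category if preferred_category in sel else None
        if cat is None:
            rows.append((thr, None, 0, np.nan, np.nan, np.nan))
            continue
        ids = sel[cat]
        rows.append(
            (
                thr,
                cat,
                len(ids),
                specificity_score(rec, ids, cat, n_repeats=n_repeats, seed=seed),
                generalization_score(
                    rec, ids, cat, level="exemplar", n_repeats=n_repeats, seed=seed
                ),
                generalization_score(
                    rec, ids, cat, level="view", n_repeats=n_repeats, seed=seed
                ),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["threshold", "category", "n_neurons", "specificity", "gen_exemplar", "gen_view"],
    )


def balance_score(
    specificity: np.ndarray,
    generalization: np.ndarray,
    labels: np.ndarray | None = None,
) -> BalanceResult:
    """Min-max normalize specificity and generalization across conditions and
    sum them; higher = better balance between the two demands."""
    spec = np.asarray(specificity, dtype=float)
    gen = np.asarray(generalization, dtype=float)
    if spec.shape != gen.shape or spec.ndim != 1 or spec.size < 2:
        raise ValueError("need two 1-D arrays of equal length >= 2")

    def _norm(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("constant array: min-max normalization undefined")
        return (x - lo) / (hi - lo)

    ns, ng = _norm(spec), _norm(gen)
    if labels is None:
        labels = np.arange(spec.size)
    return BalanceResult(np.asarray(labels), ns, ng, ns + ng)
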