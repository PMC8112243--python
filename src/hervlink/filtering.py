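"""Median-of-ratios normalisation and Jaccard-similarity low-signal filtering.

The filter scans candidate count thresholds and keeps the one that
maximises replicate-to-replicate agreement of feature presence/absence
(the mean pairwise Jaccard index within each condition). Features whose
maximum normalised count never exceeds the chosen threshold are dropped.
Defaults mirror the usual screen over 100 log-spaced thresholds between
1 and 200 with median-of-ratios ("DESeq") normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hervlink.counts import CountMatrix


@dataclass
class FilterConfig:
    s_min: float = 1.0
    s_max: float = 200.0
    s_len: int = 100
    normalization: str = "median_of_ratios"  # or "none"
    grid: str = "log"  # or "linear"

    def __post_init__(self) -> None:
        if not (0 < self.s_min < self.s_max):
            raise ValueError("need 0 < s_min < s_max")
        if self.s_len < 2:
            raise ValueError("s_len must be >= 2")
        if self.normalization not in ("median_of_ratios", "none"):
            raise ValueError("normalization must be 'median_of_ratios' or 'none'")

    def thresholds(self) -> np.ndarray:
        if self.grid == "log":
            return np.geomspace(self.s_min, self.s_max, self.s_len)
        return np.linspace(self.s_min, self.s_max, self.s_len)


@dataclass
class FilterResult:
    s_star: float
    similarity_curve: pd.DataFrame  # columns: threshold, similarity
    retained_ids: list[str]


def size_factors(cm: CountMatrix, allow_fallback: bool = True) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over reference features i of counts[i, j] / geomean_i,
    where the reference features are those positive in every sample. When no
    feature is positive everywhere (sparse HERV matrices), the geometric
    mean falls back to positive entries only, unless ``allow_fallback`` is
    off, in which case that situation is a hard error.
    """
    x = cm.values()
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        ref = x[all_pos]
        geo = np.exp(np.log(ref).mean(axis=1))
        ratios = ref / geo[:, None]
    elif allow_fallback:
        pos = x > 0
        usable = pos.sum(axis=1) >= 2
        if not usable.any():
            raise ValueError("no feature with >= 2 positive samples")
        ref = x[usable]
        with np.errstate(divide="ignore"):
            logx = np.where(ref > 0, np.log(ref), np.nan)
        geo = np.exp(np.nanmean(logx, axis=1))
        ratios = np.where(ref > 0, ref / geo[:, None], np.nan)
    else:
        raise ValueError("no feature positive in all samples and fallback disabled")
    with np.errstate(invalid="ignore"):
        factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("degenerate size factors")
    s = pd.Series(factors, index=cm.sample_ids, name="size_factor")
    gm = float(np.exp(np.log(s).mean()))
    if not 0.5 <= gm <= 2.0:
        import warnings

        warnings.warn(f"size-factor geometric mean {gm:.3g} outside [0.5, 2]")
    return s


def normalized_counts(cm: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(cm)
    return cm.counts / sf.reindex(cm.sample_ids).to_numpy()


def _mean_pairwise_jaccard(binary: np.ndarray) -> float:
    """Mean Jaccard over all column pairs of a features x replicates 0/1 array.

    The Jaccard of two all-zero vectors is defined as 1. Computed via the
    Gram matrix: |a & b| = a'b and |a | b| = |a| + |b| - a'b.
    """
    b = binary.astype(np.int64)
    n = b.shape[1]
    inter = b.T @ b
    sizes = np.diag(inter)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    iu = np.triu_indices(n, k=1)
    return float(jac[iu].mean())


def jaccard_threshold(cm: CountMatrix, cfg: FilterConfig | None = None) -> FilterResult:
    """Pick the presence threshold maximising within-condition replicate
    agreement and return the retained feature ids.

    For each candidate s, normalised counts are binarised as (value > s);
    similarity(s) is the mean over conditions of the mean pairwise Jaccard
    across that condition's replicates; s_star is the argmax (ties to the
    smallest s). Retained features have max normalised count > s_star.
    """
    cfg = cfg or FilterConfig()
    norm = (
        normalized_counts(cm)
        if cfg.normalization == "median_of_ratios"
        else cm.counts.astype(float)
    )
    x = norm.to_numpy()
    cond = cm.sample_meta["condition"].to_numpy()
    groups = []
    for c in np.unique(cond):
        cols = np.flatnonzero(cond == c)
        if len(cols) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")
        groups.append(cols)

    thresholds = cfg.thresholds()
    sims = np.empty(len(thresholds))
    for k, s in enumerate(thresholds):
        per_cond = [_mean_pairwise_jaccard(x[:, cols] > s) for cols in groups]
        sims[k] = float(np.mean(per_cond))
    best = int(np.argmax(sims))  # argmax takes the first, i.e. smallest s, on ties
    s_star = float(thresholds[best])
    retained = norm.index[(x > s_star).any(axis=1)].tolist()
    curve = pd.DataFrame({"threshold": thresholds, "similarity": sims})
    return FilterResult(s_star=s_star, similarity_curve=curve, retained_ids=retained)


def presence_filter(cm: CountMatrix, cfg: FilterConfig | None = None) -> FilterResult:
    """Plain presence filter: keep features whose maximum normalised count
    exceeds ``s_min``, without the Jaccard threshold scan.

    On sparse low-count matrices (HERV loci, where most features sit near
    the detection floor) the Jaccard scan is degenerate: high thresholds
    empty the presence vectors, which agree trivially, so the argmax drifts
    to the top of the grid and discards nearly everything. The presence
    filter is the default for the HERV feature class in the pipeline.
    """
    cfg = cfg or FilterConfig()
    norm = (
        normalized_counts(cm)
        if cfg.normalization == "median_of_ratios"
        else cm.counts.astype(float)
    )
    retained = norm.index[(norm.to_numpy() > cfg.s_min).any(axis=1)].tolist()
    curve = pd.DataFrame({"threshold": [cfg.s_min], "similarity": [np.nan]})
    return FilterResult(s_star=float(cfg.s_min), similarity_curve=curve, retained_ids=retained)


def apply_filter(cm: CountMatrix, result: FilterResult) -> CountMatrix:
    return cm.subset_features(result.retained_ids)
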