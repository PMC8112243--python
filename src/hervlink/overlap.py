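"""Cross-dataset integration statistics.

Three questions about two case/control datasets analysed separately:
does the intersection of their DE sets exceed what redrawing DE-sized
sets from each dataset's expressed universe produces (permutation test);
do the two datasets have different DE rates (Fisher's exact test); and
how correlated are their per-feature fold changes (Pearson, optionally
restricted to the DE union).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapConfig:
    n_perm: int = 200_000
    seed: int = 20210427

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class OverlapTestResult:
    observed_overlap: int
    null_max: int
    null_mean: float
    n_exceed: int
    n_perm: int
    p_empirical: float
    p_is_upper_bound: bool
    null_histogram: dict[int, int]


def overlap_permutation_test(
    universe1,
    universe2,
    de1,
    de2,
    cfg: OverlapConfig | None = None,
) -> OverlapTestResult:
    """Permutation null for the size of the DE-set intersection.

    Each of ``n_perm`` iterations draws |de1| ids uniformly without
    replacement from universe1 and |de2| from universe2 and records the
    intersection size. The empirical p-value uses the add-one rule
    (n_exceed + 1) / (n_perm + 1), so it can never be exactly zero; at zero
    exceedances of 200,000 permutations it equals 1/200,001 < 5e-6 and is
    flagged as an upper bound.
    """
    cfg = cfg or OverlapConfig()
    u1, u2 = list(universe1), list(universe2)
    de1, de2 = set(de1), set(de2)
    if not de1 <= set(u1) or not de2 <= set(u2):
        raise ValueError("DE sets must be subsets of their universes")
    if len(de1) > len(u1) or len(de2) > len(u2):
        raise ValueError("DE set larger than its universe")
    observed = len(de1 & de2)

    # map both universes into one integer id space
    all_ids = {x: i for i, x in enumerate(dict.fromkeys(u1 + u2))}
    idx1 = np.array([all_ids[x] for x in u1], dtype=np.int64)
    idx2 = np.array([all_ids[x] for x in u2], dtype=np.int64)
    k1, k2 = len(de1), len(de2)

    rng = np.random.default_rng(cfg.seed)
    mask = np.zeros(len(all_ids), dtype=bool)
    null_counts: dict[int, int] = {}
    n_exceed = 0
    total = 0
    for _ in range(cfg.n_perm):
        a = idx1[rng.choice(len(idx1), k1, replace=False)]
        b = idx2[rng.choice(len(idx2), k2, replace=False)]
        mask[a] = True
        ov = int(mask[b].sum())
        mask[a] = False
        null_counts[ov] = null_counts.get(ov, 0) + 1
        total += ov
        if ov >= observed:
            n_exceed += 1

    return OverlapTestResult(
        observed_overlap=observed,
        null_max=max(null_counts),
        null_mean=total / cfg.n_perm,
        n_exceed=n_exceed,
        n_perm=cfg.n_perm,
        p_empirical=(n_exceed + 1) / (cfg.n_perm + 1),
        p_is_upper_bound=n_exceed == 0,
        null_histogram=dict(sorted(null_counts.items())),
    )


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def fisher_de_association(
    n_de1: int, n_expr1: int, n_de2: int, n_expr2: int
) -> FisherResult:
    """Two-sided Fisher's exact test of the dataset-by-DE 2x2 table
    [[n_de1, n_expr1 - n_de1], [n_de2, n_expr2 - n_de2]]."""
    cells = (
        (n_de1, n_expr1 - n_de1),
        (n_de2, n_expr2 - n_de2),
    )
    if any(c < 0 for row in cells for c in row):
        raise ValueError("negative cell in 2x2 table (is n_de <= n_expr?)")
    odds, p = stats.fisher_exact(cells, alternative="two-sided")
    return FisherResult(table=cells, odds_ratio=float(odds), p_value=float(p))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    restrict_to: str


def cross_dataset_correlation(
    lfc1: pd.Series,
    lfc2: pd.Series,
    restrict_to: str = "all",
    de1=None,
    de2=None,
) -> CorrelationResult:
    """Pearson correlation of per-feature log2 fold changes across the two
    datasets, over shared features; ``de_union`` restricts to features DE
    in either dataset."""
    shared = lfc1.index.intersection(lfc2.index)
    if restrict_to == "de_union":
        if de1 is None or de2 is None:
            raise ValueError("de_union restriction requires de1 and de2 id sets")
        shared = shared.intersection(pd.Index(sorted(set(de1) | set(de2))))
    elif restrict_to != "all":
        raise ValueError("restrict_to must be 'all' or 'de_union'")
    if len(shared) < 3:
        raise ValueError("need >= 3 shared features after restriction")
    x, y = lfc1.loc[shared].to_numpy(), lfc2.loc[shared].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance fold changes: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(shared), restrict_to=restrict_to)
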