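"""Gene-set enrichment on importance scores and Fisher overrepresentation.

``score_enrichment`` is rank-based: for each set it compares the condition
model betas of member features against all other scored features with a
two-sided Mann-Whitney U (or, optionally, a two-sample Kolmogorov-Smirnov
statistic), BH-corrected across tested sets with the q < 0.1 reporting
convention. Signed betas keep direction meaningful: a set is called "up"
when its median member score exceeds the background median.

``overrepresentation_test`` is the classical one-sided Fisher exact test of
DE membership per set against the expressed-feature universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hervlink.de import bh_adjust
from hervlink.genesets import GeneSetCollection


@dataclass
class EnrichmentConfig:
    method: str = "rank_sum"  # or "ks"
    q_threshold: float = 0.1
    min_set_size: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.method not in ("rank_sum", "ks"):
            raise ValueError("method must be 'rank_sum' or 'ks'")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")


def score_enrichment(
    scores: pd.Series,
    sets: GeneSetCollection,
    cfg: EnrichmentConfig | None = None,
    de_ids=None,
) -> pd.DataFrame:
    """Rank-based set enrichment of per-feature importance scores.

    ``scores`` maps feature id to its signed condition beta. Sets with
    fewer than ``min_set_size`` scored members are skipped (reported with
    ``tested = False``). ``de_ids``, when given, feeds the per-set DE
    fraction column.
    """
    cfg = cfg or EnrichmentConfig()
    if len(scores) == 0:
        raise ValueError("empty score vector")
    scored = set(scores.index)
    de_ids = set(de_ids) if de_ids is not None else set()
    bg_median_all = float(scores.median())

    rows = []
    for name, members in sets:
        in_set = sorted(members & scored)
        if len(in_set) < cfg.min_set_size:
            rows.append(
                {
                    "set_name": name,
                    "tested": False,
                    "n_members_scored": len(in_set),
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "direction": "none",
                    "frac_de": np.nan,
                    "median_score_in_set": np.nan,
                    "median_score_background": bg_median_all,
                }
            )
            continue
        member_scores = scores.loc[in_set].to_numpy()
        bg_scores = scores.loc[sorted(scored - members)].to_numpy()
        if cfg.method == "rank_sum":
            stat, p = stats.mannwhitneyu(
                member_scores, bg_scores, alternative="two-sided", method="auto"
            )
        else:
            ks = stats.ks_2samp(member_scores, bg_scores)
            stat, p = ks.statistic, ks.pvalue
        med_in = float(np.median(member_scores))
        med_bg = float(np.median(bg_scores))
        rows.append(
            {
                "set_name": name,
                "tested": True,
                "n_members_scored": len(in_set),
                "statistic": float(stat),
                "p_value": float(p),
                "direction": "up" if med_in > med_bg else "down",
                "frac_de": len(set(in_set) & de_ids) / len(in_set),
                "median_score_in_set": med_in,
                "median_score_background": med_bg,
            }
        )
    out = pd.DataFrame(rows).set_index("set_name").sort_index()
    tested = out["tested"]
    q = np.full(len(out), np.nan)
    q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    out["q_value"] = q
    out["significant"] = out["q_value"] < cfg.q_threshold
    return out


def overrepresentation_test(
    de_ids,
    universe,
    sets: GeneSetCollection,
    cfg: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """One-sided Fisher exact overrepresentation of DE features per set."""
    cfg = cfg or EnrichmentConfig()
    universe = set(universe)
    de = set(de_ids)
    if not universe:
        raise ValueError("empty universe")
    if not de <= universe:
        raise ValueError("de_ids must be a subset of the universe")

    rows = []
    for name, members in sets:
        m = members & universe
        a = len(de & m)
        b = len(de - m)
        c = len(m - de)
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set_name": name,
                "n_in_universe": len(m),
                "n_de_in_set": a,
                "p_value": float(p),
                "frac_de": a / len(m) if m else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("set_name").sort_index()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < cfg.q_threshold
    return out
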