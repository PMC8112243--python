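"""Negative-binomial differential expression between case and control.

Per feature: size-factor-normalised counts, a method-of-moments dispersion
pooled within conditions, a pseudo-mean-stabilised log2 fold change, and a
Wald test whose standard error comes from the NB delta-method variance of
each group mean. P-values are BH-adjusted; a feature is flagged DE when
q < alpha and |log2FC| >= lfc_threshold. This is deliberately a plain NB
Wald test: no dispersion trend shrinkage or fold-change moderation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hervlink.counts import CountMatrix

LN2 = np.log(2.0)


@dataclass
class DEConfig:
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    dispersion_floor: float = 1e-8
    pseudo_mean: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def nb_de_test(cm: CountMatrix, sf: pd.Series, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Wald test of case vs control per feature.

    Returns a DataFrame indexed by feature id with columns base_mean,
    log2fc (case over control), se_log2fc, p_value, q_value, is_de,
    direction.
    """
    cfg = cfg or DEConfig()
    case = cm.condition_mask("case")
    ctrl = cm.condition_mask("control")
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("need >= 2 samples per condition")

    y = cm.counts.to_numpy(dtype=float) / sf.reindex(cm.sample_ids).to_numpy()
    yc, y0 = y[:, case], y[:, ctrl]
    nc, n0 = yc.shape[1], y0.shape[1]
    mc, m0 = yc.mean(axis=1), y0.mean(axis=1)
    base_mean = y.mean(axis=1)

    # method-of-moments dispersion, pooled across the two conditions:
    # var = mu + alpha mu^2  =>  alpha = (var - mu) / mu^2
    vc, v0 = yc.var(axis=1, ddof=1), y0.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ac = (vc - mc) / np.square(mc)
        a0 = (v0 - m0) / np.square(m0)
    disp = np.nanmean(np.stack([ac, a0]), axis=0)
    disp = np.where(np.isfinite(disp), disp, cfg.dispersion_floor)
    disp = np.maximum(disp, cfg.dispersion_floor)

    c = cfg.pseudo_mean
    log2fc = np.log2((mc + c) / (m0 + c))
    # delta method: Var(log2 mean_g) ~ Var(mean_g) / ((mean_g)^2 ln2^2),
    # Var(mean_g) = (mu + alpha mu^2) / n_g; pseudo-mean keeps zeros finite
    var_c = (mc + c + disp * np.square(mc + c)) / (nc * np.square(mc + c) * LN2**2)
    var_0 = (m0 + c + disp * np.square(m0 + c)) / (n0 * np.square(m0 + c) * LN2**2)
    se = np.sqrt(var_c + var_0)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(p)
    is_de = (q < cfg.alpha) & (np.abs(log2fc) >= cfg.lfc_threshold)
    direction = np.where(~is_de, "none", np.where(log2fc > 0, "up", "down"))

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "p_value": p,
            "q_value": q,
            "is_de": is_de,
            "direction": direction,
        },
        index=cm.counts.index,
    )


def summarize_de(res: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Counts of up/down/total DE, both with the fold-change threshold
    applied (the ``is_de`` flag) and on q-value alone."""
    flagged = res[res["is_de"]]
    q_only = res[res["q_value"] < alpha]
    return {
        "n_up": int((flagged["direction"] == "up").sum()),
        "n_down": int((flagged["direction"] == "down").sum()),
        "n_de": int(len(flagged)),
        "n_up_q_only": int((q_only["log2fc"] > 0).sum()),
        "n_down_q_only": int((q_only["log2fc"] < 0).sum()),
        "n_de_q_only": int(len(q_only)),
        "n_tested": int(len(res)),
    }
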