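"""Per-feature condition models and HERV-gene pair associations.

Expression is transformed to log2(normalised + 1) (or log2(CPM + 1)) and
modelled with ordinary least squares: a case-indicator model per feature
whose slope is the feature's condition effect (used downstream as the
enrichment importance score), and a gene-on-HERV simple regression per
proximity pair, BH-corrected within the tested pair family, with Spearman
correlation on the same transformed values.

The regressions are simple two-parameter OLS fits computed in closed form
and vectorised across features/pairs; tests cross-check them against a
general linear-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hervlink.counts import CountMatrix
from hervlink.de import bh_adjust
from hervlink.filtering import size_factors


@dataclass
class AssociationConfig:
    transform: str = "log2_norm_plus1"  # or "log2_cpm_plus1"
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.transform not in ("log2_norm_plus1", "log2_cpm_plus1"):
            raise ValueError(f"unknown transform {self.transform!r}")


def transform_expression(cm: CountMatrix, cfg: AssociationConfig | None = None) -> pd.DataFrame:
    cfg = cfg or AssociationConfig()
    x = cm.counts.to_numpy(dtype=float)
    if cfg.transform == "log2_cpm_plus1":
        lib = x.sum(axis=0)
        norm = x / lib * 1e6
    else:
        sf = size_factors(cm)
        norm = x / sf.to_numpy()
    return pd.DataFrame(np.log2(norm + 1.0), index=cm.counts.index, columns=cm.counts.columns)


def _simple_ols(y: np.ndarray, x: np.ndarray):
    """Closed-form simple regression of each row of ``y`` on the vector
    ``x``: returns (beta, se, t, p) with n-2 df residual variance."""
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 samples")
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0:
        raise ValueError("regressor has zero variance")
    yc = y - y.mean(axis=1, keepdims=True)
    beta = yc @ xc / sxx
    resid = yc - np.outer(beta, xc)
    s2 = (resid**2).sum(axis=1) / (n - 2)
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where((se == 0) & (beta == 0), 1.0, p)
    return beta, se, t, p


def fit_condition_model(
    cm: CountMatrix, cfg: AssociationConfig | None = None
) -> pd.DataFrame:
    """OLS of transformed expression on a case indicator, per feature.

    Returns beta (case minus control mean on the log2 scale), se, p, and
    BH q, indexed by feature id.
    """
    cfg = cfg or AssociationConfig()
    if cm.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    expr = transform_expression(cm, cfg).to_numpy()
    x = cm.condition_mask("case").astype(float)
    if x.sum() == 0 or x.sum() == x.size:
        raise ValueError("both conditions must be present")
    beta, se, _t, p = _simple_ols(expr, x)
    return pd.DataFrame(
        {"beta": beta, "se": se, "p_value": p, "q_value": bh_adjust(p)},
        index=cm.counts.index,
    )


def fit_pair_association(
    cm_gene: CountMatrix,
    cm_herv: CountMatrix,
    pairs,
    cfg: AssociationConfig | None = None,
) -> pd.DataFrame:
    """OLS of transformed gene expression on transformed HERV expression for
    each requested (herv_id, gene_id) pair, with BH across tested pairs and
    Spearman rho on the same values."""
    cfg = cfg or AssociationConfig()
    if list(cm_gene.sample_ids) != list(cm_herv.sample_ids):
        raise ValueError("gene and HERV matrices must share sample order")
    gene_expr = transform_expression(cm_gene, cfg)
    herv_expr = transform_expression(cm_herv, cfg)

    rows = []
    for herv_id, gene_id in pairs:
        if herv_id not in herv_expr.index:
            raise KeyError(f"unknown HERV {herv_id!r}")
        if gene_id not in gene_expr.index:
            raise KeyError(f"unknown gene {gene_id!r}")
        x = herv_expr.loc[herv_id].to_numpy()
        y = gene_expr.loc[gene_id].to_numpy()
        if np.std(x) == 0:
            rows.append((herv_id, gene_id, np.nan, np.nan, 1.0, np.nan))
            continue
        beta, se, _t, p = _simple_ols(y[None, :], x)
        rho = stats.spearmanr(x, y).statistic if np.std(y) > 0 else np.nan
        rows.append((herv_id, gene_id, float(beta[0]), float(se[0]), float(p[0]), rho))

    out = pd.DataFrame(
        rows, columns=["herv_id", "gene_id", "beta", "se", "p_value", "spearman_rho"]
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < cfg.q_threshold
    return out


def rank_top_associations(res: pd.DataFrame, k: int) -> pd.DataFrame:
    """Significant pairs sorted by |Spearman rho| descending, ties by
    ascending q, truncated to the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = res[res["significant"]].copy()
    sig["_abs_rho"] = sig["spearman_rho"].abs()
    sig = sig.sort_values(["_abs_rho", "q_value"], ascending=[False, True])
    return sig.drop(columns="_abs_rho").head(k).reset_index(drop=True)
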