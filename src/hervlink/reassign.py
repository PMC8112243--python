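"""EM reassignment of ambiguously mapped fragments to single HERV loci.

Fragments aligning to several loci of a HERV family are resolved with a
Dirichlet-regularised mixture model over loci, fitted by
expectation-maximization. Alignment scores enter the fragment likelihood
through w(f, l) = exp(lambda * (score(f, l) - best_score(f))), so only
score differences within a fragment matter. The symmetric Dirichlet prior
carries a total pseudo-count ``theta_prior`` (default 200,000) split
uniformly across loci, giving the strong shrinkage toward uniform locus
proportions that stabilises sparse loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class FragmentAlignments:
    """Sparse (fragment, locus, alignment_score) candidate table."""

    fragment_ids: list[str]
    locus_ids: list[str]
    entries: list[tuple[int, int, float]]  # (fragment index, locus index, score)

    def __post_init__(self) -> None:
        if len(set(self.fragment_ids)) != len(self.fragment_ids):
            raise ValueError("duplicate fragment ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        seen = set()
        covered = np.zeros(len(self.fragment_ids), dtype=bool)
        for f, l, s in self.entries:
            if not np.isfinite(s):
                raise ValueError("non-finite alignment score")
            if (f, l) in seen:
                raise ValueError(f"duplicate (fragment, locus) pair ({f}, {l})")
            seen.add((f, l))
            covered[f] = True
        if not covered.all():
            bad = [self.fragment_ids[i] for i in np.flatnonzero(~covered)[:5]]
            raise ValueError(f"fragments with no candidate locus: {bad}")

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def score_matrix(self) -> sparse.csr_matrix:
        """CSR candidate-score matrix; explicit zeros kept via +1 offset avoided
        by storing scores shifted so membership is carried in the sparsity
        structure separately."""
        f = np.array([e[0] for e in self.entries])
        l = np.array([e[1] for e in self.entries])
        s = np.array([e[2] for e in self.entries], dtype=np.float64)
        return sparse.csr_matrix(
            (s, (f, l)), shape=(self.n_fragments, self.n_loci)
        )


@dataclass
class EMConfig:
    max_iter: int = 200
    theta_prior: float = 200_000.0
    tol: float = 1e-6
    reassign_mode: str = "best"  # or "average"
    score_lambda: float = 0.1

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.theta_prior < 0:
            raise ValueError("theta_prior must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.reassign_mode not in ("best", "average"):
            raise ValueError("reassign_mode must be 'best' or 'average'")


@dataclass
class ReassignmentResult:
    locus_ids: list[str]
    pi: np.ndarray  # mixture weights, sum to 1
    responsibilities: sparse.csr_matrix  # fragment x locus, rows sum to 1
    n_iter: int
    converged: bool
    log_posterior: float
    log_posterior_trace: list[float] = field(default_factory=list)


def _weights(aln: FragmentAlignments, lam: float):
    """Per-entry likelihood weights exp(lam * (score - fragment best))."""
    f = np.array([e[0] for e in aln.entries], dtype=np.intp)
    l = np.array([e[1] for e in aln.entries], dtype=np.intp)
    s = np.array([e[2] for e in aln.entries], dtype=np.float64)
    best = np.full(aln.n_fragments, -np.inf)
    np.maximum.at(best, f, s)
    w = np.exp(lam * (s - best[f]))
    return f, l, w


def em_fit(aln: FragmentAlignments, cfg: EMConfig | None = None) -> ReassignmentResult:
    """Fit locus mixture weights by MAP EM.

    E-step: responsibility r(f, l) proportional to pi_l * w(f, l) over the
    fragment's candidates. M-step: pi_l proportional to sum_f r(f, l) +
    theta_prior / n_loci (MAP under the symmetric Dirichlet). Stops when the
    relative change in the penalised log-likelihood drops below ``tol`` or
    after ``max_iter`` sweeps. The penalised log-likelihood is non-decreasing
    across iterations (standard EM monotonicity), asserted per sweep.
    """
    cfg = cfg or EMConfig()
    if aln.n_fragments < 1:
        raise ValueError("need at least one fragment")
    n_loci, n_frag = aln.n_loci, aln.n_fragments
    f_idx, l_idx, w = _weights(aln, cfg.score_lambda)
    theta = cfg.theta_prior / n_loci

    pi = np.full(n_loci, 1.0 / n_loci)
    trace: list[float] = []
    converged = False
    n_iter = 0
    r = None
    for n_iter in range(1, cfg.max_iter + 1):
        # E-step
        num = pi[l_idx] * w
        denom = np.zeros(n_frag)
        np.add.at(denom, f_idx, num)
        r = num / denom[f_idx]
        # penalized log-likelihood at current pi
        with np.errstate(divide="ignore"):
            lp = float(np.log(denom).sum()) + theta * float(np.log(pi[pi > 0]).sum())
        if trace:
            assert lp >= trace[-1] - 1e-8 * max(1.0, abs(trace[-1])), "EM log-posterior decreased"
            if abs(lp - trace[-1]) <= cfg.tol * max(1.0, abs(trace[-1])):
                trace.append(lp)
                converged = True
                break
        trace.append(lp)
        # M-step
        counts = np.zeros(n_loci)
        np.add.at(counts, l_idx, r)
        pi = counts + theta
        pi /= pi.sum()

    resp = sparse.csr_matrix((r, (f_idx, l_idx)), shape=(n_frag, n_loci))
    return ReassignmentResult(
        locus_ids=list(aln.locus_ids),
        pi=pi,
        responsibilities=resp,
        n_iter=n_iter,
        converged=converged,
        log_posterior=trace[-1],
        log_posterior_trace=trace,
    )


def best_assignments(result: ReassignmentResult) -> list[str]:
    """Per-fragment argmax-responsibility locus id, ties broken by
    lexicographically smallest locus id."""
    r = result.responsibilities.tocsr()
    n_loci = r.shape[1]
    order = np.argsort(result.locus_ids)
    rank = np.empty(n_loci, dtype=np.intp)
    rank[order] = np.arange(n_loci)
    out = []
    for i in range(r.shape[0]):
        s, e = r.indptr[i], r.indptr[i + 1]
        cols, vals = r.indices[s:e], r.data[s:e]
        tied = cols[vals >= vals.max() - 1e-12]
        out.append(result.locus_ids[tied[np.argmin(rank[tied])]])
    return out


def reassign_to_counts(
    result: ReassignmentResult, aln: FragmentAlignments, mode: str | None = None
) -> pd.Series:
    """Turn fitted responsibilities into a per-locus count column.

    ``best`` assigns each fragment wholly to its argmax-responsibility locus
    (ties broken by lexicographically smallest locus id); ``average``
    distributes fractional responsibilities. Both conserve the fragment
    total.
    """
    mode = mode or "best"
    r = result.responsibilities.tocsr()
    n_frag, n_loci = r.shape
    counts = np.zeros(n_loci)
    if mode == "average":
        counts = np.asarray(r.sum(axis=0)).ravel()
    elif mode == "best":
        l_index = {lid: i for i, lid in enumerate(result.locus_ids)}
        for lid in best_assignments(result):
            counts[l_index[lid]] += 1
    else:
        raise ValueError("mode must be 'best' or 'average'")
    return pd.Series(counts, index=result.locus_ids)


def read_fragment_alignments(tsv_path) -> FragmentAlignments:
    """Read a sparse TSV of (fragment_id, locus_id, score) triples."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"fragment_id": str, "locus_id": str})
    frag_ids = sorted(df["fragment_id"].unique())
    locus_ids = sorted(df["locus_id"].unique())
    f_map = {f: i for i, f in enumerate(frag_ids)}
    l_map = {l: i for i, l in enumerate(locus_ids)}
    entries = [
        (f_map[f], l_map[l], float(s))
        for f, l, s in zip(df["fragment_id"], df["locus_id"], df["score"])
    ]
    return FragmentAlignments(frag_ids, locus_ids, entries)


def write_fragment_alignments(aln: FragmentAlignments, tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("fragment_id\tlocus_id\tscore\n")
        for f, l, s in aln.entries:
            fh.write(f"{aln.fragment_ids[f]}\t{aln.locus_ids[l]}\t{s:g}\n")
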