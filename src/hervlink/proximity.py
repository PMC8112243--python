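"""Expanding-window nearest-gene search around HERV loci and the
DE-vs-non-DE distance comparison.

Each HERV is first intersected with the gene annotation: an overlap gives
distance 0 and relation ``exonic`` when any overlapped gene's exon touches
the HERV, else ``intronic``, with every overlapped element reported. A
non-overlapping HERV is searched with a symmetric window that starts at
500 bp each side and grows in 500 bp steps until a gene appears or the
10 kb limit is hit; beyond the limit the relation is ``none_within_limit``.
Distances are unstranded gaps between half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from hervlink.annotations import AnnotationSet, GeneFeature, HervLocus


@dataclass
class ProximityConfig:
    initial_window_bp: int = 500
    max_window_bp: int = 10_000
    expansion_step_bp: int = 500
    gene_universe: str = "all"  # or "protein_coding"

    def __post_init__(self) -> None:
        if not 0 < self.initial_window_bp <= self.max_window_bp:
            raise ValueError("need 0 < initial_window_bp <= max_window_bp")
        if self.expansion_step_bp <= 0:
            raise ValueError("expansion_step_bp must be > 0")

    def windows(self):
        w = self.initial_window_bp
        while True:
            yield min(w, self.max_window_bp)
            if w >= self.max_window_bp:
                return
            w += self.expansion_step_bp


@dataclass
class ProximityRecord:
    herv_id: str
    nearest_gene_id: str | None
    distance_bp: int | None
    relation: str  # exonic | intronic | proximal | none_within_limit
    intersected_elements: list[tuple[str, str, str]] = field(default_factory=list)
    # (gene_id, biotype, region {exon, intron})


def _eligible(gene: GeneFeature, cfg: ProximityConfig) -> bool:
    return cfg.gene_universe == "all" or gene.biotype == "protein_coding"


def find_nearest_gene(
    herv: HervLocus, ann: AnnotationSet, cfg: ProximityConfig | None = None
) -> ProximityRecord:
    cfg = cfg or ProximityConfig()
    iv = herv.interval
    overlapped = [
        g
        for g in ann.genes_in_window(iv.chrom, iv.start, iv.end)
        if _eligible(g, cfg)
    ]
    if overlapped:
        elements = []
        any_exon = False
        for g in overlapped:
            in_exon = any(e.overlaps(iv) for e in g.exons)
            any_exon = any_exon or in_exon
            elements.append((g.gene_id, g.biotype, "exon" if in_exon else "intron"))
        # ties among overlapped genes: smallest start, then gene_id
        best = min(overlapped, key=lambda g: (g.interval.start, g.gene_id))
        return ProximityRecord(
            herv_id=herv.locus_id,
            nearest_gene_id=best.gene_id,
            distance_bp=0,
            relation="exonic" if any_exon else "intronic",
            intersected_elements=elements,
        )

    for w in cfg.windows():
        # w is an inclusive gap limit: a gene at exactly w bp is found
        hits = [
            g
            for g in ann.genes_in_window(iv.chrom, iv.start - w, iv.end + w + 1)
            if _eligible(g, cfg)
        ]
        if hits:
            gaps = [iv.gap_to(g.interval) for g in hits]
            best_idx = min(
                range(len(hits)),
                key=lambda i: (gaps[i], hits[i].interval.start, hits[i].gene_id),
            )
            return ProximityRecord(
                herv_id=herv.locus_id,
                nearest_gene_id=hits[best_idx].gene_id,
                distance_bp=gaps[best_idx],
                relation="proximal",
            )
    return ProximityRecord(
        herv_id=herv.locus_id,
        nearest_gene_id=None,
        distance_bp=None,
        relation="none_within_limit",
    )


def proximity_table(
    hervs, ann: AnnotationSet, cfg: ProximityConfig | None = None
) -> list[ProximityRecord]:
    cfg = cfg or ProximityConfig()
    return [find_nearest_gene(h, ann, cfg) for h in hervs]


@dataclass
class DistanceTestResult:
    n_de: int
    n_non_de: int
    statistic: float
    p_value: float
    median_distance_de: float
    median_distance_non_de: float
    method: str = "rank_sum"


def _distances(records, censor_at: int | None):
    out = []
    for r in records:
        if r.relation == "none_within_limit":
            if censor_at is not None:
                out.append(censor_at)
        else:
            out.append(r.distance_bp)
    return np.asarray(out, dtype=float)


def distance_null_test(
    records_de,
    records_non_de,
    censor_unfound_at: int | None = None,
    method: str = "rank_sum",
) -> DistanceTestResult:
    """Two-sided rank test of DE-HERV nearest-gene distances against the
    null distribution built from non-DE HERVs.

    HERVs with no gene inside the window limit are dropped by default, or
    censored at ``censor_unfound_at`` when given. ``signed_rank_as_printed``
    is accepted as an alias for the rank-sum method (the comparison is
    unpaired, so the two-sample Mann-Whitney U is what is computed).
    """
    d_de = _distances(records_de, censor_unfound_at)
    d_nd = _distances(records_non_de, censor_unfound_at)
    if len(d_de) == 0 or len(d_nd) == 0:
        raise ValueError("both groups must contribute at least one distance")
    if method not in ("rank_sum", "signed_rank_as_printed"):
        raise ValueError(f"unknown method {method!r}")
    u, p = stats.mannwhitneyu(d_de, d_nd, alternative="two-sided", method="auto")
    return DistanceTestResult(
        n_de=len(d_de),
        n_non_de=len(d_nd),
        statistic=float(u),
        p_value=float(p),
        median_distance_de=float(np.median(d_de)),
        median_distance_non_de=float(np.median(d_nd)),
        method=method,
    )


def classify_intersections(records) -> dict:
    """Tallies of relation classes, intersected biotypes, and multi-element
    intersections across a set of proximity records."""
    tally = {
        "exonic": 0,
        "intronic": 0,
        "proximal": 0,
        "none_within_limit": 0,
        "intersecting_any": 0,
        "multi_element": 0,
        "by_biotype": {},
    }
    for r in records:
        tally[r.relation] += 1
        if r.relation in ("exonic", "intronic"):
            tally["intersecting_any"] += 1
            if len(r.intersected_elements) > 1:
                tally["multi_element"] += 1
            for _gid, biotype, _region in r.intersected_elements:
                tally["by_biotype"][biotype] = tally["by_biotype"].get(biotype, 0) + 1
    return tally


def records_to_frame(records):
    import pandas as pd

    return pd.DataFrame(
        {
            "herv_id": [r.herv_id for r in records],
            "nearest_gene_id": [r.nearest_gene_id or "" for r in records],
            "distance_bp": [r.distance_bp if r.distance_bp is not None else -1 for r in records],
            "relation": [r.relation for r in records],
            "n_intersected": [len(r.intersected_elements) for r in records],
        }
    )
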