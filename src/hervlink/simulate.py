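"""Synthetic two-dataset case/control studies with planted structure.

The generator emulates the statistical and genomic structure the pipeline
assumes: two whole-blood-style datasets (default case/control sizes 25/23
and 99/18) of negative-binomial counts over a shared feature universe; a
minority of planted DE features, heavily skewed toward upregulation; a
planted cross-dataset overlap of DE sets; HERV loci placed with tunable
physical linkage to DE genes; HERV family / coding / enhancer labels; and
ambiguous multi-locus fragment alignments within HERV family groups for
the EM stage. All outputs are pure functions of the config (seed
included); each stage draws from its own seeded substream so that, e.g.,
regenerating counts does not disturb the annotation.

It does not emulate nucleotide sequence, read-level error, GC or length
bias, batch effects, or correlated features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hervlink.annotations import AnnotationSet, GeneFeature, GenomicInterval, HervLocus
from hervlink.counts import CountMatrix
from hervlink.genesets import GeneSetCollection
from hervlink.reassign import FragmentAlignments

DEFAULT_SEED = 20210427

HERV_FAMILIES = (
    "ERV-L",
    "ERV3",
    "MER4",
    "HERV-H",
    "HERV-K",
    "HERV-L",
    "HERV-W",
    "HERV-S",
    "ERV316A3",
    "MER61",
)

_STAGE = {"annotation": 1, "counts": 2, "fragments": 3, "gene_sets": 4}


@dataclass
class SimulationConfig:
    seed: int = DEFAULT_SEED
    n_chroms: int = 4
    chrom_length_bp: int = 30_000_000
    n_genes: int = 2000
    n_hervs: int = 600
    # (n_case, n_control) per dataset; whole-blood study sizes by default
    dataset_sizes: tuple[tuple[int, int], ...] = ((25, 23), (99, 18))
    frac_de_genes: float = 0.05
    frac_de_hervs: float = 0.05
    frac_de_up: float = 0.95
    lfc_magnitude: float = 1.5
    lfc_sd: float = 0.25
    nb_dispersion: float = 0.1
    mean_log_mu: float = 4.0
    sd_log_mu: float = 1.2
    herv_mu_scale: float = 1.0 / 30.0
    library_size_range: tuple[float, float] = (0.7, 1.4)
    proximity_link_prob: float = 0.8
    link_dist_bp: int = 10_000
    shared_de_frac: float = 0.2
    coding_rate: float = 0.10
    enhancer_rate: float = 0.10
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (20, 60)
    n_enriched_sets: int = 5
    enriched_de_frac: float = 0.75
    ambiguity_group_size: int = 3
    best_hit_prob: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "frac_de_genes",
            "frac_de_hervs",
            "frac_de_up",
            "proximity_link_prob",
            "shared_de_frac",
            "coding_rate",
            "enhancer_rate",
            "enriched_de_frac",
            "best_hit_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for n_case, n_control in self.dataset_sizes:
            if n_case < 2 or n_control < 2:
                raise ValueError("need >= 2 case and >= 2 control samples per dataset")
        if self.lfc_magnitude <= 0:
            raise ValueError("lfc_magnitude must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.ambiguity_group_size < 1:
            raise ValueError("ambiguity_group_size must be >= 1")
        if self.n_enriched_sets > self.n_gene_sets:
            raise ValueError("n_enriched_sets cannot exceed n_gene_sets")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_sizes)

    def dataset_names(self) -> list[str]:
        return [f"d{i + 1}" for i in range(self.n_datasets)]


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery tests."""

    de_gene_ids: dict[str, frozenset[str]] = field(default_factory=dict)
    de_herv_ids: dict[str, frozenset[str]] = field(default_factory=dict)
    lfc: dict[str, pd.Series] = field(default_factory=dict)  # per dataset, all features
    linked_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# truth designation


def _designate_de(cfg: SimulationConfig, rng: np.random.Generator):
    """Pick DE features and their planted fold changes per dataset.

    Dataset 1's DE set is drawn fresh; each later dataset reuses
    ``shared_de_frac`` of dataset 1's DE features (with the same planted
    fold change, so cross-dataset fold changes correlate among shared DE
    features) and draws the remainder fresh.
    """
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    herv_ids_placeholder = list(range(cfg.n_hervs))  # real ids assigned at placement

    def draw_lfc(rng, n):
        mag = np.maximum(0.25, rng.normal(cfg.lfc_magnitude, cfg.lfc_sd, size=n))
        sign = np.where(rng.random(n) < cfg.frac_de_up, 1.0, -1.0)
        return mag * sign

    truth = SimulationTruth()
    names = cfg.dataset_names()

    for ids, frac, key in (
        (gene_ids, cfg.frac_de_genes, "gene"),
        (herv_ids_placeholder, cfg.frac_de_hervs, "herv"),
    ):
        n_de = max(1, int(round(frac * len(ids)))) if frac > 0 else 0
        de_sets: dict[str, list] = {}
        lfcs: dict[str, dict] = {}
        d1 = names[0]
        chosen = list(rng.choice(len(ids), size=n_de, replace=False)) if n_de else []
        de_sets[d1] = [ids[i] for i in chosen]
        vals = draw_lfc(rng, n_de)
        lfcs[d1] = dict(zip(de_sets[d1], vals))
        for d in names[1:]:
            n_shared = int(round(cfg.shared_de_frac * n_de))
            shared = list(rng.choice(de_sets[d1], size=n_shared, replace=False)) if n_shared else []
            pool = [x for x in ids if x not in set(shared)]
            n_fresh = max(0, n_de - n_shared)
            fresh = list(rng.choice(len(pool), size=n_fresh, replace=False)) if n_fresh else []
            de_sets[d] = shared + [pool[i] for i in fresh]
            lfc_d = {x: lfcs[d1][x] for x in shared}
            lfc_d.update(dict(zip([pool[i] for i in fresh], draw_lfc(rng, n_fresh))))
            lfcs[d] = lfc_d
        if key == "gene":
            truth.de_gene_ids = {d: frozenset(s) for d, s in de_sets.items()}
            truth._gene_lfcs = lfcs  # type: ignore[attr-defined]
        else:
            truth._herv_de_slots = de_sets  # type: ignore[attr-defined]
            truth._herv_lfcs_slots = lfcs  # type: ignore[attr-defined]
    return gene_ids, truth


# ---------------------------------------------------------------------------
# annotation


def _pseudo_cytoband(chrom: str, start: int) -> str:
    num = chrom.removeprefix("chr")
    return f"{num}q{start // 1_000_000 + 11}.{start // 100_000 % 10}"


def simulate_annotation(cfg: SimulationConfig) -> tuple[AnnotationSet, SimulationTruth]:
    """Place genes and HERV loci on synthetic chromosomes.

    Genes get simple exon/intron structure and are placed uniformly. Each
    DE-designated HERV is, with probability ``proximity_link_prob``, placed
    within ``link_dist_bp`` of a DE-designated gene (possibly inside it);
    all other HERVs are placed uniformly. Returns the annotation plus the
    partial truth (DE designations, fold changes, linked pairs).
    """
    rng = cfg.rng("annotation")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    L = cfg.chrom_length_bp

    gene_ids, truth = _designate_de(cfg, rng)

    genes: list[GeneFeature] = []
    for gid in gene_ids:
        length = int(rng.integers(2_000, 20_000))
        if length >= L:
            raise ValueError("chromosome too short for requested gene lengths")
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, L - length))
        iv = GenomicInterval(chrom, start, start + length)
        n_ex = int(rng.integers(1, 6))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex, replace=False))
        exons = tuple(
            GenomicInterval(chrom, start + int(cuts[2 * k]), start + int(cuts[2 * k + 1]))
            for k in range(n_ex)
            if cuts[2 * k] < cuts[2 * k + 1]
        )
        biotype = rng.choice(
            ["protein_coding", "lncRNA", "pseudogene", "other"], p=[0.55, 0.3, 0.1, 0.05]
        )
        genes.append(
            GeneFeature(interval=iv, gene_id=gid, symbol=f"SYM{gid[1:]}", biotype=str(biotype), exons=exons)
        )
    gene_by_id = {g.gene_id: g for g in genes}

    de_herv_slots: dict[str, list] = truth._herv_de_slots  # type: ignore[attr-defined]
    herv_lfc_slots: dict[str, dict] = truth._herv_lfcs_slots  # type: ignore[attr-defined]
    de_slot_union = sorted(set().union(*de_herv_slots.values())) if de_herv_slots else []
    de_gene_union = sorted(set().union(*truth.de_gene_ids.values()))

    hervs: list[HervLocus] = []
    used_ids: set[str] = set()
    slot_to_id: dict[int, str] = {}
    linked: list[tuple[str, str, int]] = []
    for slot in range(cfg.n_hervs):
        length = int(rng.integers(500, 8_000))
        family = str(rng.choice(HERV_FAMILIES))
        link = (
            slot in set(de_slot_union)
            and de_gene_union
            and rng.random() < cfg.proximity_link_prob
        )
        if link:
            g = gene_by_id[str(rng.choice(de_gene_union))]
            lo = max(0, g.interval.start - cfg.link_dist_bp - length)
            hi = min(L - length, g.interval.end + cfg.link_dist_bp)
            start = int(rng.integers(lo, hi + 1))
            chrom = g.interval.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, L - length))
        iv = GenomicInterval(chrom, start, start + length)
        locus_id = f"{family}_{_pseudo_cytoband(chrom, start)}"
        suffix = "abcdefghijklmnopqrstuvwxyz"
        k = 0
        while locus_id in used_ids:
            locus_id = f"{family}_{_pseudo_cytoband(chrom, start)}{suffix[k % 26]}{k // 26 or ''}"
            k += 1
        used_ids.add(locus_id)
        slot_to_id[slot] = locus_id
        hervs.append(
            HervLocus(
                interval=iv,
                locus_id=locus_id,
                family=family,
                is_coding=bool(rng.random() < cfg.coding_rate),
                in_enhancer=bool(rng.random() < cfg.enhancer_rate),
            )
        )
        if link:
            linked.append((locus_id, g.gene_id, iv.gap_to(g.interval)))

    truth.de_herv_ids = {
        d: frozenset(slot_to_id[s] for s in slots) for d, slots in de_herv_slots.items()
    }
    truth.linked_pairs = linked

    # full-length lfc series per dataset over genes + hervs
    herv_ids = [h.locus_id for h in hervs]
    gene_lfcs: dict[str, dict] = truth._gene_lfcs  # type: ignore[attr-defined]
    for d in cfg.dataset_names():
        s = pd.Series(0.0, index=gene_ids + herv_ids)
        for gid, v in gene_lfcs[d].items():
            s[gid] = v
        for slot, v in herv_lfc_slots[d].items():
            s[slot_to_id[slot]] = v
        truth.lfc[d] = s
    del truth._gene_lfcs, truth._herv_de_slots, truth._herv_lfcs_slots  # type: ignore[attr-defined]

    return AnnotationSet(genes=genes, hervs=hervs), truth


# ---------------------------------------------------------------------------
# counts


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    cfg: SimulationConfig, ann: AnnotationSet, truth: SimulationTruth
) -> dict[str, dict[str, CountMatrix]]:
    """NB counts per dataset, split into "genes" and "hervs" matrices.

    count[i, j] ~ NB(mean = s_j * mu_i * 2^(lfc_i * case_j), dispersion),
    with per-sample size factors s_j uniform over ``library_size_range``,
    lognormal baseline means (HERV baselines scaled by ``herv_mu_scale``),
    and lfc_i = 0 for non-DE features.
    """
    rng = cfg.rng("counts")
    gene_ids = [g.gene_id for g in ann.genes]
    herv_ids = [h.locus_id for h in ann.hervs]
    mu_gene = np.exp(rng.normal(cfg.mean_log_mu, cfg.sd_log_mu, size=len(gene_ids)))
    mu_herv = cfg.herv_mu_scale * np.exp(
        rng.normal(cfg.mean_log_mu, cfg.sd_log_mu, size=len(herv_ids))
    )

    out: dict[str, dict[str, CountMatrix]] = {}
    for d, (n_case, n_control) in zip(cfg.dataset_names(), cfg.dataset_sizes):
        n = n_case + n_control
        sample_ids = [f"{d}_case{i + 1}" for i in range(n_case)] + [
            f"{d}_ctrl{i + 1}" for i in range(n_control)
        ]
        condition = ["case"] * n_case + ["control"] * n_control
        is_case = np.array([c == "case" for c in condition], dtype=float)
        s = rng.uniform(*cfg.library_size_range, size=n)
        meta = pd.DataFrame({"condition": condition, "dataset": d}, index=sample_ids)

        out[d] = {}
        for key, ids, mu in (("genes", gene_ids, mu_gene), ("hervs", herv_ids, mu_herv)):
            lfc = truth.lfc[d].loc[ids].to_numpy()
            mean = s[None, :] * mu[:, None] * np.power(2.0, lfc[:, None] * is_case[None, :])
            counts = _nb_sample(rng, mean, cfg.nb_dispersion)
            out[d][key] = CountMatrix(
                pd.DataFrame(counts, index=ids, columns=sample_ids), meta
            )
    return out


# ---------------------------------------------------------------------------
# fragments


def family_groups(ann: AnnotationSet, group_size: int) -> list[list[str]]:
    """Partition HERV loci into within-family groups of ``group_size``
    (last group of a family may be smaller)."""
    if group_size > len(ann.hervs):
        raise ValueError("ambiguity_group_size exceeds locus count")
    by_family: dict[str, list[str]] = {}
    for h in ann.hervs:
        by_family.setdefault(h.family, []).append(h.locus_id)
    groups = []
    for fam in sorted(by_family):
        ids = sorted(by_family[fam])
        groups.extend(ids[i : i + group_size] for i in range(0, len(ids), group_size))
    return groups


@dataclass
class SimulatedFragments:
    alignments: FragmentAlignments
    true_counts: pd.Series  # true-origin tallies per locus
    origins: list[str]  # true locus per fragment, aligned with fragment_ids


def simulate_fragments(
    cfg: SimulationConfig,
    ann: AnnotationSet,
    herv_counts: CountMatrix,
) -> dict[str, SimulatedFragments]:
    """Ambiguous fragment-alignment tables per sample.

    Each HERV count becomes one fragment originating from its locus; the
    fragment reports candidate alignments to every locus in its family
    group, with integer scores in [0, 100]. The true locus receives the
    strictly best score with probability ``best_hit_prob``. Returns, per
    sample, the alignments plus the true-origin tallies and per-fragment
    origins.
    """
    rng = cfg.rng("fragments")
    groups = family_groups(ann, cfg.ambiguity_group_size)
    group_of = {lid: g for g in groups for lid in g}

    out = {}
    for sample in herv_counts.sample_ids:
        col = herv_counts.counts[sample]
        frag_ids: list[str] = []
        origins: list[str] = []
        entries: list[tuple[int, int, float]] = []
        locus_ids = list(herv_counts.feature_ids)
        l_index = {lid: i for i, lid in enumerate(locus_ids)}
        fi = 0
        for lid in locus_ids:
            c = int(col[lid])
            if c == 0:
                continue
            candidates = group_of[lid]
            for _ in range(c):
                frag_ids.append(f"{sample}_f{fi:06d}")
                origins.append(lid)
                scores = rng.integers(40, 91, size=len(candidates)).astype(float)
                ti = candidates.index(lid)
                if rng.random() < cfg.best_hit_prob:
                    scores[ti] = scores.max() + float(rng.integers(1, 10))
                for cand, sc in zip(candidates, scores):
                    entries.append((fi, l_index[cand], min(float(sc), 100.0)))
                fi += 1
        if fi == 0:
            continue
        aln = FragmentAlignments(frag_ids, locus_ids, entries)
        out[sample] = SimulatedFragments(
            alignments=aln, true_counts=col.astype(float), origins=origins
        )
    return out


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(cfg: SimulationConfig, truth: SimulationTruth) -> GeneSetCollection:
    """Gene-set collection with ``n_enriched_sets`` planted sets drawing at
    least ``enriched_de_frac`` of their members from DE-upregulated genes
    of dataset 1; background sets draw uniformly from all genes."""
    rng = cfg.rng("gene_sets")
    d1 = cfg.dataset_names()[0]
    all_genes = sorted(truth.lfc[d1].index[truth.lfc[d1].index.str.startswith("G")])
    de_up = sorted(
        g for g in truth.de_gene_ids.get(d1, ()) if truth.lfc[d1][g] > 0
    )

    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    enriched_names = []
    for k in range(cfg.n_gene_sets):
        size = int(rng.integers(cfg.set_size_range[0], cfg.set_size_range[1] + 1))
        name = f"SET{k:03d}"
        if k < cfg.n_enriched_sets:
            n_de = int(np.ceil(cfg.enriched_de_frac * size))
            if n_de > len(de_up):
                raise ValueError(
                    f"not enough DE-up genes ({len(de_up)}) to fill enriched set of {size}"
                )
            members = list(rng.choice(de_up, size=n_de, replace=False))
            rest_pool = [g for g in all_genes if g not in set(members)]
            members += list(rng.choice(rest_pool, size=size - n_de, replace=False))
            enriched_names.append(name)
            descriptions[name] = "planted enriched set"
        else:
            members = list(rng.choice(all_genes, size=size, replace=False))
            descriptions[name] = "background set"
        sets[name] = frozenset(members)
    truth.enriched_sets = enriched_names
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# whole studies


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    annotation: AnnotationSet
    truth: SimulationTruth
    counts: dict[str, dict[str, CountMatrix]]
    gene_sets: GeneSetCollection


def simulate_study(cfg: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a complete two-dataset study (no fragment tables; call
    :func:`simulate_fragments` on a HERV count matrix when the EM stage is
    exercised)."""
    cfg = cfg or SimulationConfig()
    ann, truth = simulate_annotation(cfg)
    counts = simulate_counts(cfg, ann, truth)
    gene_sets = simulate_gene_sets(cfg, truth)
    return SyntheticStudy(
        config=cfg, annotation=ann, truth=truth, counts=counts, gene_sets=gene_sets
    )


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=seed)
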