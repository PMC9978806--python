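"""Collinearity, duplication-type classification and gene-conversion tests.

Duplicate pairs are assigned to one of five modes with the precedence
WGD > tandem > proximal > transposed > dispersed:

* WGD — the pair is an anchor in a within-genome collinear block;
* TD — gene-order adjacent on one chromosome;
* PD — gene-order distance <= proximal_max_gap (default 10);
* TRD — exactly one member sits at an ancestral locus, operationalized
  as being an anchor in a genome-vs-outgroup collinear block;
* DSD — everything else.

Collinear blocks are maximal dynamic-programming chains of homology
anchors, strictly monotone in both genomes' gene orders (descending in
one for inverted blocks), with inter-anchor gaps bounded in gene-order
units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molevol import kaks_ng86

logger = logging.getLogger(__name__)

DUP_TYPES = ("WGD", "TD", "PD", "TRD", "DSD")


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def gene_orders(gene_df: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome gene-order indices from a gene table (IG/MEG only).

    Input needs columns gene_id, chrom, start, gene_class; returns a
    frame indexed by gene_id with columns chrom, order.
    """
    df = gene_df[gene_df.gene_class.isin(["IG", "MEG"])].copy()
    df = df.sort_values(["chrom", "start", "gene_id"])
    df["order"] = df.groupby("chrom").cumcount()
    return df.set_index("gene_id")[["chrom", "order"]]


def top_hits(homology: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Restrict a homology map to each gene's top-n scoring partners.

    A pair is kept when it ranks in the top n for either member
    (emulating per-query hit limits of all-vs-all searches).
    """
    if homology.empty:
        return homology.copy()
    df = homology.assign(score=homology.identity * homology.coverage)
    keep = set()
    half = pd.concat(
        [
            df.rename(columns={"gene_a": "g", "gene_b": "h"})[["g", "h", "score"]],
            df.rename(columns={"gene_b": "g", "gene_a": "h"})[["g", "h", "score"]],
        ]
    )
    half = half.sort_values(["g", "score", "h"], ascending=[True, False, True])
    for g, sub in half.groupby("g", sort=False):
        for h in sub.head(n).h:
            keep.add((min(g, h), max(g, h)))
    mask = [
        (min(a, b), max(a, b)) in keep for a, b in zip(homology.gene_a, homology.gene_b)
    ]
    return homology[mask].reset_index(drop=True)


def _best_chain(
    anchors: list[tuple[int, int, int]], sign: int, max_gap: int
) -> list[int]:
    """Best strictly-monotone chain (indices into ``anchors``).

    ``anchors`` holds (i, j, id); chains increase in i and in sign*j with
    both gaps <= max_gap. Returns anchor ids of the best chain.
    """
    if not anchors:
        return []
    arr = sorted(anchors, key=lambda x: (x[0], sign * x[1]))
    n = len(arr)
    score = [1] * n
    prev = [-1] * n
    for k in range(n):
        ik, jk, _ = arr[k]
        for p in range(k):
            ip, jp, _ = arr[p]
            if ip >= ik:
                continue
            dj = sign * (jk - jp)
            if dj <= 0:
                continue
            if ik - ip > max_gap or dj > max_gap:
                continue
            if score[p] + 1 > score[k]:
                score[k] = score[p] + 1
                prev[k] = p
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(arr[best][2])
        best = prev[best]
    return chain[::-1]


def chain_collinear_blocks(
    anchors: pd.DataFrame,
    orders: pd.DataFrame,
    orders_b: "pd.DataFrame | None" = None,
    *,
    max_gap_genes: int = 25,
    min_block_anchors: int = 5,
    max_median_step: "int | None" = None,
) -> list[CollinearBlock]:
    """Chain homology anchors into collinear blocks per chromosome pair.

    One order frame means a within-genome self comparison, where
    near-diagonal hits (tandem/proximal arrays) are masked so they cannot
    chain into spurious blocks; pass ``orders_b`` for genome-vs-genome
    comparisons. Chains are extracted greedily: the highest-scoring chain
    is removed and chaining repeats until none reaches
    ``min_block_anchors``.

    A chain must also be locally dense: its median inter-anchor step (in
    both genomes' gene orders) may not exceed ``max_median_step``
    (default max_gap_genes // 3). Scattered hits that only chain because
    every step sits at the gap bound are not real syntenic runs; they are
    discarded rather than emitted.
    """
    if max_median_step is None:
        max_median_step = max(1, max_gap_genes // 3)
    self_comparison = orders_b is None
    if orders_b is None:
        orders_b = orders
    ok = anchors.gene_a.isin(orders.index) & anchors.gene_b.isin(orders_b.index)
    anchors = anchors[ok]
    if anchors.empty:
        return []
    joined = anchors[["gene_a", "gene_b"]].copy()
    joined["chrom_a"] = orders.loc[joined.gene_a, "chrom"].to_numpy()
    joined["i"] = orders.loc[joined.gene_a, "order"].to_numpy()
    joined["chrom_b"] = orders_b.loc[joined.gene_b, "chrom"].to_numpy()
    joined["j"] = orders_b.loc[joined.gene_b, "order"].to_numpy()
    blocks: list[CollinearBlock] = []
    for (ca, cb), sub in joined.groupby(["chrom_a", "chrom_b"], sort=True):
        pool = {
            idx: (int(r.i), int(r.j), r.gene_a, r.gene_b)
            for idx, r in sub.iterrows()
            if not (self_comparison and ca == cb and abs(r.i - r.j) <= max_gap_genes)
        }
        while pool:
            best_chain, best_sign = [], 1
            for sign in (1, -1):
                triples = [(v[0], v[1], k) for k, v in pool.items()]
                chain = _best_chain(triples, sign, max_gap_genes)
                if len(chain) > len(best_chain):
                    best_chain, best_sign = chain, sign
            if len(best_chain) < min_block_anchors:
                break
            ii = np.array([pool[k][0] for k in best_chain])
            jj = np.array([pool[k][1] for k in best_chain])
            dense = (
                np.median(np.abs(np.diff(ii))) <= max_median_step
                and np.median(np.abs(np.diff(jj))) <= max_median_step
            )
            if dense:
                blocks.append(
                    CollinearBlock(
                        chrom_a=ca,
                        chrom_b=cb,
                        orientation="same" if best_sign == 1 else "inverted",
                        anchors=[(pool[k][2], pool[k][3]) for k in best_chain],
                    )
                )
            for k in best_chain:
                del pool[k]
    return blocks


def anchor_pair_set(blocks: list[CollinearBlock]) -> set[tuple[str, str]]:
    out = set()
    for b in blocks:
        for ga, gb in b.anchors:
            out.add((min(ga, gb), max(ga, gb)))
    return out


def anchored_genes(
    blocks: list[CollinearBlock], side: str = "a", *, interior_only: bool = True
) -> set[str]:
    """Genes appearing as block anchors on one side (ancestral-locus evidence).

    By default chain-terminal anchors are excluded: an interior anchor is
    constrained on both sides, whereas a stray hit can attach to a chain
    end with only a one-sided gap check.
    """
    idx = 0 if side == "a" else 1
    out: set[str] = set()
    for b in blocks:
        anchors = b.anchors[1:-1] if interior_only and len(b.anchors) > 2 else b.anchors
        out.update(a[idx] for a in anchors)
    return out


def classify_duplication_types(
    pairs: pd.DataFrame,
    blocks: list[CollinearBlock],
    orders: pd.DataFrame,
    outgroup_anchored: set[str],
    *,
    proximal_max_gap: int = 10,
) -> pd.DataFrame:
    """Five-way duplication classification under WGD>TD>PD>TRD>DSD precedence."""
    anchors = anchor_pair_set(blocks)
    rows = []
    for a, b in zip(pairs.gene_a, pairs.gene_b):
        key = (min(a, b), max(a, b))
        evidence = ""
        if a not in orders.index or b not in orders.index:
            logger.warning("pair (%s,%s) spans an unplaced contig; classified DSD", a, b)
            rows.append(dict(gene_a=key[0], gene_b=key[1], dup_type="DSD", evidence="unplaced"))
            continue
        ca, ia = orders.loc[a, "chrom"], int(orders.loc[a, "order"])
        cb, ib = orders.loc[b, "chrom"], int(orders.loc[b, "order"])
        dist = abs(ia - ib) if ca == cb else None
        if key in anchors:
            dup = "WGD"
            evidence = "block_anchor"
        elif dist == 1:
            dup = "TD"
            evidence = "adjacent"
        elif dist is not None and dist <= proximal_max_gap:
            dup = "PD"
            evidence = f"gene_order_distance={dist}"
        elif (a in outgroup_anchored) != (b in outgroup_anchored):
            dup = "TRD"
            evidence = "one_member_outgroup_anchored"
        else:
            dup = "DSD"
            evidence = "" if dist is None else f"gene_order_distance={dist}"
        rows.append(dict(gene_a=key[0], gene_b=key[1], dup_type=dup, evidence=evidence))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "dup_type", "evidence"])


# ---------------------------------------------------------------------------
# WGD quartets and the gene-conversion bootstrap
# ---------------------------------------------------------------------------


@dataclass
class Quartet:
    a1: str
    a2: str
    b1: str
    b2: str


def build_quartets(paralog_pairs: pd.DataFrame, rbh: pd.DataFrame) -> list[Quartet]:
    """Quartets from genome-A paralog pairs and A-vs-B reciprocal best hits."""
    ortho = dict(zip(rbh.gene_a, rbh.gene_b))
    quartets = []
    for a1, a2 in zip(paralog_pairs.gene_a, paralog_pairs.gene_b):
        b1, b2 = ortho.get(a1), ortho.get(a2)
        if b1 is None or b2 is None or b1 == b2:
            continue
        if len({a1, a2, b1, b2}) == 4:
            quartets.append(Quartet(a1, a2, b1, b2))
    return quartets


def _pair_contribs(cds_by_gene, x, y):
    return kaks_ng86(cds_by_gene[x], cds_by_gene[y])


def detect_gene_conversion(
    quartets: list[Quartet],
    cds_by_gene: dict[str, str],
    intron_counts: dict[str, int],
    *,
    n_bootstrap: int = 1000,
    support_threshold: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap test for gene conversion on WGD quartets.

    A quartet is called converted when the paralogs are closer to each
    other than either is to its ortholog — Ks(a1,a2) < min(Ks(a1,b1),
    Ks(a2,b2)) — and the inequality is preserved in at least
    ``support_threshold`` of codon-resampled replicates. Quartets with a
    saturated Ks anywhere in the sextet are skipped (flagged in the
    output). Paralog-pair class is IG-IG / IG-MEG / MEG-MEG by the intron
    counts of a1 and a2.
    """
    rng = np.random.default_rng(seed)
    columns = [
        "a1", "a2", "b1", "b2", "pair_class",
        "ks_paralog", "ks_ortholog_1", "ks_ortholog_2",
        "ks_paralog_b", "ks_cross_1", "ks_cross_2",
        "skipped", "converted", "bootstrap_support",
    ]
    rows = []
    for q in quartets:
        six = {}
        sat = False
        for x, y in [
            (q.a1, q.a2),
            (q.b1, q.b2),
            (q.a1, q.b1),
            (q.a2, q.b2),
            (q.a1, q.b2),
            (q.a2, q.b1),
        ]:
            r = _pair_contribs(cds_by_gene, x, y)
            six[(x, y)] = r
            if r.saturated_s:
                sat = True
        ig_a1 = intron_counts.get(q.a1, 0) == 0
        ig_a2 = intron_counts.get(q.a2, 0) == 0
        pclass = {2: "IG-IG", 1: "IG-MEG", 0: "MEG-MEG"}[int(ig_a1) + int(ig_a2)]
        base = dict(
            a1=q.a1, a2=q.a2, b1=q.b1, b2=q.b2, pair_class=pclass,
            ks_paralog=six[(q.a1, q.a2)].ks,
            ks_ortholog_1=six[(q.a1, q.b1)].ks,
            ks_ortholog_2=six[(q.a2, q.b2)].ks,
            ks_paralog_b=six[(q.b1, q.b2)].ks,
            ks_cross_1=six[(q.a1, q.b2)].ks,
            ks_cross_2=six[(q.a2, q.b1)].ks,
        )
        if sat:
            rows.append(dict(**base, skipped=True, converted=False, bootstrap_support=np.nan))
            continue
        kp = six[(q.a1, q.a2)]
        k1 = six[(q.a1, q.b1)]
        k2 = six[(q.a2, q.b2)]
        point = kp.ks < min(k1.ks, k2.ks)
        support = _bootstrap_support(kp, k1, k2, n_bootstrap, rng)
        rows.append(
            dict(
                **base,
                skipped=False,
                converted=bool(point and support >= support_threshold),
                bootstrap_support=support,
            )
        )
    return pd.DataFrame(rows, columns=columns)


def _resampled_ks(res, idx) -> float:
    pc = res.per_codon
    sd = pc["sd"].to_numpy()[idx].sum(axis=1)
    ss = pc["s_sites"].to_numpy()[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sd / ss
        d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.749999) / 3.0), np.nan)
    return d


def _bootstrap_support(kp, k1, k2, n_boot: int, rng) -> float:
    lens = {len(kp.per_codon), len(k1.per_codon), len(k2.per_codon)}
    if len(lens) == 1:
        # shared codon columns: resample jointly
        L = lens.pop()
        idx = rng.integers(0, L, size=(n_boot, L))
        ks_p = _resampled_ks(kp, idx)
        ks_1 = _resampled_ks(k1, idx)
        ks_2 = _resampled_ks(k2, idx)
    else:
        ks_p = _resampled_ks(kp, rng.integers(0, len(kp.per_codon), size=(n_boot, len(kp.per_codon))))
        ks_1 = _resampled_ks(k1, rng.integers(0, len(k1.per_codon), size=(n_boot, len(k1.per_codon))))
        ks_2 = _resampled_ks(k2, rng.integers(0, len(k2.per_codon), size=(n_boot, len(k2.per_codon))))
    ok = ~(np.isnan(ks_p) | np.isnan(ks_1) | np.isnan(ks_2))
    hold = ok & (ks_p < np.minimum(ks_1, ks_2))
    return float(hold.sum() / n_boot)


def conversion_rate_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Converted / total quartets per paralog-pair class."""
    rows = []
    for pclass in ("IG-IG", "IG-MEG", "MEG-MEG"):
        sub = calls[(calls.pair_class == pclass) & (~calls.skipped)]
        n = len(sub)
        conv = int(sub.converted.sum()) if n else 0
        rows.append(
            dict(
                pair_class=pclass,
                n_quartets=n,
                n_converted=conv,
                conversion_rate=conv / n if n else np.nan,
                n_skipped=int((calls.pair_class == pclass).sum() - n),
            )
        )
    return pd.DataFrame(rows)
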