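"""GFF3 parsing, intronless-gene calling, homology maps and pair sets.

The IG/MEG caller applies, in order: require at least one CDS line; drop
redundant records of the same locus (same chromosome, span and strand —
first record wins); drop organellar genes (contig names like MT/PT,
configurable); drop genes on unplaced scaffolds; pick the representative
transcript as the one with the longest summed CDS (ties to the
lexicographically smallest transcript id); count coding introns as the
number of CDS-bearing exon blocks minus one. A gene is intronless (IG)
iff its representative coding region is a single block.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

DEFAULT_ORGANELLAR = frozenset({"MT", "PT", "MITO", "CHLORO", "CHRM", "CHRC"})
DEFAULT_UNPLACED_RE = r"(?i)^(scaffold|contig|ctg|chrun|un)"

IG = "IG"
MEG = "MEG"
EXCLUDED = "EXCLUDED"


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    transcripts: dict[str, dict] = field(default_factory=dict)
    representative_transcript_id: str | None = None
    intron_count: int = -1
    gene_class: str = EXCLUDED
    exclusion_reason: str | None = None

    @property
    def is_ig(self) -> bool:
        return self.gene_class == IG


@dataclass
class GeneTable:
    genome_id: str
    genes: list[GeneModel]
    n_deduplicated: int = 0

    @property
    def counts(self) -> dict[str, int]:
        out = {IG: 0, MEG: 0, EXCLUDED: 0}
        for g in self.genes:
            out[g.gene_class] += 1
        out["deduplicated"] = self.n_deduplicated
        return out

    def class_of(self) -> dict[str, str]:
        return {g.gene_id: g.gene_class for g in self.genes}

    def intron_count_of(self) -> dict[str, int]:
        return {
            g.gene_id: g.intron_count for g in self.genes if g.gene_class != EXCLUDED
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    representative=g.representative_transcript_id,
                    intron_count=g.intron_count,
                    gene_class=g.gene_class,
                    exclusion_reason=g.exclusion_reason,
                )
                for g in self.genes
            ]
        )


def _merged_blocks(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge bookended/overlapping 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_gene_classes(
    gff3_path: str,
    *,
    genome_id: str = "genome",
    chromosomes: "set[str] | None" = None,
    organellar_names: frozenset = DEFAULT_ORGANELLAR,
    unplaced_pattern: str = DEFAULT_UNPLACED_RE,
) -> GeneTable:
    """Parse a GFF3 file and call IG/MEG/EXCLUDED classes.

    ``chromosomes``, when given, is the declared chromosome list: any
    other contig (that is not organellar) counts as unplaced. Otherwise
    unplaced contigs are recognised by ``unplaced_pattern``.
    """
    db = gffutils.create_db(
        gff3_path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    if not any(True for _ in db.features_of_type("CDS", limit=None)):
        raise ValueError(f"{gff3_path}: GFF3 contains no CDS features")
    unplaced_re = re.compile(unplaced_pattern)
    genes: list[GeneModel] = []
    seen_loci: set[tuple[str, int, int, str]] = set()
    n_dedup = 0
    for gene in db.features_of_type("gene", order_by="start"):
        gm = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
        )
        transcripts = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            transcripts[mrna.id] = dict(exons=exons, cds=cds)
        gm.transcripts = transcripts
        # filter 1: require a CDS line
        if not any(t["cds"] for t in transcripts.values()):
            gm.gene_class, gm.exclusion_reason = EXCLUDED, "no_cds"
            genes.append(gm)
            continue
        # filter 2: redundant records for the same locus (first wins)
        locus = (gm.chrom, gm.start, gm.end, gm.strand)
        if locus in seen_loci:
            n_dedup += 1
            continue
        seen_loci.add(locus)
        # filter 3: organellar contigs
        if gm.chrom.upper() in organellar_names:
            gm.gene_class, gm.exclusion_reason = EXCLUDED, "organellar"
            genes.append(gm)
            continue
        # filter 4: unplaced scaffolds
        if chromosomes is not None:
            unplaced = gm.chrom not in chromosomes
        else:
            unplaced = bool(unplaced_re.search(gm.chrom))
        if unplaced:
            gm.gene_class, gm.exclusion_reason = EXCLUDED, "unplaced"
            genes.append(gm)
            continue
        # representative transcript: longest total CDS, tie -> smallest id
        def cds_len(tid):
            return sum(e - s + 1 for s, e in transcripts[tid]["cds"])

        with_cds = [t for t in transcripts if transcripts[t]["cds"]]
        rep = min(with_cds, key=lambda t: (-cds_len(t), t))
        gm.representative_transcript_id = rep
        # exon/CDS consistency: every CDS inside some exon of its transcript
        exons = _merged_blocks(transcripts[rep]["exons"] or transcripts[rep]["cds"])
        bad = [
            (s, e)
            for s, e in transcripts[rep]["cds"]
            if not any(s >= xs and e <= xe for xs, xe in exons)
        ]
        if bad:
            logger.warning("%s: CDS outside exons %s; gene excluded as malformed", gene.id, bad)
            gm.gene_class, gm.exclusion_reason = EXCLUDED, "malformed"
            genes.append(gm)
            continue
        coding_blocks = _merged_blocks(transcripts[rep]["cds"])
        gm.intron_count = len(coding_blocks) - 1
        gm.gene_class = IG if gm.intron_count == 0 else MEG
        genes.append(gm)
    return GeneTable(genome_id=genome_id, genes=genes, n_deduplicated=n_dedup)


# ---------------------------------------------------------------------------
# pairwise CDS homology
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2.0
    a.mismatch_score = -3.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    # end-gap-free so that subsequence relationships are not penalized
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


def alignment_identity_coverage(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Global (end-gap-free) alignment identity and shorter-sequence coverage.

    identity = matches / columns where both sequences are non-gap;
    coverage = (columns where both non-gap) / length of the shorter one.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    matches = 0
    aligned_cols = 0
    for (as_, ae), (bs, be) in zip(*aln.aligned):
        aligned_cols += ae - as_
        for x, y in zip(seq_a[as_:ae], seq_b[bs:be]):
            if x == y:
                matches += 1
    if aligned_cols == 0:
        return 0.0, 0.0
    identity = matches / aligned_cols
    coverage = aligned_cols / min(len(seq_a), len(seq_b))
    return identity, coverage


def _kmer_candidates(
    cds_a: dict[str, str], cds_b: "dict[str, str] | None", k: int, min_shared: int
) -> set[tuple[str, str]]:
    def kmers(s):
        return {s[i : i + k] for i in range(0, len(s) - k + 1)}

    index: dict[str, set] = defaultdict(set)
    ka = {g: kmers(s) for g, s in cds_a.items()}
    for g, ks in ka.items():
        for km in ks:
            index[km].add(g)
    out: defaultdict[tuple[str, str], int] = defaultdict(int)
    if cds_b is None:  # within one genome: unordered pairs
        for g, ks in ka.items():
            hits: defaultdict[str, int] = defaultdict(int)
            for km in ks:
                for h in index[km]:
                    if h > g:
                        hits[h] += 1
            for h, c in hits.items():
                if c >= min_shared:
                    out[(g, h)] = c
    else:
        for g, s in cds_b.items():
            hits = defaultdict(int)
            for km in kmers(s):
                for h in index.get(km, ()):
                    hits[h] += 1
            for h, c in hits.items():
                if c >= min_shared:
                    out[(h, g)] = c
    return set(out)


def pairwise_cds_homology(
    cds_by_gene: dict[str, str],
    cds_by_gene_b: "dict[str, str] | None" = None,
    *,
    min_identity: float = 0.7,
    min_coverage: float = 0.7,
    k: int = 12,
    min_shared_kmers: int = 2,
) -> pd.DataFrame:
    """All-vs-all CDS homology with identity/coverage thresholds.

    One-genome mode (default) returns within-genome pairs stored once
    with gene_a < gene_b; two-dict mode compares genome A vs genome B.
    Candidate pairs are prefiltered by shared k-mers, then globally
    aligned; pairs meeting both thresholds are retained.
    """
    for g, s in cds_by_gene.items():
        if not s:
            raise ValueError(f"empty CDS for {g}")
    if cds_by_gene_b is not None:
        for g, s in cds_by_gene_b.items():
            if not s:
                raise ValueError(f"empty CDS for {g}")
    within = cds_by_gene_b is None
    cands = _kmer_candidates(cds_by_gene, cds_by_gene_b, k, min_shared_kmers)
    rows = []
    other = cds_by_gene if within else cds_by_gene_b
    for ga, gb in sorted(cands):
        ident, cov = alignment_identity_coverage(cds_by_gene[ga], other[gb])
        if ident >= min_identity and cov >= min_coverage:
            a, b = (min(ga, gb), max(ga, gb)) if within else (ga, gb)
            rows.append(
                dict(gene_a=a, gene_b=b, identity=ident, coverage=cov, within_genome=within)
            )
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "identity", "coverage", "within_genome"]
    )


def reciprocal_best_hits(cross: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal best hits from a cross-genome homology table.

    Best partner scored by identity * coverage; ties broken by gene id
    for determinism.
    """
    if cross.empty:
        return cross.copy()
    df = cross.assign(score=cross.identity * cross.coverage)
    df = df.sort_values(["score", "gene_a", "gene_b"], ascending=[False, True, True])
    best_ab = df.drop_duplicates("gene_a").set_index("gene_a")["gene_b"]
    best_ba = df.drop_duplicates("gene_b").set_index("gene_b")["gene_a"]
    keep = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    mask = df.apply(lambda r: (r.gene_a, r.gene_b) in set(keep), axis=1)
    return df[mask].drop(columns="score").reset_index(drop=True)


# ---------------------------------------------------------------------------
# paralog families, context bins, pair sets
# ---------------------------------------------------------------------------


def cluster_paralog_families(
    homology: pd.DataFrame, genes: "list[str] | None" = None
) -> dict[str, str]:
    """Single-linkage families over retained within-genome pairs.

    Returns gene -> family id (fam0001, ...). Genes in ``genes`` with no
    retained pair become singleton families.
    """
    parent: dict[str, str] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic: smaller id wins as root
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    if "within_genome" in homology.columns:
        hom = homology[homology.within_genome]
    else:
        hom = homology
    for a, b in zip(hom.gene_a, hom.gene_b):
        union(a, b)
    for g in genes or []:
        parent.setdefault(g, g)
    roots = sorted({find(g) for g in parent})
    fam_of_root = {r: f"fam{i + 1:05d}" for i, r in enumerate(roots)}
    return {g: fam_of_root[find(g)] for g in sorted(parent)}


CONTEXT_BINS = ["no_paralog", "intronless_only", "one_ME", "two_ME", "three_plus_ME"]


def classify_paralog_context(
    gene_table: GeneTable, homology: pd.DataFrame
) -> pd.DataFrame:
    """Per-IG paralog context: intronless vs multiexon paralog counts.

    Mixed cases are binned by multiexon-paralog count; ``intronless_only``
    is reserved for IGs whose every paralog is intronless.
    """
    cls = gene_table.class_of()
    partners: defaultdict[str, list[str]] = defaultdict(list)
    for a, b in zip(homology.gene_a, homology.gene_b):
        if cls.get(a) in (IG, MEG) and cls.get(b) in (IG, MEG):
            partners[a].append(b)
            partners[b].append(a)
    rows = []
    for g in sorted(gid for gid, c in cls.items() if c == IG):
        n_ig = sum(1 for p in partners.get(g, []) if cls[p] == IG)
        n_me = sum(1 for p in partners.get(g, []) if cls[p] == MEG)
        if n_ig == 0 and n_me == 0:
            b = "no_paralog"
        elif n_me == 0:
            b = "intronless_only"
        elif n_me == 1:
            b = "one_ME"
        elif n_me == 2:
            b = "two_ME"
        else:
            b = "three_plus_ME"
        if n_ig > 0 and n_me > 0:
            logger.debug("%s has mixed paralogy (%d IG, %d ME): binned %s", g, n_ig, n_me, b)
        rows.append(dict(gene_id=g, n_intronless_paralogs=n_ig, n_multiexon_paralogs=n_me, bin=b))
    return pd.DataFrame(rows, columns=["gene_id", "n_intronless_paralogs", "n_multiexon_paralogs", "bin"])


def context_bin_percentages(context: pd.DataFrame) -> pd.Series:
    """Percentage of IGs per paralog-context bin (bar-plot table)."""
    if len(context) == 0:
        return pd.Series(0.0, index=CONTEXT_BINS)
    pct = context["bin"].value_counts(normalize=True) * 100.0
    return pct.reindex(CONTEXT_BINS, fill_value=0.0)


def _count_bin(n: int) -> str:
    return str(n) if n < 3 else "3+"


def build_pair_sets(gene_table: GeneTable, homology: pd.DataFrame) -> pd.DataFrame:
    """Assign every retained within-genome pair to intronless / transition /
    multiexon sets, with transition pairs subdivided by the MEG partner's
    intron count and same-intron-count pairs collected separately."""
    introns = gene_table.intron_count_of()
    cls = gene_table.class_of()
    rows = []
    for a, b in zip(homology.gene_a, homology.gene_b):
        if cls.get(a) not in (IG, MEG) or cls.get(b) not in (IG, MEG):
            continue
        ia, ib = introns[a], introns[b]
        if ia == 0 and ib == 0:
            top = "intronless"
            sub = None
        elif ia > 0 and ib > 0:
            top = "multiexon"
            sub = None
        else:
            top = "transition"
            sub = _count_bin(max(ia, ib))
        same = _count_bin(ia) if ia == ib else None
        rows.append(
            dict(
                gene_a=a,
                gene_b=b,
                introns_a=ia,
                introns_b=ib,
                pair_set=top,
                transition_sub=sub,
                same_count=same,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "introns_a", "introns_b", "pair_set", "transition_sub", "same_count"],
    )
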