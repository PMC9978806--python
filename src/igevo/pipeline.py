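"""End-to-end orchestration: annotation -> homology -> families/pair sets ->
Ka/Ks -> duplication/conversion -> family dynamics -> intron gain/loss ->
retro density, writing one TSV per report table plus a JSON manifest.

Every stage is a pure function of (inputs, config); the manifest records
the seed and all thresholds so any table can be reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, duplication, genomescan, molevol, phylodynamics
from ._tree import load_dated_tree
from .stats import rank_sum

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full run.

    The input directory is expected to follow the simulator layout:
    ``<genome>.gff3``, ``<genome>.cds.fa``, ``retro/<genome>.bed`` and
    ``tree.nwk``. All thresholds default to the study values (0.7/0.7
    homology, 50-70% intronless + 60% presence family rule, neutral rate
    6.5e-9, 100-bp windows in 500-bp bins over 4-kb flanks, proximal gap
    10).
    """

    input_dir: Path
    output_dir: Path
    genomes: list[str] = field(default_factory=list)
    seed: int = 0
    min_identity: float = 0.7
    min_coverage: float = 0.7
    intronless_lo: float = 0.50
    intronless_hi: float = 0.70
    species_presence: float = 0.60
    neutral_rate: float = 6.5e-9
    flank: int = 4000
    window: int = 100
    bin_size: int = 500
    min_block_anchors: int = 5
    max_gap_genes: int = 25
    proximal_max_gap: int = 10
    top_n_hits: int = 5
    n_bootstrap: int = 200
    support_threshold: float = 0.95
    quartet_genomes: tuple[str, str] | None = None
    expression_path: Path | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not self.genomes:
            self.genomes = sorted(p.stem for p in self.input_dir.glob("*.gff3"))
        if not self.genomes:
            raise PipelineError("validate", f"no GFF3 inputs under {self.input_dir}")
        required = [self.input_dir / "tree.nwk"]
        for g in self.genomes:
            required += [
                self.input_dir / f"{g}.gff3",
                self.input_dir / f"{g}.cds.fa",
                self.input_dir / "retro" / f"{g}.bed",
            ]
        if self.expression_path is not None:
            required.append(Path(self.expression_path))
        missing = [str(p) for p in required if not p.exists()]
        if missing:
            raise PipelineError("validate", f"missing input files: {missing}")


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "igevo_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in vars(config).items()
            if not isinstance(v, (list,))
        },
        "genomes": config.genomes,
        "tables": {},
    }

    def _save(name: str, df: pd.DataFrame):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["tables"][name] = path.name

    stage = "annotation"
    try:
        tree = load_dated_tree(config.input_dir / "tree.nwk")
        gene_tables: dict[str, annotation.GeneTable] = {}
        cds: dict[str, dict[str, str]] = {}
        for g in config.genomes:
            gt = annotation.call_gene_classes(
                str(config.input_dir / f"{g}.gff3"), genome_id=g
            )
            gene_tables[g] = gt
            fasta = _read_fasta(config.input_dir / f"{g}.cds.fa")
            cds[g] = {
                gm.gene_id: fasta[gm.gene_id]
                for gm in gt.genes
                if gm.gene_class != annotation.EXCLUDED and gm.gene_id in fasta
            }
        _save(
            "gene_classes",
            pd.concat(
                [gt.to_dataframe().assign(genome=g) for g, gt in gene_tables.items()]
            ),
        )

        stage = "homology"
        within: dict[str, pd.DataFrame] = {}
        for g in config.genomes:
            within[g] = annotation.pairwise_cds_homology(
                cds[g], min_identity=config.min_identity, min_coverage=config.min_coverage
            )
        _save("homology_within", pd.concat(
            [h.assign(genome=g) for g, h in within.items()], ignore_index=True
        ))

        stage = "paralog_context"
        ctx_rows = []
        for g in config.genomes:
            ctx = annotation.classify_paralog_context(gene_tables[g], within[g])
            pct = annotation.context_bin_percentages(ctx)
            for b, v in pct.items():
                ctx_rows.append(dict(genome=g, bin=b, percent=v))
        _save("fig1_paralog_context", pd.DataFrame(ctx_rows))

        stage = "pair_sets"
        pair_sets = {
            g: annotation.build_pair_sets(gene_tables[g], within[g])
            for g in config.genomes
        }
        _save("fig6_pair_sets", pd.concat(
            [p.assign(genome=g) for g, p in pair_sets.items()], ignore_index=True
        ))

        stage = "kaks"
        kaks: dict[str, pd.DataFrame] = {}
        for g in config.genomes:
            pairs = list(zip(within[g].gene_a, within[g].gene_b))
            kaks[g] = molevol.kaks_table(pairs, cds[g])
            kaks[g]["T_my"] = [
                molevol.divergence_time(k, molevol.EvolConstants(config.neutral_rate))
                if not np.isnan(k)
                else np.nan
                for k in kaks[g].ks
            ]
        _save("kaks_pairs", pd.concat(
            [k.assign(genome=g) for g, k in kaks.items()], ignore_index=True
        ))
        # Fig 6 style: Ks by pair set
        f6 = []
        for g in config.genomes:
            merged = pair_sets[g].merge(kaks[g], on=["gene_a", "gene_b"], how="inner")
            if merged.empty:
                continue
            f6.append(
                molevol.summarize_kaks_by_group(merged, ["pair_set"], "ks").assign(genome=g)
            )
        if f6:
            _save("fig6_ks_by_pair_set", pd.concat(f6, ignore_index=True))

        stage = "duplication"
        dup_calls: dict[str, pd.DataFrame] = {}
        blocks_by_genome = {}
        cross_cache: dict[tuple[str, str], pd.DataFrame] = {}
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for g in config.genomes:
            orders = duplication.gene_orders(gene_tables[g].to_dataframe())
            anchors = duplication.top_hits(within[g], config.top_n_hits)
            blocks = duplication.chain_collinear_blocks(
                anchors,
                orders,
                max_gap_genes=config.max_gap_genes,
                min_block_anchors=config.min_block_anchors,
            )
            blocks_by_genome[g] = blocks
            outgroup = max(
                (h for h in config.genomes if h != g),
                key=lambda h: pdm.distance(taxa[g], taxa[h]),
            )
            key = tuple(sorted((g, outgroup)))
            if key not in cross_cache:
                cross_cache[key] = annotation.pairwise_cds_homology(
                    cds[key[0]], cds[key[1]],
                    min_identity=config.min_identity, min_coverage=config.min_coverage,
                )
            cross = cross_cache[key]
            if key[0] != g:  # orient: gene_a in g
                cross = cross.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
            out_orders = duplication.gene_orders(gene_tables[outgroup].to_dataframe())
            out_blocks = duplication.chain_collinear_blocks(
                duplication.top_hits(cross, config.top_n_hits),
                orders,
                out_orders,
                max_gap_genes=config.max_gap_genes,
                min_block_anchors=config.min_block_anchors,
            )
            anchored = duplication.anchored_genes(out_blocks, side="a")
            dup_calls[g] = duplication.classify_duplication_types(
                within[g], blocks, orders, anchored,
                proximal_max_gap=config.proximal_max_gap,
            )
        _save("duplication_calls", pd.concat(
            [d.assign(genome=g) for g, d in dup_calls.items()], ignore_index=True
        ))
        # Fig 4 style: Ks / Ka/Ks by duplication type and IG/MEG pair class
        f4 = []
        for g in config.genomes:
            cls = gene_tables[g].class_of()
            merged = dup_calls[g].merge(kaks[g], on=["gene_a", "gene_b"], how="inner")
            if merged.empty:
                continue
            merged["pair_class"] = [
                "IG" if cls[a] == "IG" and cls[b] == "IG" else
                "MEG" if cls[a] == "MEG" and cls[b] == "MEG" else "mixed"
                for a, b in zip(merged.gene_a, merged.gene_b)
            ]
            sub = merged[merged.pair_class.isin(["IG", "MEG"])]
            if sub.empty:
                continue
            for col in ("ks", "ratio"):
                f4.append(
                    molevol.summarize_kaks_by_group(
                        sub, ["dup_type"], col, compare_col="pair_class"
                    ).assign(genome=g, value=col)
                )
        if f4:
            _save("fig4_kaks_by_duptype", pd.concat(f4, ignore_index=True))

        stage = "conversion"
        qa, qb = config.quartet_genomes or (config.genomes[0], config.genomes[-1])
        key = tuple(sorted((qa, qb)))
        if key not in cross_cache:
            cross_cache[key] = annotation.pairwise_cds_homology(
                cds[key[0]], cds[key[1]],
                min_identity=config.min_identity, min_coverage=config.min_coverage,
            )
        cross = cross_cache[key]
        if key[0] != qa:
            cross = cross.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        rbh = annotation.reciprocal_best_hits(cross)
        wgd_pairs = dup_calls[qa][dup_calls[qa].dup_type == "WGD"]
        quartets = duplication.build_quartets(wgd_pairs, rbh)
        all_cds = dict(cds[qa])
        all_cds.update(cds[qb])
        introns = gene_tables[qa].intron_count_of()
        conv = duplication.detect_gene_conversion(
            quartets, all_cds, introns,
            n_bootstrap=config.n_bootstrap,
            support_threshold=config.support_threshold,
            seed=config.seed,
        )
        _save("fig5_conversion_calls", conv)
        _save("fig5_conversion_rates", duplication.conversion_rate_table(conv))

        stage = "family_dynamics"
        fam_of = _cross_species_families(config, cds, within, cross_cache)
        counts, ig_counts = _family_matrices(config, gene_tables, fam_of)
        flags = phylodynamics.flag_ig_families(
            counts, ig_counts,
            intronless_lo=config.intronless_lo,
            intronless_hi=config.intronless_hi,
            species_presence=config.species_presence,
        )
        nonzero = counts.sum(axis=1) > 0
        node_counts = phylodynamics.reconstruct_family_counts(counts[nonzero], tree)
        edges_ig = phylodynamics.summarize_edge_dynamics(node_counts, tree, flags[nonzero])
        edges_meg = phylodynamics.summarize_edge_dynamics(node_counts, tree, ~flags[nonzero])
        _save("fig3_flow_ig", edges_ig)
        _save("fig3_flow_meg", edges_meg)
        manifest["n_ig_families"] = int(flags.sum())

        stage = "intron_gain_loss"
        sites = _intron_site_matrix(config, gene_tables, fam_of)
        if len(sites) >= 10:
            res = phylodynamics.estimate_intron_gain_loss(sites, tree)
            _save("fig3_gain_loss", res.edge_table)
            manifest["intron_gain_rate"] = res.gain_rate
            manifest["intron_loss_rate"] = res.loss_rate
        else:
            logger.warning("too few intron sites (%d); gain/loss stage skipped", len(sites))

        stage = "retro_density"
        f2 = []
        for g in config.genomes:
            retro = pd.read_csv(
                config.input_dir / "retro" / f"{g}.bed",
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "name", "score", "strand"],
            )
            prof = genomescan.profile_retro_density(
                gene_tables[g].to_dataframe(),
                retro,
                flank=config.flank,
                window=config.window,
                bin_size=config.bin_size,
            )
            f2.append(genomescan.compare_density_profiles(prof).assign(genome=g))
        _save("fig2_retro_density", pd.concat(f2, ignore_index=True))

        stage = "expression"
        if config.expression_path is not None:
            expr = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            rows = []
            for g in config.genomes:
                cls = gene_tables[g].class_of()
                ig_vals = expr.loc[[i for i in expr.index if cls.get(i) == "IG"]]
                meg_vals = expr.loc[[i for i in expr.index if cls.get(i) == "MEG"]]
                for tissue in expr.columns:
                    a, b = ig_vals[tissue].dropna(), meg_vals[tissue].dropna()
                    if len(a) and len(b):
                        res = rank_sum(a, b)
                        rows.append(
                            dict(genome=g, tissue=tissue, median_ig=float(a.median()),
                                 median_meg=float(b.median()), p_value=res.p_two_sided,
                                 method=res.method)
                        )
            if rows:
                _save("fig8_expression", pd.DataFrame(rows))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _cross_species_families(config, cds, within, cross_cache) -> dict[str, str]:
    """Single-linkage orthogroups over within- plus cross-genome homology."""
    frames = [h for h in within.values()]
    genomes = config.genomes
    for i, gi in enumerate(genomes):
        for gj in genomes[i + 1 :]:
            key = (gi, gj)
            if key not in cross_cache:
                cross_cache[key] = annotation.pairwise_cds_homology(
                    cds[gi], cds[gj],
                    min_identity=config.min_identity, min_coverage=config.min_coverage,
                )
            frames.append(cross_cache[key])
    hom = pd.concat(frames, ignore_index=True)
    all_genes = [g for d in cds.values() for g in d]
    return annotation.cluster_paralog_families(
        hom.assign(within_genome=True), genes=all_genes
    )


def _family_matrices(config, gene_tables, fam_of):
    rows_total: dict[str, dict[str, int]] = {}
    rows_ig: dict[str, dict[str, int]] = {}
    for g in config.genomes:
        for gm in gene_tables[g].genes:
            if gm.gene_class == annotation.EXCLUDED:
                continue
            fam = fam_of.get(gm.gene_id)
            if fam is None:
                continue
            rows_total.setdefault(fam, {}).setdefault(g, 0)
            rows_total[fam][g] += 1
            if gm.gene_class == annotation.IG:
                rows_ig.setdefault(fam, {}).setdefault(g, 0)
                rows_ig[fam][g] += 1
    counts = pd.DataFrame.from_dict(rows_total, orient="index").fillna(0).astype(int)
    counts = counts.reindex(columns=config.genomes, fill_value=0).sort_index()
    ig = pd.DataFrame.from_dict(rows_ig, orient="index").fillna(0).astype(int)
    ig = ig.reindex(index=counts.index, columns=config.genomes, fill_value=0)
    return counts, ig


def _intron_site_matrix(config, gene_tables, fam_of) -> pd.DataFrame:
    """Rank-within-gene projection of intron positions onto families.

    Site ``fam:r`` is present in a genome when any family member there
    has at least r introns — a simplification of cross-species intron
    position homology.
    """
    max_rank: dict[str, int] = {}
    present: dict[tuple[str, int], set[str]] = {}
    for g in config.genomes:
        for gm in gene_tables[g].genes:
            fam = fam_of.get(gm.gene_id)
            if fam is None or gm.intron_count < 0:
                continue
            max_rank[fam] = max(max_rank.get(fam, 0), gm.intron_count)
            for r in range(1, gm.intron_count + 1):
                present.setdefault((fam, r), set()).add(g)
    rows = {}
    for (fam, r), genomes in sorted(present.items()):
        rows[f"{fam}:i{r}"] = {g: int(g in genomes) for g in config.genomes}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=config.genomes, fill_value=0
    )
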