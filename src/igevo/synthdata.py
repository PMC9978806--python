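"""Forward simulator for multi-genome datasets with known ground truth.

The generator enacts the retroposition model of IG origin: multi-exon
genes evolve along a dated species tree; copies arise by whole-genome,
tandem, proximal, transposed and dispersed duplication; transposed
copies lose their introns with high probability (the retroposition
route to intronless genes); intron sites within surviving lineages gain
and lose introns under a two-state Markov process; codon sequences
accumulate synonymous and nonsynonymous substitutions at configured
rates; and retroelement insertions are enriched around IG bodies.

Per leaf genome it emits GFF3 gene models (plus organellar, unplaced
and redundant-record decoys), genomic and CDS FASTA, and retro interval
BED; the TruthSet records every planted event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _codon
from ._tree import edges, load_dated_tree

DEFAULT_TREE = (
    "((Bdis:35,(Osat:18,Lper:18)Oryzoideae:17)PO:15,"
    "((Ecur:28,Otho:28)Chloridoideae:10,"
    "((Phal:20,Sita:20)Paniceae:6,(Sbic:16,Zmay:16)Andropogoneae:10)Panicoideae:12)CP:12)MRCA;"
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Rates are per gene (duplication, loss) or per intron site (gain,
    loss) per million years; ``ks_per_my`` is the per-lineage synonymous
    substitution rate per synonymous site per My (default r*1e6 with the
    neutral rate r = 6.5e-9/site/year).
    """

    seed: int = 0
    tree_newick: str = DEFAULT_TREE
    n_chromosomes: int = 2
    genes_per_chromosome: int = 500
    intergenic_gap_bp: int = 5000
    codon_length_range: tuple[int, int] = (100, 250)
    root_intron_mean: float = 3.0
    # discrete WGD events: (edge child label or "root", copy retention)
    wgd_events: tuple[tuple[str, float], ...] = (("root", 0.3),)
    td_rate: float = 0.0015
    pd_rate: float = 0.0015
    trd_rate: float = 0.003
    dsd_rate: float = 0.0015
    gene_loss_rate: float = 0.0015
    intron_gain_rate: float = 0.0005
    intron_loss_rate: float = 0.005
    ks_per_my: float = 6.5e-3
    ka_ks_target: float = 0.3
    trd_intron_removal_prob: float = 0.9
    proximal_max_gap: int = 10
    intron_length_range: tuple[int, int] = (80, 300)
    retro_baseline_per_kb: float = 0.4
    retro_enrichment_factor: float = 3.0
    retro_flank_bp: int = 4000
    retro_length_range: tuple[int, int] = (100, 400)
    n_organellar_genes: tuple[int, int] = (3, 2)  # MT, PT
    n_unplaced_scaffolds: int = 4
    redundant_record_fraction: float = 0.02

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("simulation would produce zero genes")
        for name in (
            "td_rate", "pd_rate", "trd_rate", "dsd_rate", "gene_loss_rate",
            "intron_gain_rate", "intron_loss_rate", "ks_per_my", "ka_ks_target",
            "retro_baseline_per_kb", "retro_enrichment_factor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.redundant_record_fraction <= 1:
            raise ValueError("redundant_record_fraction must be in [0, 1]")
        if not 0 <= self.trd_intron_removal_prob <= 1:
            raise ValueError("trd_intron_removal_prob must be in [0, 1]")
        for label, retention in self.wgd_events:
            if not 0 <= retention <= 1:
                raise ValueError(f"WGD retention for {label!r} must be in [0, 1]")


# ---------------------------------------------------------------------------
# codon sequence evolution
# ---------------------------------------------------------------------------


def evolve_codons(
    codons: np.ndarray, t: float, lam_s: float, lam_n: float, rng: np.random.Generator
) -> tuple[np.ndarray, int, int]:
    """Evolve a codon index array for time t under uniform per-option rates.

    Each synonymous single-nucleotide change fires at rate ``lam_s`` and
    each nonsynonymous change at ``lam_n``; stop codons are never offered
    as targets. Returns the evolved array and the realized numbers of
    synonymous and nonsynonymous substitution events.
    """
    codons = codons.copy()
    n_syn = n_non = 0
    rate = lam_s * _codon.N_SYN_OPTIONS[codons] + lam_n * _codon.N_NON_OPTIONS[codons]
    draws = rng.exponential(1.0, size=codons.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        first = np.where(rate > 0, draws / np.maximum(rate, 1e-300), np.inf)
    for i in np.nonzero(first < t)[0]:
        c = int(codons[i])
        tau = first[i]
        while tau < t:
            rs = lam_s * _codon.N_SYN_OPTIONS[c]
            rn = lam_n * _codon.N_NON_OPTIONS[c]
            if rng.random() * (rs + rn) < rs:
                targets = _codon.SYN_TARGETS[c]
                n_syn += 1
            else:
                targets = _codon.NON_TARGETS[c]
                n_non += 1
            c = int(targets[rng.integers(len(targets))])
            r2 = lam_s * _codon.N_SYN_OPTIONS[c] + lam_n * _codon.N_NON_OPTIONS[c]
            if r2 <= 0:
                break
            tau += rng.exponential(1.0 / r2)
        codons[i] = c
    return codons, n_syn, n_non


@dataclass
class EvolvedPair:
    cds_a: str
    cds_b: str
    n_syn_events: int
    n_non_events: int
    syn_sites: float  # NG86 synonymous sites of the ancestor
    non_sites: float
    saturated: bool

    @property
    def realized_ks(self) -> float:
        return self.n_syn_events / self.syn_sites

    @property
    def realized_ka(self) -> float:
        return self.n_non_events / self.non_sites


def evolve_codon_pair(
    ancestor_len_codons: int, ks: float, ka_ks: float, seed: int
) -> EvolvedPair:
    """Two CDS descended from a random ancestor at target (Ks, Ka).

    Substitution events are placed so that the expected number of
    synonymous events per synonymous site between the two sequences is
    ``ks`` and the nonsynonymous rate is ``ks * ka_ks``. A ``saturated``
    flag is raised when the requested divergence puts the expected
    p-distance at the Jukes-Cantor boundary.
    """
    if ancestor_len_codons < 1:
        raise ValueError("need at least one codon")
    if ks < 0 or ka_ks < 0:
        raise ValueError("ks and ka_ks must be >= 0")
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, len(_codon.SENSE_CODONS), size=ancestor_len_codons)
    lam_s = ks / 3.0 / 2.0  # per branch, unit branch time
    lam_n = ks * ka_ks / 3.0 / 2.0
    a, sa, na = evolve_codons(anc, 1.0, lam_s, lam_n, rng)
    b, sb, nb = evolve_codons(anc, 1.0, lam_s, lam_n, rng)
    syn_sites = float(_codon.SENSE_SYN_SITES[anc].sum())
    # expected JC p-distance at this many events per site
    p_expected = 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))
    return EvolvedPair(
        cds_a=_codon.codons_to_str(a),
        cds_b=_codon.codons_to_str(b),
        n_syn_events=sa + sb,
        n_non_events=na + nb,
        syn_sites=syn_sites,
        non_sites=3.0 * ancestor_len_codons - syn_sites,
        saturated=p_expected >= 0.74,
    )


# ---------------------------------------------------------------------------
# stand-alone intron-site and quartet simulators (estimator-scale helpers)
# ---------------------------------------------------------------------------


def simulate_intron_sites(
    tree,
    gain_rate: float,
    loss_rate: float,
    n_sites: int,
    seed: int,
    *,
    condition_on_presence: bool = True,
    root_present_prob: "float | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a site x leaf presence matrix under the 2-state CTMC.

    Root states are present with probability ``root_present_prob``
    (default: the ancestrally intron-rich condition, 0.95 — intron site
    panels are dominated by positions that predate the family, which is
    exactly why loss can dominate gain in per-branch tallies; pass the
    stationary probability explicitly for an equilibrium simulation).
    With ``condition_on_presence`` sites absent from every leaf are
    rejected and redrawn (matching how intron site matrices are
    observed). Returns (matrix, per-edge true gain/loss event counts).
    """
    tree = load_dated_tree(tree)
    rng = np.random.default_rng(seed)
    q = gain_rate + loss_rate
    if q <= 0:
        raise ValueError("need gain_rate + loss_rate > 0")
    pi1 = root_present_prob if root_present_prob is not None else 0.95
    edge_list = edges(tree)
    counts = {(p, c): dict(gain=0, loss=0, parent_present=0, child_present=0) for p, c, _ in edge_list}
    rows = []
    attempts = 0
    while len(rows) < n_sites:
        attempts += 1
        if attempts > 200 * n_sites:
            raise RuntimeError("rejection sampling failed: sites never present at leaves")
        states = {tree.seed_node.label: int(rng.random() < pi1)}
        events = []
        for parent, child, t in edge_list:
            s = states[parent]
            # alternating exponential waits between gain/loss flips
            tau = 0.0
            while True:
                rate = loss_rate if s == 1 else gain_rate
                if rate <= 0:
                    break
                tau += rng.exponential(1.0 / rate)
                if tau >= t:
                    break
                events.append((parent, child, "loss" if s == 1 else "gain"))
                s = 1 - s
            states[child] = s
        leaf_states = {n.label: states[n.label] for n in tree.leaf_node_iter()}
        if condition_on_presence and not any(leaf_states.values()):
            continue
        rows.append(leaf_states)
        for parent, child, _ in edge_list:
            rec = counts[(parent, child)]
            rec["parent_present"] += states[parent]
            rec["child_present"] += states[child]
        for parent, child, kind in events:
            counts[(parent, child)][kind] += 1
    matrix = pd.DataFrame(rows, index=[f"site{i:05d}" for i in range(len(rows))])
    edge_truth = pd.DataFrame(
        [dict(parent=p, child=c, length_my=t, **counts[(p, c)]) for p, c, t in edge_list]
    )
    return matrix, edge_truth


def simulate_quartet(
    n_codons: int,
    t_dup_my: float,
    t_spec_my: float,
    seed: int,
    *,
    ks_per_my: float = 6.5e-3,
    ka_ks: float = 0.3,
    conversion: bool = False,
) -> dict[str, str]:
    """Simulate a WGD quartet: duplication at ``t_dup_my``, speciation at
    ``t_spec_my`` (both My before present, duplication older).

    With ``conversion`` the a2 paralog is overwritten by a1 halfway
    between speciation and the present (nonreciprocal homogenization),
    making the paralogs more similar to each other than to their
    orthologs.
    """
    if t_dup_my <= t_spec_my:
        raise ValueError("duplication must predate speciation")
    rng = np.random.default_rng(seed)
    lam_s = ks_per_my / 3.0
    lam_n = ks_per_my * ka_ks / 3.0
    anc = rng.integers(0, len(_codon.SENSE_CODONS), size=n_codons)
    seg = t_dup_my - t_spec_my
    p1, *_ = evolve_codons(anc, seg, lam_s, lam_n, rng)
    p2, *_ = evolve_codons(anc, seg, lam_s, lam_n, rng)
    if not conversion:
        a1, *_ = evolve_codons(p1, t_spec_my, lam_s, lam_n, rng)
        a2, *_ = evolve_codons(p2, t_spec_my, lam_s, lam_n, rng)
    else:
        t_conv = t_spec_my / 2.0
        a1_mid, *_ = evolve_codons(p1, t_spec_my - t_conv, lam_s, lam_n, rng)
        a1, *_ = evolve_codons(a1_mid, t_conv, lam_s, lam_n, rng)
        a2, *_ = evolve_codons(a1_mid.copy(), t_conv, lam_s, lam_n, rng)
    b1, *_ = evolve_codons(p1, t_spec_my, lam_s, lam_n, rng)
    b2, *_ = evolve_codons(p2, t_spec_my, lam_s, lam_n, rng)
    return dict(
        a1=_codon.codons_to_str(a1),
        a2=_codon.codons_to_str(a2),
        b1=_codon.codons_to_str(b1),
        b2=_codon.codons_to_str(b2),
    )


# ---------------------------------------------------------------------------
# full genome simulation
# ---------------------------------------------------------------------------


@dataclass
class _Gene:
    uid: int
    family: int
    codons: np.ndarray
    introns: dict[int, bool]  # site id -> present
    cum_syn: int = 0
    cum_non: int = 0

    def present_sites(self) -> list[int]:
        return [s for s, p in self.introns.items() if p]

    def clone(self, uid: int) -> "_Gene":
        return _Gene(
            uid=uid,
            family=self.family,
            codons=self.codons.copy(),
            introns=dict(self.introns),
            cum_syn=self.cum_syn,
            cum_non=self.cum_non,
        )


@dataclass
class TruthSet:
    duplication_events: pd.DataFrame
    intron_events: pd.DataFrame
    family_membership: pd.DataFrame
    ancestral_family_sizes: pd.DataFrame
    true_kaks: pd.DataFrame
    site_matrix: pd.DataFrame


@dataclass
class GenomeBundle:
    genome_id: str
    gene_df: pd.DataFrame  # gene_id, chrom, start, end, strand, intron_count, family, uid
    cds: dict[str, str]
    retro: pd.DataFrame
    chrom_lengths: dict[str, int]
    gff3_text: str
    genome_fasta: "str | None"
    n_decoys: int


@dataclass
class SimResult:
    config: SimConfig
    tree_newick: str
    bundles: dict[str, GenomeBundle]
    truth: TruthSet
    outdir: "Path | None" = None


class _Simulator:
    def __init__(self, config: SimConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.tree = load_dated_tree(config.tree_newick)
        self._uid = 0
        self._site = 0
        self.dup_records: list[dict] = []  # uid-level events
        self.intron_records: list[dict] = []
        self.node_family_sizes: dict[str, dict[int, int]] = {}
        self.height = self.tree.max_distance_from_root()
        self.node_age: dict[str, float] = {}
        self.node_age[self.tree.seed_node.label] = 0.0
        for p, c, t in edges(self.tree):
            self.node_age[c] = self.node_age[p] + t
        self.lam_s = config.ks_per_my / 3.0
        self.lam_n = config.ks_per_my * config.ka_ks_target / 3.0

    def next_uid(self) -> int:
        self._uid += 1
        return self._uid

    def next_site(self) -> int:
        self._site += 1
        return self._site

    # -- root genome ------------------------------------------------------

    def root_genome(self) -> list[list[_Gene]]:
        cfg, rng = self.cfg, self.rng
        chroms = []
        for _ in range(cfg.n_chromosomes):
            genes = []
            for _ in range(cfg.genes_per_chromosome):
                uid = self.next_uid()
                length = int(rng.integers(cfg.codon_length_range[0], cfg.codon_length_range[1] + 1))
                codons = rng.integers(0, len(_codon.SENSE_CODONS), size=length)
                n_introns = int(rng.poisson(cfg.root_intron_mean))
                introns = {self.next_site(): True for _ in range(n_introns)}
                genes.append(_Gene(uid=uid, family=uid, codons=codons, introns=introns))
            chroms.append(genes)
        for label, retention in cfg.wgd_events:
            if label == "root":
                chroms = self.apply_wgd(chroms, retention, time_my=self.height, edge="root")
        return chroms

    # -- WGD --------------------------------------------------------------

    def apply_wgd(
        self, chroms: list[list[_Gene]], retention: float, time_my: float, edge: str
    ) -> list[list[_Gene]]:
        rng = self.rng
        new_chroms = [list(c) for c in chroms]
        for c in chroms:
            copy_chrom = []
            for g in c:
                if rng.random() < retention:
                    child = g.clone(self.next_uid())
                    copy_chrom.append(child)
                    self.dup_records.append(
                        dict(
                            uid_a=g.uid,
                            uid_b=child.uid,
                            dup_type="WGD",
                            time_my=time_my,
                            edge=edge,
                            cum_syn=g.cum_syn,
                            cum_non=g.cum_non,
                        )
                    )
            if copy_chrom:
                new_chroms.append(copy_chrom)
        return new_chroms

    # -- per-edge evolution ----------------------------------------------

    def evolve_edge(
        self, chroms: list[list[_Gene]], parent_label: str, child_label: str, t: float
    ) -> list[list[_Gene]]:
        cfg, rng = self.cfg, self.rng
        age0 = self.node_age[parent_label]
        chroms = [[g.clone(g.uid) for g in c] for c in chroms]
        for label, retention in cfg.wgd_events:
            if label == child_label:
                chroms = self.apply_wgd(
                    chroms, retention, time_my=self.height - age0, edge=child_label
                )
        placements = []  # (kind, parent_uid, copy gene)
        dead: set[int] = set()
        rates = dict(
            TD=cfg.td_rate, PD=cfg.pd_rate, TRD=cfg.trd_rate, DSD=cfg.dsd_rate,
            LOSS=cfg.gene_loss_rate,
        )
        for chrom in chroms:
            for g in chrom:
                events = []
                for kind, rate in rates.items():
                    for _ in range(rng.poisson(rate * t)):
                        events.append((rng.uniform(0, t), kind))
                events.sort()
                prev = 0.0
                alive = True
                for tau, kind in events:
                    self._evolve_gene(g, tau - prev, child_label)
                    prev = tau
                    if kind == "LOSS":
                        dead.add(g.uid)
                        alive = False
                        break
                    child = g.clone(self.next_uid())
                    if kind == "TRD":
                        for site in list(child.introns):
                            if child.introns[site] and rng.random() < cfg.trd_intron_removal_prob:
                                child.introns[site] = False
                    self.dup_records.append(
                        dict(
                            uid_a=g.uid,
                            uid_b=child.uid,
                            dup_type=kind,
                            time_my=self.height - (age0 + tau),
                            edge=child_label,
                            cum_syn=g.cum_syn,
                            cum_non=g.cum_non,
                        )
                    )
                    self._evolve_gene(child, t - tau, child_label)
                    placements.append((kind, g.uid, child))
                if alive:
                    self._evolve_gene(g, t - prev, child_label)
        # remove dead genes
        chroms = [[g for g in c if g.uid not in dead] for c in chroms]
        # apply placements (positions re-resolved after each insertion)
        for kind, parent_uid, child in placements:
            pos = self._find(chroms, parent_uid)
            if pos is None:  # parent died after duplicating; place randomly
                kind = "DSD" if kind in ("TD", "PD") else kind
                self._insert_random(chroms, child)
                continue
            ci, gi = pos
            if kind == "TD":
                chroms[ci].insert(gi + 1, child)
            elif kind == "PD":
                offset = int(rng.integers(2, cfg.proximal_max_gap + 1))
                chroms[ci].insert(min(gi + offset, len(chroms[ci])), child)
            elif kind == "TRD":
                self._insert_random(chroms, child)
            else:  # DSD: copy elsewhere and relocate the source too
                self._insert_random(chroms, child)
                pos = self._find(chroms, parent_uid)
                ci, gi = pos
                src = chroms[ci].pop(gi)
                self._insert_random(chroms, src)
        chroms = [c for c in chroms if c]
        return chroms

    def _find(self, chroms, uid):
        for ci, c in enumerate(chroms):
            for gi, g in enumerate(c):
                if g.uid == uid:
                    return ci, gi
        return None

    def _insert_random(self, chroms, gene):
        ci = int(self.rng.integers(len(chroms)))
        gi = int(self.rng.integers(len(chroms[ci]) + 1))
        chroms[ci].insert(gi, gene)

    def _evolve_gene(self, g: _Gene, duration: float, edge_label: str) -> None:
        if duration <= 0:
            return
        g.codons, ns, nn = evolve_codons(g.codons, duration, self.lam_s, self.lam_n, self.rng)
        g.cum_syn += ns
        g.cum_non += nn
        cfg, rng = self.cfg, self.rng
        # per-site two-state gain/loss
        for site in list(g.introns):
            state = g.introns[site]
            tau = 0.0
            while True:
                rate = cfg.intron_loss_rate if state else cfg.intron_gain_rate
                if rate <= 0:
                    break
                tau += rng.exponential(1.0 / rate)
                if tau >= duration:
                    break
                state = not state
                self.intron_records.append(
                    dict(edge=edge_label, site_id=site, event="loss" if not state else "gain", uid=g.uid)
                )
            g.introns[site] = state
        # novel sites (gene-level gain process)
        if cfg.intron_gain_rate > 0:
            for _ in range(rng.poisson(cfg.intron_gain_rate * cfg.root_intron_mean * duration)):
                site = self.next_site()
                g.introns[site] = True
                self.intron_records.append(
                    dict(edge=edge_label, site_id=site, event="gain", uid=g.uid)
                )

    # -- traversal --------------------------------------------------------

    def run(self) -> dict[str, list[list[_Gene]]]:
        genomes: dict[str, list[list[_Gene]]] = {}
        root = self.tree.seed_node
        root_genome = self.root_genome()
        self._record_family_sizes(root.label, root_genome)
        stack = [(root, root_genome)]
        leaf_genomes: dict[str, list[list[_Gene]]] = {}
        while stack:
            node, genome = stack.pop()
            for child in node.child_nodes():
                child_genome = self.evolve_edge(genome, node.label, child.label, child.edge.length)
                self._record_family_sizes(child.label, child_genome)
                if child.is_leaf():
                    leaf_genomes[child.label] = child_genome
                else:
                    stack.append((child, child_genome))
        genomes.update(leaf_genomes)
        return genomes

    def _record_family_sizes(self, label: str, chroms) -> None:
        sizes: dict[int, int] = {}
        for c in chroms:
            for g in c:
                sizes[g.family] = sizes.get(g.family, 0) + 1
        self.node_family_sizes[label] = sizes


def plant_duplication_scenario(
    n_per_type: int = 50,
    seed: int = 0,
    *,
    n_chromosomes: int = 4,
    genes_per_chromosome: int = 100,
    t_split_my: float = 20.0,
    t_event_my: float = 2.0,
) -> tuple["GenomeBundle", "GenomeBundle", pd.DataFrame]:
    """Two-genome scenario with exactly ``n_per_type`` duplications per mode.

    A target genome and an outgroup diverge ``t_split_my`` My ago; at
    ``t_event_my`` My before present the target receives n WGD-retained
    pairs (whole-chromosome copies with exact retention) plus n tandem,
    proximal, transposed and dispersed duplications on distinct source
    genes. Returns (target bundle, outgroup bundle, truth pair table).
    """
    tree = f"(TargetA:{t_split_my},OutB:{t_split_my})R;"
    cfg = SimConfig(
        seed=seed,
        tree_newick=tree,
        n_chromosomes=n_chromosomes,
        genes_per_chromosome=genes_per_chromosome,
        wgd_events=(),
        td_rate=0.0, pd_rate=0.0, trd_rate=0.0, dsd_rate=0.0,
        gene_loss_rate=0.0,
        intron_gain_rate=0.0, intron_loss_rate=0.0,
    )
    sim = _Simulator(cfg)
    rng = sim.rng
    root = sim.root_genome()
    gen_b = sim.evolve_edge(root, "R", "OutB", t_split_my)
    gen_a = sim.evolve_edge(root, "R", "TargetA", t_split_my - t_event_my)
    chroms = [list(c) for c in gen_a]
    # single-copy sources for TD/PD/TRD/DSD live off the WGD chromosome so
    # every gene participates in at most one planted event pair
    all_idx = [(ci, gi) for ci, c in enumerate(gen_a) if ci != 0 for gi in range(len(c))]
    need = 4 * n_per_type
    if len(all_idx) < need:
        raise ValueError(f"need >= {need} non-WGD genes for {n_per_type} events per type")
    truth_rows = []
    # collinear duplication: one chromosome copied, retaining exactly
    # n_per_type copies (dense anchors, as WGD blocks survive erosion)
    if genes_per_chromosome < n_per_type:
        raise ValueError("genes_per_chromosome must be >= n_per_type")
    keep = set(rng.choice(genes_per_chromosome, size=n_per_type, replace=False))
    copy_chrom = []
    for gi, g in enumerate(gen_a[0]):
        if gi in keep:
            child = g.clone(sim.next_uid())
            copy_chrom.append(child)
            truth_rows.append((g.uid, child.uid, "WGD"))
    chroms.append(copy_chrom)
    # other events on distinct source genes; random placements go first so
    # tandem adjacency is established last and stays exact
    order = rng.permutation(len(all_idx))
    picks = order[: 4 * n_per_type]
    kinds = (["TRD"] * n_per_type + ["DSD"] * n_per_type
             + ["PD"] * n_per_type + ["TD"] * n_per_type)
    for k, kind in zip(picks, kinds):
        ci, gi = all_idx[k]
        src = gen_a[ci][gi]
        child = src.clone(sim.next_uid())
        if kind == "TRD":
            for site in list(child.introns):
                if child.introns[site] and rng.random() < cfg.trd_intron_removal_prob:
                    child.introns[site] = False
        truth_rows.append((src.uid, child.uid, kind))
        pos = sim._find(chroms, src.uid)
        cii, gii = pos
        if kind == "TD":
            chroms[cii].insert(gii + 1, child)
        elif kind == "PD":
            offset = int(rng.integers(2, 9))
            chroms[cii].insert(min(gii + offset, len(chroms[cii])), child)
        elif kind == "TRD":
            sim._insert_random(chroms, child)
        else:
            sim._insert_random(chroms, child)
            cii, gii = sim._find(chroms, src.uid)
            moved = chroms[cii].pop(gii)
            sim._insert_random(chroms, moved)
    for c in chroms:
        for g in c:
            sim._evolve_gene(g, t_event_my, "TargetA")
    bundle_a, uid_a, _ = _emit_leaf(sim, "TargetA", chroms, False)
    bundle_b, _, _ = _emit_leaf(sim, "OutB", gen_b, False)
    truth = pd.DataFrame(
        [
            dict(gene_a=uid_a[ua], gene_b=uid_a[ub], dup_type=t)
            for ua, ub, t in truth_rows
        ]
    )
    return bundle_a, bundle_b, truth


def plant_retro_scenario(
    n_per_class: int = 500,
    seed: int = 0,
    *,
    rho: float = 3.0,
    intergenic_gap_bp: int = 5000,
    gene_length_range: tuple[int, int] = (1000, 4000),
    n_chromosomes: int = 2,
    baseline_per_kb: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Gene coordinates plus retro intervals with rho-fold IG-flank enrichment.

    Lays ``n_per_class`` IGs and MEGs in random order along chromosomes
    and draws retro insertions from a piecewise-constant intensity:
    baseline everywhere, ``rho`` times baseline within 4 kb of IG bodies.
    Returns (gene table, retro BED-style frame, chromosome lengths).
    """
    cfg = SimConfig(
        seed=seed,
        retro_enrichment_factor=rho,
        retro_baseline_per_kb=baseline_per_kb,
        intergenic_gap_bp=intergenic_gap_bp,
    )
    rng = np.random.default_rng(seed)
    classes = np.array(["IG"] * n_per_class + ["MEG"] * n_per_class)
    rng.shuffle(classes)
    per_chrom = math.ceil(len(classes) / n_chromosomes)
    rows = []
    chrom_lengths: dict[str, int] = {}
    ig_zones: dict[str, list[tuple[int, int]]] = {}
    k = 0
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 0
        for _ in range(per_chrom):
            if k >= len(classes):
                break
            cls = classes[k]
            k += 1
            pos += intergenic_gap_bp
            length = int(rng.integers(*gene_length_range))
            start, end = pos + 1, pos + length
            pos = end
            rows.append(
                dict(
                    gene_id=f"g{k:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    gene_class=cls,
                    intron_count=0 if cls == "IG" else 3,
                )
            )
            if cls == "IG":
                ig_zones.setdefault(chrom, []).append(
                    (max(start - 1 - cfg.retro_flank_bp, 0), end + cfg.retro_flank_bp)
                )
        pos += intergenic_gap_bp
        chrom_lengths[chrom] = pos
    retro = _sample_retro(cfg, rng, chrom_lengths, ig_zones)
    return pd.DataFrame(rows), retro, chrom_lengths


# ---------------------------------------------------------------------------
# leaf emission (coordinates, decoys, retro, files)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _emit_leaf(
    sim: _Simulator, leaf: str, chroms: list[list[_Gene]], write_genome: bool
) -> tuple[GenomeBundle, dict[int, str], list[dict]]:
    """Lay a leaf genome onto coordinates and render GFF3/FASTA/BED text."""
    cfg, rng = sim.cfg, sim.rng
    gap = cfg.intergenic_gap_bp
    gene_rows: list[dict] = []
    gff: list[str] = ["##gff-version 3"]
    fasta_parts: list[tuple[str, str]] = []
    cds: dict[str, str] = {}
    uid_to_gid: dict[int, str] = {}
    chrom_lengths: dict[str, int] = {}
    ig_zones: dict[str, list[tuple[int, int]]] = {}
    idx = 0
    redundant: list[dict] = []
    for ci, chrom_genes in enumerate(chroms):
        chrom = f"chr{ci + 1}"
        pos = 0  # 0-based running coordinate
        seq_parts: list[str] = []
        for g in chrom_genes:
            idx += 1
            gid = f"{leaf}_g{idx:05d}"
            uid_to_gid[g.uid] = gid
            cds_seq = _codon.codons_to_str(g.codons)
            n_introns = len(g.present_sites())
            strand = "+" if rng.random() < 0.5 else "-"
            intron_lens = [
                int(rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1))
                for _ in range(n_introns)
            ]
            # split CDS into n+1 blocks at codon boundaries
            L = len(cds_seq)
            pool = np.arange(3, L - 2, 3)
            if n_introns and len(pool) >= n_introns:
                cuts = sorted(int(c) for c in rng.choice(pool, size=n_introns, replace=False))
            else:
                cuts = []
            n_introns = len(cuts)
            intron_lens = intron_lens[:n_introns]
            blocks = []
            prev = 0
            for cut in cuts:
                blocks.append(cds_seq[prev:cut])
                prev = cut
            blocks.append(cds_seq[prev:])
            body_parts = []
            exon_coords = []  # relative (start, end) 1-based within gene body
            cursor = 0
            for bi, block in enumerate(blocks):
                exon_coords.append((cursor + 1, cursor + len(block)))
                body_parts.append(block)
                cursor += len(block)
                if bi < len(intron_lens):
                    intron = "GT" + _random_seq(rng, max(intron_lens[bi] - 4, 0)) + "AG"
                    body_parts.append(intron)
                    cursor += len(intron)
            body = "".join(body_parts)
            if strand == "-":
                genome_body = _revcomp(body)
                body_len = len(body)
                exon_coords = [(body_len - e + 1, body_len - s + 1) for s, e in exon_coords][::-1]
            else:
                genome_body = body
            seq_parts.append(_random_seq(rng, gap))
            pos += gap
            gstart = pos + 1  # 1-based
            seq_parts.append(genome_body)
            pos += len(genome_body)
            gend = pos
            exons_abs = [(gstart + s - 1, gstart + e - 1) for s, e in exon_coords]
            _append_gene_gff(gff, chrom, gid, gstart, gend, strand, exons_abs)
            cds[gid] = cds_seq
            gene_rows.append(
                dict(
                    gene_id=gid,
                    chrom=chrom,
                    start=gstart,
                    end=gend,
                    strand=strand,
                    intron_count=n_introns,
                    family=f"fam{g.family:05d}",
                    uid=g.uid,
                    gene_class="IG" if n_introns == 0 else "MEG",
                )
            )
            if n_introns == 0:
                ig_zones.setdefault(chrom, []).append(
                    (max(gstart - 1 - cfg.retro_flank_bp, 0), gend + cfg.retro_flank_bp)
                )
            if rng.random() < cfg.redundant_record_fraction:
                redundant.append(dict(chrom=chrom, gid=gid, start=gstart, end=gend, strand=strand, exons=exons_abs))
        seq_parts.append(_random_seq(rng, gap))
        pos += gap
        chrom_lengths[chrom] = pos
        fasta_parts.append((chrom, "".join(seq_parts)))
    # redundant records (same locus, new id)
    for r in redundant:
        _append_gene_gff(gff, r["chrom"], r["gid"] + "R", r["start"], r["end"], r["strand"], r["exons"])
    # organellar decoys
    n_decoys = len(redundant)
    for contig, n_genes in zip(("MT", "PT"), cfg.n_organellar_genes):
        pos = 0
        seq_parts = []
        for k in range(n_genes):
            gid = f"{leaf}_{contig}_g{k + 1:02d}"
            length = int(rng.integers(cfg.codon_length_range[0], cfg.codon_length_range[1] + 1)) * 3
            seq_parts.append(_random_seq(rng, 200))
            pos += 200
            gstart = pos + 1
            block = _random_seq(rng, length)
            seq_parts.append(block)
            pos += length
            _append_gene_gff(gff, contig, gid, gstart, pos, "+", [(gstart, pos)])
            n_decoys += 1
        seq_parts.append(_random_seq(rng, 200))
        pos += 200
        chrom_lengths[contig] = pos
        fasta_parts.append((contig, "".join(seq_parts)))
    # unplaced scaffolds
    for k in range(cfg.n_unplaced_scaffolds):
        contig = f"scaffold_{k + 1}"
        gid = f"{leaf}_{contig}_g01"
        length = int(rng.integers(cfg.codon_length_range[0], cfg.codon_length_range[1] + 1)) * 3
        seq = _random_seq(rng, 200) + _random_seq(rng, length) + _random_seq(rng, 200)
        _append_gene_gff(gff, contig, gid, 201, 200 + length, "+", [(201, 200 + length)])
        n_decoys += 1
        chrom_lengths[contig] = len(seq)
        fasta_parts.append((contig, seq))
    retro = _sample_retro(cfg, rng, chrom_lengths, ig_zones)
    genome_fasta = _render_fasta(fasta_parts) if write_genome else None
    bundle = GenomeBundle(
        genome_id=leaf,
        gene_df=pd.DataFrame(gene_rows),
        cds=cds,
        retro=retro,
        chrom_lengths=chrom_lengths,
        gff3_text="\n".join(gff) + "\n",
        genome_fasta=genome_fasta,
        n_decoys=n_decoys,
    )
    return bundle, uid_to_gid, gene_rows


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def _append_gene_gff(gff, chrom, gid, start, end, strand, exons):
    phased = _cds_phases(exons, strand)
    gff.append(f"{chrom}\tigevo\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}")
    gff.append(f"{chrom}\tigevo\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={gid}.1;Parent={gid}")
    for (s, e), phase in phased:
        gff.append(f"{chrom}\tigevo\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={gid}.1")
    for (s, e), phase in phased:
        gff.append(f"{chrom}\tigevo\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\tID={gid}.1.cds;Parent={gid}.1")


def _cds_phases(exons, strand):
    ordered = exons if strand == "+" else exons[::-1]
    phases = []
    carried = 0
    for s, e in ordered:
        phases.append(((s, e), (3 - carried % 3) % 3))
        carried += e - s + 1
    out = dict(zip([c for c, _ in phases], [p for _, p in phases]))
    return [((s, e), out[(s, e)]) for s, e in exons]


def _sample_retro(cfg, rng, chrom_lengths, ig_zones) -> pd.DataFrame:
    rows = []
    lam_max = cfg.retro_baseline_per_kb / 1000.0 * max(1.0, cfg.retro_enrichment_factor)
    counter = 0
    for chrom, clen in chrom_lengths.items():
        if chrom.startswith(("MT", "PT", "scaffold")):
            continue
        zones = sorted(ig_zones.get(chrom, []))
        starts = np.sort(rng.uniform(0, clen, size=rng.poisson(lam_max * clen))).astype(int)
        if len(starts) == 0:
            continue
        zstarts = np.array([z[0] for z in zones]) if zones else np.empty(0)
        zends = np.array([z[1] for z in zones]) if zones else np.empty(0)
        for s in starts:
            in_zone = bool(zones) and bool(
                np.any((zstarts <= s) & (s < zends))
            )
            intensity = (
                cfg.retro_baseline_per_kb / 1000.0 * cfg.retro_enrichment_factor
                if in_zone
                else cfg.retro_baseline_per_kb / 1000.0
            )
            if rng.random() < intensity / lam_max:
                counter += 1
                length = int(rng.integers(cfg.retro_length_range[0], cfg.retro_length_range[1] + 1))
                rows.append(
                    dict(
                        chrom=chrom,
                        start=int(s),
                        end=min(int(s) + length, clen),
                        name=f"RT{counter:06d}",
                        score=0,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def _render_fasta(parts: list[tuple[str, str]], width: int = 80) -> str:
    out = []
    for name, seq in parts:
        out.append(f">{name}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
    return "\n".join(out) + "\n"


def simulate_dataset(
    config: SimConfig, outdir: "Path | str | None" = None, *, write_genome_fasta: bool = True
) -> SimResult:
    """Simulate the full multi-genome dataset with ground truth.

    When ``outdir`` is given, writes per-genome ``<genome>.gff3``,
    ``<genome>.cds.fa`` (and ``<genome>.genome.fa``), ``retro/<genome>.bed``,
    ``tree.nwk`` and ``truth/*.tsv`` under it.
    """
    sim = _Simulator(config)
    leaf_genomes = sim.run()
    # per-leaf bookkeeping for truth tables (cumulative events, site states)
    sim._leaf_cums = {}
    sim._leaf_sites = {}
    leaf_order = [n.label for n in sim.tree.leaf_node_iter()]
    for leaf in leaf_order:
        cums: dict[int, tuple] = {}
        sites: dict[int, int] = {}
        for c in leaf_genomes[leaf]:
            for g in c:
                syn_sites = float(_codon.SENSE_SYN_SITES[g.codons].sum())
                cums[g.uid] = (g.cum_syn, g.cum_non, syn_sites, 3 * len(g.codons) - syn_sites)
                for s, p in g.introns.items():
                    if p:
                        sites[s] = 1
                    else:
                        sites.setdefault(s, 0)
        sim._leaf_cums[leaf] = cums
        sim._leaf_sites[leaf] = sites
    # emit leaves in a fixed order for byte-identical reproducibility
    bundles: dict[str, GenomeBundle] = {}
    uid_maps: dict[str, dict[int, str]] = {}
    for leaf in leaf_order:
        bundle, uid_to_gid, _ = _emit_leaf(sim, leaf, leaf_genomes[leaf], write_genome_fasta)
        bundles[leaf] = bundle
        uid_maps[leaf] = uid_to_gid
    truth = _build_truth(sim, bundles, uid_maps)
    result = SimResult(
        config=config,
        tree_newick=config.tree_newick,
        bundles=bundles,
        truth=truth,
    )
    if outdir is not None:
        result.outdir = Path(outdir)
        _write_result(result)
    return result


def _build_truth(sim: _Simulator, bundles, uid_maps) -> TruthSet:
    cfg = sim.cfg
    dup_rows = []
    kaks_rows = []
    for leaf, bundle in bundles.items():
        uid_map = uid_maps[leaf]
        cums = sim._leaf_cums[leaf]
        for ev in sim.dup_records:
            ga, gb = uid_map.get(ev["uid_a"]), uid_map.get(ev["uid_b"])
            if ga is None or gb is None:
                continue
            dup_rows.append(
                dict(
                    genome=leaf,
                    gene_a=ga,
                    gene_b=gb,
                    dup_type=ev["dup_type"],
                    time_my=ev["time_my"],
                    edge=ev["edge"],
                )
            )
            # realized substitution events since the duplication
            ca, cb = cums[ev["uid_a"]], cums[ev["uid_b"]]
            syn_ev = (ca[0] - ev["cum_syn"]) + (cb[0] - ev["cum_syn"])
            non_ev = (ca[1] - ev["cum_non"]) + (cb[1] - ev["cum_non"])
            kaks_rows.append(
                dict(
                    genome=leaf,
                    gene_a=ga,
                    gene_b=gb,
                    true_ks=syn_ev / ca[2] if ca[2] else np.nan,
                    true_ka=non_ev / ca[3] if ca[3] else np.nan,
                )
            )
    fam_rows = []
    for leaf, bundle in bundles.items():
        for r in bundle.gene_df.itertuples():
            fam_rows.append(dict(genome=leaf, gene_id=r.gene_id, family=r.family))
    internal = [
        n.label for n in sim.tree.postorder_node_iter() if not n.is_leaf()
    ]
    families = sorted({f for sizes in sim.node_family_sizes.values() for f in sizes})
    anc = pd.DataFrame(0, index=[f"fam{f:05d}" for f in families], columns=internal, dtype=int)
    for label in internal:
        for f, n in sim.node_family_sizes[label].items():
            anc.at[f"fam{f:05d}", label] = n
    intron_df = pd.DataFrame(
        sim.intron_records, columns=["edge", "site_id", "event", "uid"]
    )
    site_matrix = _leaf_site_matrix(sim, bundles, uid_maps)
    return TruthSet(
        duplication_events=pd.DataFrame(
            dup_rows, columns=["genome", "gene_a", "gene_b", "dup_type", "time_my", "edge"]
        ),
        intron_events=intron_df,
        family_membership=pd.DataFrame(fam_rows, columns=["genome", "gene_id", "family"]),
        ancestral_family_sizes=anc,
        true_kaks=pd.DataFrame(kaks_rows, columns=["genome", "gene_a", "gene_b", "true_ks", "true_ka"]),
        site_matrix=site_matrix,
    )


def _leaf_site_matrix(sim, bundles, uid_maps) -> pd.DataFrame:
    presence: dict[int, dict[str, int]] = {}
    for leaf in bundles:
        for site, p in sim._leaf_sites[leaf].items():
            presence.setdefault(site, {})[leaf] = int(p)
    if not presence:
        return pd.DataFrame(columns=list(bundles))
    mat = pd.DataFrame.from_dict(presence, orient="index").fillna(0).astype(int)
    mat = mat.reindex(columns=list(bundles), fill_value=0)
    mat.index = [f"site{int(s):06d}" for s in mat.index]
    return mat.sort_index()


def _write_result(result: SimResult) -> None:
    out = result.outdir
    out.mkdir(parents=True, exist_ok=True)
    (out / "retro").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    (out / "tree.nwk").write_text(result.tree_newick + "\n")
    for leaf, b in result.bundles.items():
        (out / f"{leaf}.gff3").write_text(b.gff3_text)
        (out / f"{leaf}.cds.fa").write_text(_render_fasta(sorted(b.cds.items())))
        if b.genome_fasta is not None:
            (out / f"{leaf}.genome.fa").write_text(b.genome_fasta)
        b.retro.to_csv(out / "retro" / f"{leaf}.bed", sep="\t", header=False, index=False)
    t = result.truth
    t.duplication_events.to_csv(out / "truth" / "duplication_events.tsv", sep="\t", index=False)
    t.intron_events.to_csv(out / "truth" / "intron_events.tsv", sep="\t", index=False)
    t.family_membership.to_csv(out / "truth" / "family_membership.tsv", sep="\t", index=False)
    t.ancestral_family_sizes.to_csv(out / "truth" / "ancestral_family_sizes.tsv", sep="\t")
    t.true_kaks.to_csv(out / "truth" / "true_kaks.tsv", sep="\t", index=False)
    t.site_matrix.to_csv(out / "truth" / "site_matrix.tsv", sep="\t")
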