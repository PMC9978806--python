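"""IG/MEG calling filter chain, homology thresholds, families and pair sets."""

import numpy as np
import pandas as pd
import pytest

from igevo import annotation as ann


class TestGeneCalling:
    def test_toy_fixture_counts(self, toy_gff3):
        gt = ann.call_gene_classes(toy_gff3, genome_id="toy")
        counts = gt.counts
        assert counts["IG"] == 1
        assert counts["MEG"] == 1
        assert counts["EXCLUDED"] == 2
        assert counts["deduplicated"] == 1
        by_id = {g.gene_id: g for g in gt.genes}
        assert by_id["g1"].gene_class == "IG" and by_id["g1"].intron_count == 0
        assert by_id["g2"].gene_class == "MEG" and by_id["g2"].intron_count == 2
        assert by_id["g3"].exclusion_reason == "organellar"
        assert by_id["g4"].exclusion_reason == "unplaced"

    def test_class_partition(self, toy_gff3):
        gt = ann.call_gene_classes(toy_gff3)
        c = gt.counts
        assert c["IG"] + c["MEG"] + c["EXCLUDED"] == len(gt.genes)

    def test_representative_transcript_is_longest_cds(self, tmp_path):
        gff = tmp_path / "two_iso.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t1\t2000\t.\t+\t.\tID=gA\n"
            "chr1\tt\tmRNA\t1\t2000\t.\t+\t.\tID=gA.t1;Parent=gA\n"
            "chr1\tt\texon\t1\t300\t.\t+\t.\tParent=gA.t1\n"
            "chr1\tt\tCDS\t1\t300\t.\t+\t0\tID=c1;Parent=gA.t1\n"
            "chr1\tt\tmRNA\t1\t2000\t.\t+\t.\tID=gA.t2;Parent=gA\n"
            "chr1\tt\texon\t1\t450\t.\t+\t.\tParent=gA.t2\n"
            "chr1\tt\tCDS\t1\t450\t.\t+\t0\tID=c2;Parent=gA.t2\n"
        )
        gt = ann.call_gene_classes(str(gff))
        assert gt.genes[0].representative_transcript_id == "gA.t2"

    def test_no_cds_gff3_is_an_error(self, tmp_path):
        gff = tmp_path / "nocds.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t1\t300\t.\t+\t.\tID=gX\n"
            "chr1\tt\tmRNA\t1\t300\t.\t+\t.\tID=gX.t1;Parent=gX\n"
            "chr1\tt\texon\t1\t300\t.\t+\t.\tParent=gX.t1\n"
        )
        with pytest.raises(ValueError, match="no CDS"):
            ann.call_gene_classes(str(gff))

    def test_cds_outside_exons_excluded_as_malformed(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t1\t900\t.\t+\t.\tID=gB\n"
            "chr1\tt\tmRNA\t1\t900\t.\t+\t.\tID=gB.t1;Parent=gB\n"
            "chr1\tt\texon\t1\t300\t.\t+\t.\tParent=gB.t1\n"
            "chr1\tt\tCDS\t400\t900\t.\t+\t0\tID=cB;Parent=gB.t1\n"
        )
        gt = ann.call_gene_classes(str(gff))
        assert gt.genes[0].exclusion_reason == "malformed"

    def test_filter_chain_idempotent(self, toy_gff3, tmp_path):
        gt = ann.call_gene_classes(toy_gff3)
        keep = {g.gene_id for g in gt.genes if g.gene_class != "EXCLUDED"}
        lines = [
            ln
            for ln in open(toy_gff3).read().splitlines()
            if ln.startswith("#") or any(f"={gid}" in ln for gid in keep)
        ]
        survivors = tmp_path / "survivors.gff3"
        survivors.write_text("\n".join(lines) + "\n")
        gt2 = ann.call_gene_classes(str(survivors))
        assert gt2.counts["EXCLUDED"] == 0
        assert gt2.counts["deduplicated"] == 0
        assert {g.gene_id: g.gene_class for g in gt2.genes} == {
            g.gene_id: g.gene_class for g in gt.genes if g.gene_id in keep
        }


class TestHomology:
    def test_identical_sequences_retained(self):
        cds = {"a": "ATGGCT" * 50, "b": "ATGGCT" * 50}
        hom = ann.pairwise_cds_homology(cds)
        assert len(hom) == 1
        row = hom.iloc[0]
        assert row.identity == pytest.approx(1.0)
        assert row.coverage == pytest.approx(1.0)

    def test_sixty_percent_core_rejected_at_default_threshold(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 300)])
        # mutate 40% of positions
        b = list(a)
        for i in rng.choice(300, size=120, replace=False):
            b[i] = bases[(list(bases).index(b[i]) + 1) % 4]
        hom = ann.pairwise_cds_homology({"a": a, "b": "".join(b)}, min_shared_kmers=1)
        assert hom.empty

    def test_exact_prefix_full_coverage_of_shorter(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        full = "".join(bases[rng.integers(0, 4, 300)])
        hom = ann.pairwise_cds_homology({"full": full, "half": full[:150]})
        assert len(hom) == 1
        assert hom.iloc[0].coverage == pytest.approx(1.0)
        assert hom.iloc[0].identity == pytest.approx(1.0)

    def test_identity_symmetric(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 200)])
        b = list(a)
        for i in rng.choice(200, size=30, replace=False):
            b[i] = bases[(list(bases).index(b[i]) + 1) % 4]
        b = "".join(b)
        i1, c1 = ann.alignment_identity_coverage(a, b)
        i2, c2 = ann.alignment_identity_coverage(b, a)
        assert i1 == pytest.approx(i2, abs=1e-12)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            ann.pairwise_cds_homology({"a": "", "b": "ATG"})


class TestFamilies:
    def test_single_linkage_transitivity(self):
        hom = pd.DataFrame(
            dict(gene_a=["A", "B"], gene_b=["B", "C"], within_genome=[True, True])
        )
        fams = ann.cluster_paralog_families(hom, genes=["A", "B", "C", "D", "E"])
        assert fams["A"] == fams["B"] == fams["C"]
        assert fams["D"] != fams["E"]
        assert len({fams["A"], fams["D"], fams["E"]}) == 3

    def test_planted_family_recovered(self, small_sim):
        """A simulated family with several high-identity members clusters whole."""
        bundle = small_sim.bundles["Osat"]
        hom = ann.pairwise_cds_homology(bundle.cds)
        fams = ann.cluster_paralog_families(hom, genes=list(bundle.cds))
        truth = bundle.gene_df.groupby("family")["gene_id"].apply(list)
        big = [g for g in truth if len(g) >= 3]
        assert big, "simulation produced no multi-member families"
        recovered = 0
        for members in big:
            if len({fams[m] for m in members}) == 1:
                recovered += 1
        assert recovered / len(big) >= 0.7


class TestContextAndPairSets:
    @staticmethod
    def _table(classes, introns):
        genes = [
            ann.GeneModel(
                gene_id=g, chrom="chr1", strand="+", start=i * 1000 + 1,
                end=i * 1000 + 500, intron_count=introns[g], gene_class=classes[g],
            )
            for i, g in enumerate(classes)
        ]
        return ann.GeneTable(genome_id="t", genes=genes)

    def test_context_bins(self):
        classes = {"q": "IG", "p1": "IG", "p2": "IG", "m1": "MEG", "m2": "MEG", "m3": "MEG", "solo": "IG"}
        introns = {k: (0 if v == "IG" else 2) for k, v in classes.items()}
        gt = self._table(classes, introns)
        hom = pd.DataFrame(
            dict(
                gene_a=["p1", "p2", "m1", "m2", "m3"],
                gene_b=["q"] * 5,
                within_genome=[True] * 5,
            )
        )
        ctx = ann.classify_paralog_context(gt, hom).set_index("gene_id")
        assert ctx.loc["solo", "bin"] == "no_paralog"
        assert ctx.loc["q", "bin"] == "three_plus_ME"  # mixed case binned by ME count
        hom_ig_only = hom[hom.gene_a.isin(["p1", "p2"])]
        ctx2 = ann.classify_paralog_context(gt, hom_ig_only).set_index("gene_id")
        assert ctx2.loc["q", "bin"] == "intronless_only"
        hom_one = hom[hom.gene_a.isin(["p1", "m1"])]
        ctx3 = ann.classify_paralog_context(gt, hom_one).set_index("gene_id")
        assert ctx3.loc["q", "bin"] == "one_ME"

    def test_bins_partition_ig_set(self):
        classes = {"a": "IG", "b": "IG", "c": "MEG"}
        introns = {"a": 0, "b": 0, "c": 3}
        gt = self._table(classes, introns)
        hom = pd.DataFrame(dict(gene_a=["a"], gene_b=["b"], within_genome=[True]))
        ctx = ann.classify_paralog_context(gt, hom)
        assert len(ctx) == 2  # every IG binned exactly once
        pct = ann.context_bin_percentages(ctx)
        assert pct.sum() == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "ia,ib,expected_set,expected_sub,expected_same",
        [
            (0, 0, "intronless", None, "0"),
            (0, 2, "transition", "2", None),
            (4, 5, "multiexon", None, None),
            (0, 5, "transition", "3+", None),
            (1, 1, "multiexon", None, "1"),
            (3, 3, "multiexon", None, "3+"),
        ],
    )
    def test_pair_sets(self, ia, ib, expected_set, expected_sub, expected_same):
        classes = {"x": "IG" if ia == 0 else "MEG", "y": "IG" if ib == 0 else "MEG"}
        gt = self._table(classes, {"x": ia, "y": ib})
        hom = pd.DataFrame(dict(gene_a=["x"], gene_b=["y"], within_genome=[True]))
        ps = ann.build_pair_sets(gt, hom)
        row = ps.iloc[0]
        assert row.pair_set == expected_set
        assert (row.transition_sub if pd.notna(row.transition_sub) else None) == expected_sub
        assert (row.same_count if pd.notna(row.same_count) else None) == expected_same

    def test_pair_sets_partition(self, small_sim):
        bundle = small_sim.bundles["Zmay"]
        from igevo import annotation

        gt = annotation.GeneTable(
            genome_id="Zmay",
            genes=[
                annotation.GeneModel(
                    gene_id=r.gene_id, chrom=r.chrom, strand=r.strand,
                    start=r.start, end=r.end, intron_count=r.intron_count,
                    gene_class=r.gene_class,
                )
                for r in bundle.gene_df.itertuples()
            ],
        )
        hom = ann.pairwise_cds_homology(bundle.cds)
        ps = ann.build_pair_sets(gt, hom)
        assert (ps.pair_set.isin(["intronless", "transition", "multiexon"])).all()
        assert len(ps) == len(hom)
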