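"""Anchor chaining, the five-way classifier and the conversion bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from igevo import duplication as dup
from igevo import synthdata as sd


def _orders(n_a, n_b=None, chrom_a="c1", chrom_b="c2"):
    rows = {}
    for i in range(n_a):
        rows[f"a{i}"] = dict(chrom=chrom_a, order=i)
    for j in range(n_b if n_b is not None else 0):
        rows[f"b{j}"] = dict(chrom=chrom_b, order=j)
    return pd.DataFrame.from_dict(rows, orient="index")


def _anchors(pairs):
    return pd.DataFrame(
        dict(
            gene_a=[p[0] for p in pairs],
            gene_b=[p[1] for p in pairs],
            identity=1.0,
            coverage=1.0,
        )
    )


class TestChaining:
    def test_five_consecutive_anchors_one_block(self):
        orders = _orders(10, 10)
        anchors = _anchors([(f"a{i}", f"b{i}") for i in range(5)])
        blocks = dup.chain_collinear_blocks(anchors, orders)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 5
        assert blocks[0].orientation == "same"

    def test_reversed_partner_order_inverted_block(self):
        orders = _orders(10, 10)
        anchors = _anchors([(f"a{i}", f"b{4 - i}") for i in range(5)])
        blocks = dup.chain_collinear_blocks(anchors, orders)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_four_anchors_below_minimum(self):
        orders = _orders(10, 10)
        anchors = _anchors([(f"a{i}", f"b{i}") for i in range(4)])
        assert dup.chain_collinear_blocks(anchors, orders) == []

    def test_gap_limit_splits_chain(self):
        orders = _orders(100, 100)
        pairs = [(f"a{i}", f"b{i}") for i in range(5)]
        pairs += [(f"a{i + 40}", f"b{i + 40}") for i in range(5)]
        blocks = dup.chain_collinear_blocks(_anchors(pairs), orders)
        assert sorted(b.n_anchors for b in blocks) == [5, 5]

    def test_dp_chain_matches_bruteforce_on_small_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(25):
            n = int(rng.integers(4, 12))
            pts = [(int(rng.integers(0, 30)), int(rng.integers(0, 30)), k) for k in range(n)]
            max_gap = 25
            best_len = 0
            for r in range(1, n + 1):
                for sub in itertools.combinations(pts, r):
                    s = sorted(sub)
                    ok = all(
                        0 < s[k + 1][0] - s[k][0] <= max_gap
                        and 0 < s[k + 1][1] - s[k][1] <= max_gap
                        for k in range(len(s) - 1)
                    )
                    if ok:
                        best_len = max(best_len, r)
            got = dup._best_chain(pts, sign=1, max_gap=max_gap)
            assert len(got) == best_len


class TestClassifier:
    def _setup(self):
        rows = {f"g{i}": dict(chrom="c1", order=i) for i in range(40)}
        return pd.DataFrame.from_dict(rows, orient="index")

    def _classify(self, pairs, blocks=(), anchored=()):
        orders = self._setup()
        return dup.classify_duplication_types(
            _anchors(pairs), list(blocks), orders, set(anchored)
        )

    def test_adjacent_is_tandem(self):
        calls = self._classify([("g0", "g1")])
        assert calls.dup_type.iloc[0] == "TD"

    def test_proximal_thresholds(self):
        calls = self._classify([("g0", "g7"), ("g0", "g11")])
        assert list(calls.dup_type) == ["PD", "DSD"]

    def test_block_anchor_precedence_over_adjacency(self):
        block = dup.CollinearBlock("c1", "c1", "same", anchors=[("g0", "g1")])
        calls = self._classify([("g0", "g1")], blocks=[block])
        assert calls.dup_type.iloc[0] == "WGD"

    def test_transposed_requires_exactly_one_anchored(self):
        calls = self._classify([("g0", "g30")], anchored={"g0"})
        assert calls.dup_type.iloc[0] == "TRD"
        both = self._classify([("g0", "g30")], anchored={"g0", "g30"})
        assert both.dup_type.iloc[0] == "DSD"

    def test_unplaced_pair_becomes_dispersed(self):
        orders = self._setup()
        calls = dup.classify_duplication_types(
            _anchors([("g0", "missing")]), [], orders, set()
        )
        assert calls.dup_type.iloc[0] == "DSD"
        assert calls.evidence.iloc[0] == "unplaced"

    def test_every_pair_gets_exactly_one_type(self):
        rng = np.random.default_rng(1)
        pairs = [(f"g{a}", f"g{b}") for a, b in rng.integers(0, 40, size=(30, 2)) if a != b]
        calls = self._classify(pairs)
        assert calls.dup_type.isin(dup.DUP_TYPES).all()
        assert len(calls) == len(pairs)


class TestConversion:
    def test_equal_distances_not_converted(self):
        q = sd.simulate_quartet(300, 40, 20, seed=1, conversion=False)
        # degenerate check: all-identical sequences fail the strict inequality
        same = {k: q["a1"] for k in q}
        calls = dup.detect_gene_conversion(
            [dup.Quartet("a1", "a2", "b1", "b2")], same, {"a1": 0, "a2": 0},
            n_bootstrap=50, seed=0,
        )
        assert not calls.converted.iloc[0]

    def test_converted_quartet_high_support(self):
        q = sd.simulate_quartet(600, 45, 30, seed=5, conversion=True)
        calls = dup.detect_gene_conversion(
            [dup.Quartet("a1", "a2", "b1", "b2")], q, {"a1": 0, "a2": 3},
            n_bootstrap=500, seed=1,
        )
        row = calls.iloc[0]
        assert row.pair_class == "IG-MEG"
        assert row.converted
        assert row.bootstrap_support > 0.95

    def test_marginal_signal_small_n_low_support(self):
        """With few codons a borderline inequality cannot reach 95% support."""
        rng = np.random.default_rng(7)
        hits = []
        for s in range(8):
            q = sd.simulate_quartet(30, 22, 20, seed=100 + s, conversion=False)
            calls = dup.detect_gene_conversion(
                [dup.Quartet("a1", "a2", "b1", "b2")], q, {"a1": 0, "a2": 0},
                n_bootstrap=300, seed=int(rng.integers(1 << 30)),
            )
            if not calls.skipped.iloc[0]:
                hits.append(bool(calls.converted.iloc[0]))
        assert sum(hits) <= 1

    def test_rate_table_denominator(self):
        calls = pd.DataFrame(
            dict(
                pair_class=["IG-IG", "IG-IG", "MEG-MEG"],
                skipped=[False, False, True],
                converted=[True, False, False],
            )
        )
        table = dup.conversion_rate_table(calls).set_index("pair_class")
        assert table.loc["IG-IG", "conversion_rate"] == pytest.approx(0.5)
        assert table.loc["MEG-MEG", "n_skipped"] == 1


def test_quartet_construction_requires_distinct_orthologs():
    pairs = pd.DataFrame(dict(gene_a=["a1", "a3"], gene_b=["a2", "a4"]))
    rbh = pd.DataFrame(dict(gene_a=["a1", "a2", "a3", "a4"], gene_b=["b1", "b2", "b3", "b3"]))
    quartets = dup.build_quartets(pairs, rbh)
    assert len(quartets) == 1
    assert (quartets[0].a1, quartets[0].b2) == ("a1", "b2")
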