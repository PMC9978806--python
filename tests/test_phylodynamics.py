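"""Family flags, Sankoff reconstruction, flow tables and the gain/loss CTMC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from igevo import phylodynamics as pdyn
from igevo import synthdata as sd
from igevo._tree import load_dated_tree


class TestIGFamilyFlags:
    @staticmethod
    def _mats(total_per_sp, ig_per_sp, n_species=9):
        cols = [f"sp{i}" for i in range(n_species)]
        counts = pd.DataFrame([total_per_sp], index=["fam"], columns=cols[: len(total_per_sp)])
        counts = counts.reindex(columns=cols, fill_value=0)
        ig = pd.DataFrame([ig_per_sp], index=["fam"], columns=cols[: len(ig_per_sp)])
        ig = ig.reindex(columns=cols, fill_value=0)
        return counts, ig

    def test_sixty_percent_intronless_present_in_six_of_nine(self):
        counts, ig = self._mats([2, 2, 2, 2, 1, 1], [1, 1, 1, 1, 1, 1])
        assert pdyn.flag_ig_families(counts, ig).iloc[0]

    def test_eighty_percent_intronless_excluded_as_homogeneous(self):
        counts, ig = self._mats([2, 2, 2, 2, 1, 1], [2, 2, 2, 1, 1, 0])
        assert not pdyn.flag_ig_families(counts, ig).iloc[0]

    def test_presence_below_sixty_percent_excluded(self):
        counts, ig = self._mats([2, 2, 2, 2, 2], [1, 1, 1, 1, 2])
        assert not pdyn.flag_ig_families(counts, ig).iloc[0]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        cols = [f"sp{i}" for i in range(9)]
        counts = pd.DataFrame(rng.integers(0, 5, size=(40, 9)), columns=cols)
        ig = (counts * rng.random((40, 9))).round().astype(int).clip(upper=counts)
        base = pdyn.flag_ig_families(counts, ig, intronless_hi=0.70)
        wider = pdyn.flag_ig_families(counts, ig, intronless_hi=0.90)
        assert (wider | ~base).all()  # raising hi never removes a flag
        stricter = pdyn.flag_ig_families(counts, ig, species_presence=0.9)
        assert (base | ~stricter).all()  # raising presence never adds one


class TestSankoff:
    def test_worked_example(self):
        m = pd.DataFrame({"A": [3], "B": [1], "C": [1]}, index=["f"])
        out = pdyn.reconstruct_family_counts(m, "((A:1,B:1)AB:1,C:2)R;")
        assert out.loc["f", "AB"] == 1
        assert out.loc["f", "R"] == 1

    def test_constant_leaves_reconstruct_exactly(self):
        m = pd.DataFrame({"A": [4], "B": [4], "C": [4]}, index=["f"])
        out = pdyn.reconstruct_family_counts(m, "((A:1,B:1)AB:1,C:2)R;")
        assert (out.loc["f"] == 4).all()

    def test_absent_family_is_error(self):
        m = pd.DataFrame({"A": [0], "B": [0], "C": [0]}, index=["f"])
        with pytest.raises(ValueError, match="absent"):
            pdyn.reconstruct_family_counts(m, "((A:1,B:1)AB:1,C:2)R;")

    def test_matches_exhaustive_minimisation_on_five_leaf_trees(self):
        newick = "(((A:1,B:1)N1:1,(C:1,D:1)N2:1)N3:1,E:2)R;"
        tree = load_dated_tree(newick)
        rng = np.random.default_rng(1)
        leaves = ["A", "B", "C", "D", "E"]
        internals = ["N1", "N2", "N3", "R"]
        child_of = {"N1": ["A", "B"], "N2": ["C", "D"], "N3": ["N1", "N2"], "R": ["N3", "E"]}
        for _ in range(15):
            counts = {l: int(rng.integers(0, 4)) for l in leaves}
            if sum(counts.values()) == 0:
                continue
            smax = max(counts.values())
            best_cost = math.inf
            for assign in itertools.product(range(smax + 1), repeat=4):
                a = dict(zip(internals, assign))
                full = {**counts, **a}
                cost = sum(
                    abs(full[p] - full[c]) for p in child_of for c in child_of[p]
                )
                best_cost = min(best_cost, cost)
            m = pd.DataFrame({l: [counts[l]] for l in leaves}, index=["f"])
            out = pdyn.reconstruct_family_counts(m, newick)
            full = {**counts, **{n: int(out.loc["f", n]) for n in internals}}
            got_cost = sum(abs(full[p] - full[c]) for p in child_of for c in child_of[p])
            assert got_cost == best_cost

    def test_recovery_of_simulated_ancestral_sizes_loss_free(self):
        """With no gene loss, parsimony reconstructs the true ancestral
        family sizes exactly for >= 90% of families."""
        # low duplication rates: single events per edge dominate, so the
        # parsimony optimum coincides with the generating history
        cfg = sd.SimConfig(
            seed=23, n_chromosomes=2, genes_per_chromosome=40,
            gene_loss_rate=0.0, wgd_events=(),
            td_rate=5e-4, pd_rate=5e-4, dsd_rate=5e-4, trd_rate=1e-3,
        )
        res = sd.simulate_dataset(cfg)
        truth = res.truth.ancestral_family_sizes
        counts = {
            leaf: b.gene_df.groupby("family").size()
            for leaf, b in res.bundles.items()
        }
        m = pd.DataFrame(counts).fillna(0).astype(int)
        m = m[m.sum(axis=1) > 0]
        out = pdyn.reconstruct_family_counts(m, res.tree_newick)
        shared = m.index.intersection(truth.index)
        exact = sum(
            (out.loc[fam, truth.columns] == truth.loc[fam]).all() for fam in shared
        )
        assert exact / len(shared) >= 0.9


class TestEdgeDynamics:
    def test_fold_change_worked_example(self):
        fc = pdyn.fold_change([50, 42], [4, 1])
        assert fc == pytest.approx(18.4)
        assert round(fc) == 18

    def test_static_families_count_nothing(self):
        m = pd.DataFrame({"A": [2], "B": [2]}, index=["f"])
        nc = pdyn.reconstruct_family_counts(m, "(A:1,B:1)R;")
        summ = pdyn.summarize_edge_dynamics(nc, "(A:1,B:1)R;")
        assert (summ.n_expanded == 0).all()
        assert (summ.n_contracted == 0).all()

    def test_flow_conservation(self, small_sim):
        counts = {
            leaf: b.gene_df.groupby("family").size()
            for leaf, b in small_sim.bundles.items()
        }
        m = pd.DataFrame(counts).fillna(0).astype(int)
        nc = pdyn.reconstruct_family_counts(m, small_sim.tree_newick)
        summ = pdyn.summarize_edge_dynamics(nc, small_sim.tree_newick)
        assert (
            summ.parent_total + summ.gene_gain - summ.gene_loss == summ.child_total
        ).all()

    def test_planted_expansion_edge_has_max_tally(self):
        newick = "((A:1,B:1)AB:1,C:2)R;"
        rng = np.random.default_rng(3)
        fams = {}
        for i in range(30):
            base = int(rng.integers(1, 3))
            fams[f"f{i}"] = dict(A=base + 2, B=base + 2, C=base)  # expansion on AB edge
        m = pd.DataFrame(fams).T
        nc = pdyn.reconstruct_family_counts(m, newick)
        summ = pdyn.summarize_edge_dynamics(nc, newick).set_index("child")
        assert summ.loc["AB", "n_expanded"] == summ.n_expanded.max()


class TestGainLossModel:
    def test_single_edge_closed_form(self):
        m = 0.3
        t = 2.0
        p = pdyn.transition_matrix(0.0, m, t)
        assert p[1, 0] == pytest.approx(1 - math.exp(-m * t))
        assert p[0, 0] == 1.0

    def test_gain_loss_percent_worked_example(self):
        # parent sites {s1..s4}, child {s2,s3,s5}
        parent = np.array([1, 1, 1, 1, 0])
        child = np.array([0, 1, 1, 0, 1])
        rec = pdyn.gain_loss_percent(parent, child)
        assert rec["loss_pct"] == pytest.approx(50.0)
        assert rec["gain_pct"] == pytest.approx(100.0 / 3.0)

    def test_pruning_matches_bruteforce_enumeration(self):
        newick = "((A:1.5,B:0.7)N1:0.9,(C:1.1,D:0.4)N2:0.6)R;"
        tree = load_dated_tree(newick)
        g, m = 0.13, 0.42
        rng = np.random.default_rng(4)
        sites = pd.DataFrame(
            rng.integers(0, 2, size=(6, 4)), columns=["A", "B", "C", "D"]
        )
        sites = sites[sites.sum(axis=1) > 0]
        model = pdyn.IntronGainLossModel(sites, newick, ascertainment=False)
        ll = model.loglike(g, m)
        # brute force: sum over all internal-state combinations
        q = g + m
        pi = np.array([m / q, g / q])
        edges = {"A": ("N1", 1.5), "B": ("N1", 0.7), "C": ("N2", 1.1), "D": ("N2", 0.4),
                 "N1": ("R", 0.9), "N2": ("R", 0.6)}
        total = 0.0
        for _, row in sites.iterrows():
            site_p = 0.0
            for sN1, sN2, sR in itertools.product((0, 1), repeat=3):
                states = dict(row)
                states.update(N1=sN1, N2=sN2, R=sR)
                p = pi[sR]
                for child, (parent, t) in edges.items():
                    pt = pdyn.transition_matrix(g, m, t)
                    p *= pt[states[parent], states[child]]
                site_p += p
            total += math.log(site_p)
        assert ll == pytest.approx(total, rel=1e-10)

    def test_ascertainment_correction_normalises(self):
        newick = "(A:1,B:1)R;"
        sites = pd.DataFrame({"A": [1], "B": [0]})
        cond = pdyn.IntronGainLossModel(sites, newick, ascertainment=True)
        raw = pdyn.IntronGainLossModel(sites, newick, ascertainment=False)
        g, m = 0.2, 0.5
        l0 = raw._all_absent_likelihood(g, m, raw._root_prior(g, m))
        assert cond.loglike(g, m) == pytest.approx(
            raw.loglike(g, m) - math.log1p(-l0)
        )

    def test_loss_dominant_regime_recovered(self):
        mat, _ = sd.simulate_intron_sites(sd.DEFAULT_TREE, 0.001, 0.01, 400, seed=9)
        res = pdyn.estimate_intron_gain_loss(mat, sd.DEFAULT_TREE)
        ratio = res.loss_rate / res.gain_rate
        assert 3 < ratio < 30
        et = res.edge_table
        assert (et.loss_pct > et.gain_pct).mean() >= 0.8

    def test_summary_mentions_rates(self):
        mat, _ = sd.simulate_intron_sites("(A:10,B:10)R;", 0.002, 0.02, 60, seed=2)
        res = pdyn.estimate_intron_gain_loss(mat, "(A:10,B:10)R;")
        s = res.summary()
        assert "gain rate" in s and "loss rate" in s
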