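"""Gene-family dynamics on a dated tree and Markov intron gain/loss.

Three layers:

* IG-family flagging — a paralogous family counts as an *intronless-gene
  family* when 50-70% of its genes lack introns (the upper bound excludes
  families so homogeneous that the signal is uninformative) and the family
  is present in at least 60% of the species.
* Ancestral family sizes by Sankoff parsimony with linear |delta-count|
  cost, plus per-edge expansion/contraction tallies and the Sankey-style
  flow table with fold changes.
* A two-state continuous-time Markov model of intron presence/absence
  (gain rate g, loss rate m, per site per My) fitted by maximum likelihood
  with Felsenstein pruning, exposed as Model/Results objects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._tree import edges, load_dated_tree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# IG-family flagging
# ---------------------------------------------------------------------------


def flag_ig_families(
    counts: pd.DataFrame,
    intronless_counts: pd.DataFrame,
    *,
    intronless_lo: float = 0.50,
    intronless_hi: float = 0.70,
    species_presence: float = 0.60,
    per_genome: bool = False,
) -> pd.Series:
    """Flag families as intronless-gene (IG) families.

    Parameters
    ----------
    counts, intronless_counts
        family x genome integer matrices: total genes and intronless genes.
    per_genome
        Default pools genes over all species before applying the 50-70%
        rule; ``per_genome=True`` instead requires the rule to hold in a
        majority of the genomes where the family is present.
    """
    counts = counts.astype(int)
    intronless_counts = intronless_counts.reindex_like(counts).fillna(0).astype(int)
    n_species = counts.shape[1]
    need_present = math.ceil(species_presence * n_species)
    present = (counts > 0).sum(axis=1)
    if per_genome:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = intronless_counts / counts.replace(0, np.nan)
        ok = ((frac >= intronless_lo) & (frac <= intronless_hi)).sum(axis=1)
        rule = ok * 2 > present
    else:
        tot = counts.sum(axis=1)
        pooled = intronless_counts.sum(axis=1) / tot.replace(0, np.nan)
        rule = (pooled >= intronless_lo) & (pooled <= intronless_hi)
    return (rule & (present >= need_present)).fillna(False)


# ---------------------------------------------------------------------------
# Sankoff parsimony over integer family sizes
# ---------------------------------------------------------------------------


def _sankoff_one(tree: dendropy.Tree, leaf_counts: dict[str, int]) -> dict[str, int]:
    smax = max(leaf_counts.values())
    states = np.arange(smax + 1)
    delta = np.abs(states[:, None] - states[None, :])  # cost matrix
    cost: dict[str, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = np.full(smax + 1, np.inf)
            c[leaf_counts[node.label]] = 0.0
        else:
            c = np.zeros(smax + 1)
            for child in node.child_nodes():
                # min over child state of (child cost + |parent - child|)
                c = c + np.min(cost[child.label][None, :] + delta, axis=1)
        cost[node.label] = c
    assign: dict[str, int] = {}
    root = tree.seed_node
    # tie-break: smallest count in the optimal set (argmin returns first min)
    assign[root.label] = int(np.argmin(cost[root.label]))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = assign[node.parent_node.label]
        assign[node.label] = int(
            np.argmin(cost[node.label] + np.abs(states - parent_state))
        )
    return assign


def reconstruct_family_counts(
    matrix: pd.DataFrame, tree: "dendropy.Tree | str"
) -> pd.DataFrame:
    """Ancestral integer family sizes by Sankoff parsimony.

    ``matrix`` is family x leaf. Returns family x node (leaves + internal)
    counts; ancestral counts minimize total |delta| change, ties resolved
    to the smallest count.
    """
    tree = load_dated_tree(tree)
    leaves = [n.label for n in tree.leaf_node_iter()]
    missing = set(leaves) - set(matrix.columns)
    if missing:
        raise ValueError(f"count matrix lacks leaf columns: {sorted(missing)}")
    all_nodes = [n.label for n in tree.postorder_node_iter()]
    out = pd.DataFrame(0, index=matrix.index, columns=all_nodes, dtype=int)
    for fam, row in matrix.iterrows():
        leaf_counts = {l: int(row[l]) for l in leaves}
        if sum(leaf_counts.values()) == 0:
            raise ValueError(f"family {fam!r} absent from every leaf")
        assign = _sankoff_one(tree, leaf_counts)
        for node, s in assign.items():
            out.at[fam, node] = s
    return out


def summarize_edge_dynamics(
    node_counts: pd.DataFrame,
    tree: "dendropy.Tree | str",
    family_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-edge expansion/contraction tallies and the Sankey flow table.

    One row per tree edge with the number of expanded / contracted
    families, summed gene gains and losses, node totals and the fold
    change of child vs parent summed counts. Flow conservation holds by
    construction: parent_total + gains - losses = child_total.
    """
    tree = load_dated_tree(tree)
    if family_flags is not None:
        node_counts = node_counts.loc[family_flags.reindex(node_counts.index, fill_value=False)]
    rows = []
    for parent, child, length in edges(tree):
        pc = node_counts[parent]
        cc = node_counts[child]
        diff = cc - pc
        parent_total = int(pc.sum())
        child_total = int(cc.sum())
        fold = child_total / parent_total if parent_total > 0 else np.nan
        if parent_total == 0:
            logger.warning("edge %s->%s: parent total 0, fold change undefined", parent, child)
        rows.append(
            dict(
                parent=parent,
                child=child,
                length_my=length,
                n_expanded=int((diff > 0).sum()),
                n_contracted=int((diff < 0).sum()),
                gene_gain=int(diff[diff > 0].sum()),
                gene_loss=int(-diff[diff < 0].sum()),
                parent_total=parent_total,
                child_total=child_total,
                fold_change=fold,
            )
        )
    return pd.DataFrame(rows)


def fold_change(child_counts, parent_counts) -> float:
    """Summed child counts over summed parent counts (Sankey fold change)."""
    child = float(np.sum(child_counts))
    parent = float(np.sum(parent_counts))
    if parent <= 0:
        return math.nan
    return child / parent


# ---------------------------------------------------------------------------
# two-state CTMC intron gain/loss model
# ---------------------------------------------------------------------------


def gain_loss_percent(parent_states: np.ndarray, child_states: np.ndarray) -> dict:
    """Per-edge gain/loss tallies from known parent/child site states.

    Loss% = 100 * (sites 1->0) / (sites present at the parent);
    Gain% = 100 * (sites 0->1) / (sites present at the child).
    """
    ps = np.asarray(parent_states)
    cs = np.asarray(child_states)
    losses = int(((ps == 1) & (cs == 0)).sum())
    gains = int(((ps == 0) & (cs == 1)).sum())
    parent_present = int((ps == 1).sum())
    child_present = int((cs == 1).sum())
    return dict(
        n_gain=gains,
        n_loss=losses,
        gain_pct=100.0 * gains / child_present if child_present else 0.0,
        loss_pct=100.0 * losses / parent_present if parent_present else 0.0,
    )


def transition_matrix(gain: float, loss: float, t: float) -> np.ndarray:
    """P(t) of the 2-state chain, states (0=absent, 1=present)."""
    q = gain + loss
    if q == 0:
        return np.eye(2)
    e = math.exp(-q * t)
    p01 = gain / q * (1 - e)
    p10 = loss / q * (1 - e)
    return np.array([[1 - p01, p01], [p10, 1 - p10]])


class IntronGainLossModel:
    """Markov model of intron presence/absence along a dated tree.

    Parameters
    ----------
    site_matrix
        site x leaf DataFrame with entries 0 (absent), 1 (present) or
        NaN/'?' (unknown). Sites are assumed observed only when present
        in at least one leaf, so the default likelihood conditions on the
        pattern not being all-absent (ascertainment correction).
    tree
        rooted dated tree (dendropy Tree or newick).
    root_prior
        "estimated" (default) fits the root presence probability as a
        free parameter: intron site panels are typically far from the
        chain's stationary state (ancestrally intron-rich, decaying), and
        under a stationary root the expected per-branch gain and loss
        fluxes balance exactly, hiding loss dominance. "stationary" pins
        the root at (m/(g+m), g/(g+m)).
    """

    def __init__(
        self,
        site_matrix: pd.DataFrame,
        tree,
        *,
        ascertainment: bool = True,
        root_prior: str = "estimated",
    ):
        if root_prior not in ("estimated", "stationary"):
            raise ValueError("root_prior must be 'estimated' or 'stationary'")
        self.root_prior_mode = root_prior
        self.root_present_prob: float | None = None
        self.tree = load_dated_tree(tree)
        self.leaves = [n.label for n in self.tree.leaf_node_iter()]
        missing = set(self.leaves) - set(site_matrix.columns)
        if missing:
            raise ValueError(f"site matrix lacks leaf columns: {sorted(missing)}")
        m = site_matrix[self.leaves].replace("?", np.nan).astype(float)
        if len(m) == 0:
            raise ValueError("need at least one site")
        self.sites = m
        self.ascertainment = ascertainment
        self._nodes = list(self.tree.postorder_node_iter())

    # -- likelihood -------------------------------------------------------

    def _partials(self, gain: float, loss: float) -> dict[str, np.ndarray]:
        """Post-order conditional likelihood arrays, (n_sites, 2) per node."""
        n = len(self.sites)
        partial: dict[str, np.ndarray] = {}
        for node in self._nodes:
            if node.is_leaf():
                obs = self.sites[node.label].to_numpy()
                p = np.ones((n, 2))
                p[obs == 0, 1] = 0.0
                p[obs == 1, 0] = 0.0
                partial[node.label] = p
            else:
                p = np.ones((n, 2))
                for child in node.child_nodes():
                    pt = transition_matrix(gain, loss, child.edge.length)
                    p *= partial[child.label] @ pt.T
                partial[node.label] = p
        return partial

    def loglike(self, gain: float, loss: float, root_p1: "float | None" = None) -> float:
        """Log-likelihood at (g, m), ascertainment-corrected if configured.

        ``root_p1`` overrides the root presence probability; by default
        the stationary value is used (the "stationary" prior, and the
        starting point of the "estimated" fit).
        """
        if gain < 0 or loss < 0 or gain + loss == 0:
            return -np.inf
        prior = self._root_prior(gain, loss, root_p1)
        partial = self._partials(gain, loss)
        site_l = partial[self.tree.seed_node.label] @ prior
        if np.any(site_l <= 0):
            return -np.inf
        ll = float(np.log(site_l).sum())
        if self.ascertainment:
            l_absent = self._all_absent_likelihood(gain, loss, prior)
            if l_absent >= 1.0:
                return -np.inf
            ll -= len(self.sites) * math.log1p(-l_absent)
        return ll

    def _root_prior(
        self, gain: float, loss: float, root_p1: "float | None" = None
    ) -> np.ndarray:
        if root_p1 is None:
            root_p1 = self.root_present_prob
        if root_p1 is None:
            q = gain + loss
            root_p1 = gain / q
        return np.array([1.0 - root_p1, root_p1])

    def _all_absent_likelihood(self, gain, loss, prior) -> float:
        lk: dict[str, np.ndarray] = {}
        for node in self._nodes:
            if node.is_leaf():
                lk[node.label] = np.array([1.0, 0.0])
            else:
                p = np.ones(2)
                for child in node.child_nodes():
                    pt = transition_matrix(gain, loss, child.edge.length)
                    p *= pt @ lk[child.label]
                lk[node.label] = p
        return float(lk[self.tree.seed_node.label] @ prior)

    # -- fitting ----------------------------------------------------------

    def fit(self, x0: tuple[float, float] | None = None) -> "IntronGainLossResults":
        """Maximize the likelihood over the gain/loss rates (and, in the
        default "estimated" mode, the root presence probability)."""
        if x0 is None:
            depth = self.tree.max_distance_from_root() or 1.0
            x0 = (0.1 / depth, 1.0 / depth)
        estimate_root = self.root_prior_mode == "estimated"

        def nll(x):
            g, m = math.exp(x[0]), math.exp(x[1])
            p1 = 1.0 / (1.0 + math.exp(-x[2])) if estimate_root else None
            return -self.loglike(g, m, p1)

        start = list(np.log(x0)) + ([0.0] if estimate_root else [])
        res = minimize(
            nll,
            start,
            method="Nelder-Mead",
            options=dict(xatol=1e-6, fatol=1e-8, maxiter=4000),
        )
        if not res.success:
            raise RuntimeError(
                f"intron gain/loss ML did not converge: {res.message}; "
                f"last iterate={res.x}"
            )
        gain, loss = (float(v) for v in np.exp(res.x[:2]))
        if estimate_root:
            self.root_present_prob = float(1.0 / (1.0 + math.exp(-res.x[2])))
        if loss < 1e-12:
            logger.warning("estimated loss rate ~ 0 (all sites invariant-present?)")
        return IntronGainLossResults(self, gain, loss, -res.fun)


@dataclass
class IntronGainLossResults:
    """Fitted intron gain/loss rates plus per-edge Gain%/Loss% tallies."""

    model: IntronGainLossModel
    gain_rate: float
    loss_rate: float
    loglike: float

    def __post_init__(self):
        self.ancestral_states = self._joint_ml_states()
        self.edge_table = self._edge_table()

    # joint max-likelihood ancestral states (Viterbi-style max-product)
    def _joint_ml_states(self) -> pd.DataFrame:
        g, m, tree = self.gain_rate, self.loss_rate, self.model.tree
        sites = self.model.sites
        n = len(sites)
        prior = np.log(self.model._root_prior(g, m))
        best: dict[str, np.ndarray] = {}
        back: dict[str, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                obs = sites[node.label].to_numpy()
                b = np.zeros((n, 2))
                b[obs == 0, 1] = -np.inf
                b[obs == 1, 0] = -np.inf
                best[node.label] = b
            else:
                b = np.zeros((n, 2))
                for child in node.child_nodes():
                    logp = np.log(transition_matrix(g, m, child.edge.length))
                    # scores[site, parent_state, child_state]
                    scores = logp[None, :, :] + best[child.label][:, None, :]
                    back[child.label] = np.argmax(scores, axis=2)
                    b += np.max(scores, axis=2)
                best[node.label] = b
        states = pd.DataFrame(index=sites.index, columns=[nd.label for nd in tree.preorder_node_iter()], dtype=int)
        root = tree.seed_node
        states[root.label] = np.argmax(best[root.label] + prior[None, :], axis=1)
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            parent_states = states[node.parent_node.label].to_numpy()
            states[node.label] = back[node.label][np.arange(n), parent_states]
        return states

    def _edge_table(self) -> pd.DataFrame:
        rows = []
        st = self.ancestral_states
        for parent, child, length in edges(self.model.tree):
            rec = gain_loss_percent(st[parent].to_numpy(), st[child].to_numpy())
            rows.append(dict(parent=parent, child=child, length_my=length, **rec))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Two-state intron gain/loss model (CTMC, ML via pruning)",
            f"  sites: {len(self.model.sites)}   leaves: {len(self.model.leaves)}",
            f"  gain rate g = {self.gain_rate:.6g} /site/My",
            f"  loss rate m = {self.loss_rate:.6g} /site/My",
            f"  loss/gain ratio = {self.loss_rate / self.gain_rate:.3g}"
            if self.gain_rate > 0
            else "  loss/gain ratio = inf",
            f"  log-likelihood = {self.loglike:.4f}"
            + ("  (ascertainment-corrected)" if self.model.ascertainment else ""),
            f"  root P(present) = {self.model.root_present_prob:.3f} (estimated)"
            if self.model.root_present_prob is not None
            else "  root prior: stationary",
            "",
            self.edge_table.to_string(index=False),
        ]
        return "\n".join(lines)


def estimate_intron_gain_loss(
    sites: pd.DataFrame,
    tree,
    *,
    ascertainment: bool = True,
    root_prior: str = "estimated",
) -> IntronGainLossResults:
    """Functional wrapper: fit the gain/loss model and return results."""
    return IntronGainLossModel(
        sites, tree, ascertainment=ascertainment, root_prior=root_prior
    ).fit()
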