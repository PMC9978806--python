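"""Nei–Gojobori (NG86) Ka/Ks estimation and divergence-time conversion.

The estimator follows the classic unweighted recipe: per-codon synonymous
site fractions averaged over the two sequences, differences counted by
equal-weight averaging over all minimal mutational pathways between
differing codons (pathways through stop codons excluded), and a
Jukes–Cantor multiple-hit correction applied to the proportions.

Divergence times use T = Ks / (2 r) with a neutral substitution rate of
r = 6.5e-9 substitutions per site per year by default, reported in
million years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import _codon
from .stats import rank_sum, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

SATURATION_P = 0.75  # Jukes-Cantor correction undefined at p >= 3/4


@dataclass(frozen=True)
class EvolConstants:
    """Molecular-clock constants.

    r : neutral substitution rate per site per year (default 6.5e-9,
        the grass nuclear rate commonly used for Ks dating).
    """

    r: float = 6.5e-9

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("neutral rate r must be positive")


@dataclass
class KaKsResult:
    """NG86 site/difference counts and corrected rates for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float  # NaN when saturated
    ka: float
    ratio: float  # Ka/Ks; NaN when undefined
    n_codons: int
    n_codons_dropped: int = 0
    saturated_s: bool = False
    saturated_n: bool = False
    undefined_ratio: bool = False
    # per-codon contributions, kept for codon-bootstrap resampling
    per_codon: pd.DataFrame | None = field(default=None, repr=False)


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); NaN at/after saturation."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= SATURATION_P:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _codon_pair_contributions(idx_a: np.ndarray, idx_b: np.ndarray) -> pd.DataFrame:
    """Per-codon (s_sites, n_sites, sd, nd) table; stop-blocked codons dropped."""
    rows = []
    dropped = 0
    for ia, ib in zip(idx_a, idx_b):
        ca, cb = _codon.SENSE_CODONS[ia], _codon.SENSE_CODONS[ib]
        diffs = _codon.pathway_differences(ca, cb)
        if diffs is None:
            dropped += 1
            continue
        s_sites = 0.5 * (_codon.SENSE_SYN_SITES[ia] + _codon.SENSE_SYN_SITES[ib])
        rows.append((s_sites, 3.0 - s_sites, diffs[0], diffs[1]))
    df = pd.DataFrame(rows, columns=["s_sites", "n_sites", "sd", "nd"])
    df.attrs["n_dropped"] = dropped
    return df


def kaks_from_contributions(per_codon: pd.DataFrame) -> KaKsResult:
    """Assemble a :class:`KaKsResult` from per-codon contribution rows."""
    if len(per_codon) == 0:
        raise ValueError("no scorable codons (all dropped)")
    S = float(per_codon["s_sites"].sum())
    N = float(per_codon["n_sites"].sum())
    Sd = float(per_codon["sd"].sum())
    Nd = float(per_codon["nd"].sum())
    ps = Sd / S
    pn = Nd / N
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated_s = math.isnan(ks)
    saturated_n = math.isnan(ka)
    undefined = saturated_s or saturated_n or ks == 0.0
    ratio = ka / ks if not undefined else math.nan
    return KaKsResult(
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        ratio=ratio,
        n_codons=len(per_codon),
        n_codons_dropped=per_codon.attrs.get("n_dropped", 0),
        saturated_s=saturated_s,
        saturated_n=saturated_n,
        undefined_ratio=undefined,
        per_codon=per_codon,
    )


def kaks_ng86(cds_a: str, cds_b: str, *, aligned: bool | None = None) -> KaKsResult:
    """NG86 Ka/Ks for a pair of coding sequences.

    Unaligned sequences (or sequences of unequal length) are first put
    through the protein-guided codon aligner; codon columns containing a
    gap or a stop are dropped in codon units.
    """
    if not cds_a or not cds_b:
        raise ValueError("empty CDS")
    if aligned is None:
        aligned = len(cds_a) == len(cds_b)
    if not aligned or len(cds_a) != len(cds_b):
        cds_a, cds_b = align_codons(cds_a, cds_b)
    if len(cds_a) % 3 or len(cds_b) % 3:
        raise ValueError("aligned CDS length not divisible by 3")
    idx_a, idx_b = _gapped_to_indices(cds_a, cds_b)
    if idx_a.size == 0:
        raise ValueError("no codons left after dropping gapped/stop columns")
    per_codon = _codon_pair_contributions(idx_a, idx_b)
    return kaks_from_contributions(per_codon)


def _gapped_to_indices(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = [], []
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3].upper(), b[k : k + 3].upper()
        if ca in _codon.SENSE_INDEX and cb in _codon.SENSE_INDEX:
            ia.append(_codon.SENSE_INDEX[ca])
            ib.append(_codon.SENSE_INDEX[cb])
    return np.array(ia, dtype=np.int64), np.array(ib, dtype=np.int64)


# ---------------------------------------------------------------------------
# codon-aware alignment: protein-level global alignment back-threaded to nt
# ---------------------------------------------------------------------------

_protein_aligner = Align.PairwiseAligner()
_protein_aligner.mode = "global"
_protein_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_protein_aligner.open_gap_score = -10.0
_protein_aligner.extend_gap_score = -0.5


def _translate(cds: str) -> str:
    prot = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        prot.append(_codon.AA.get(cds[i : i + 3].upper(), "X"))
    return "".join(prot)


def align_codons(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment (protein alignment threaded back).

    Returns two equal-length gapped nucleotide strings whose length is a
    multiple of 3; every gap run is a whole number of codons.
    """
    prot_a = _translate(cds_a).replace("*", "X")
    prot_b = _translate(cds_b).replace("*", "X")
    if not prot_a or not prot_b:
        raise ValueError("CDS shorter than one codon")
    aln = _protein_aligner.align(prot_a, prot_b)[0]
    out_a, out_b = [], []
    pa = pb = 0
    for col_a, col_b in zip(aln[0], aln[1]):
        if col_a == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * pa : 3 * pa + 3])
            pa += 1
        if col_b == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * pb : 3 * pb + 3])
            pb += 1
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# divergence time and group summaries
# ---------------------------------------------------------------------------


def divergence_time(ks: float, constants: EvolConstants = EvolConstants()) -> float:
    """Divergence time T = Ks / (2 r), in million years.

    Saturated (NaN) Ks propagates as NaN rather than a number.
    """
    if math.isnan(ks):
        return math.nan
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    return ks / (2.0 * constants.r) / 1e6


def _bootstrap_ci_median(
    values: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    meds = np.median(values[idx], axis=1)
    return float(np.quantile(meds, 0.025)), float(np.quantile(meds, 0.975))


def summarize_kaks_by_group(
    table: pd.DataFrame,
    group_cols: list[str],
    value_col: str = "ks",
    *,
    compare_col: str | None = None,
    paired: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median/IQR/95% bootstrap CI of a Ka/Ks quantity per group.

    ``table`` holds one row per pair; NaN (saturated/undefined) values are
    excluded and counted. If ``compare_col`` names a binary column (e.g.
    IG-vs-MEG membership), a two-group rank test is run within each level
    of ``group_cols`` and reported as ``p_value`` (rank-sum for unpaired
    groups; exact signed-rank when ``paired`` and sizes match).
    """
    rows = []
    for key, sub in table.groupby(group_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        vals = sub[value_col].to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        row = dict(zip(group_cols, key))
        row["n"] = len(defined)
        row["n_undefined"] = int(np.isnan(vals).sum())
        if len(defined) == 0:
            row.update(median=np.nan, q25=np.nan, q75=np.nan, ci_lo=np.nan, ci_hi=np.nan)
        else:
            row["median"] = float(np.median(defined))
            row["q25"] = float(np.quantile(defined, 0.25))
            row["q75"] = float(np.quantile(defined, 0.75))
            lo, hi = _bootstrap_ci_median(defined, n_boot=n_boot, seed=seed)
            row["ci_lo"], row["ci_hi"] = lo, hi
        if compare_col is not None and compare_col in sub:
            levels = sorted(sub[compare_col].dropna().unique())
            if len(levels) == 2:
                a = sub.loc[sub[compare_col] == levels[0], value_col].dropna().to_numpy()
                b = sub.loc[sub[compare_col] == levels[1], value_col].dropna().to_numpy()
                if len(a) and len(b):
                    if paired and len(a) == len(b):
                        res = wilcoxon_signed_rank(np.asarray(a) - np.asarray(b))
                    else:
                        res = rank_sum(a, b)
                    row["p_value"] = res.p_two_sided
                    row["test_method"] = res.method
        rows.append(row)
    return pd.DataFrame(rows)


def kaks_table(
    pairs: list[tuple[str, str]], cds_by_gene: dict[str, str]
) -> pd.DataFrame:
    """Run NG86 over a pair list; one row per pair, NaN where saturated."""
    rows = []
    for a, b in pairs:
        try:
            r = kaks_ng86(cds_by_gene[a], cds_by_gene[b])
        except (ValueError, KeyError) as exc:
            logger.warning("kaks failed for pair (%s, %s): %s", a, b, exc)
            continue
        rows.append(
            dict(
                gene_a=a,
                gene_b=b,
                S=r.S,
                N=r.N,
                Sd=r.Sd,
                Nd=r.Nd,
                ks=r.ks,
                ka=r.ka,
                ratio=r.ratio,
                saturated=r.saturated_s or r.saturated_n,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "S", "N", "Sd", "Nd", "ks", "ka", "ratio", "saturated"],
    )
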