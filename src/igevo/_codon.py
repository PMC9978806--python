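"""Codon-level bookkeeping shared by the Ka/Ks estimator and the sequence simulator.

Everything here is derived once, at import time, from the standard genetic
code (Biopython's table 1): per-codon synonymous-site fractions, the list of
single-nucleotide mutational neighbours of every sense codon, and the
pathway-averaged difference counts between codon pairs.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: all 64 codons in a fixed order
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

AA: dict[str, str] = {c: _standard.forward_table.get(c, "*") for c in CODONS}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def _single_mutants(codon: str):
    """Yield (position, new_base, mutant_codon) over all 9 single-nt changes."""
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            yield pos, base, codon[: pos] + base + codon[pos + 1 :]


def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of a sense codon.

    Each of the 9 single-nucleotide mutants contributes 1/3 of a site;
    a mutant is synonymous iff it encodes the same amino acid. Mutations
    to stop codons count as nonsynonymous so that S + N = 3 exactly.
    """
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    syn = sum(
        1 for _, _, m in _single_mutants(codon) if not is_stop(m) and AA[m] == AA[codon]
    )
    return syn / 3.0


#: per-codon synonymous sites, indexed like CODONS (NaN for stops)
SYN_SITES: np.ndarray = np.array(
    [np.nan if is_stop(c) else synonymous_sites(c) for c in CODONS]
)


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All minimal mutational pathways (orderings of the differing positions)
    are enumerated; each step is scored synonymous or nonsynonymous by
    comparing amino acids before/after the step.  Pathways passing through
    a stop codon are excluded from the average.  Returns ``None`` when every
    pathway is blocked by stops (the codon pair should then be dropped).
    """
    if codon_a == codon_b:
        return (0.0, 0.0)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    syn_tot = 0.0
    non_tot = 0.0
    n_valid = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if AA[cur] == AA[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_tot += syn
            non_tot += non
            n_valid += 1
    if n_valid == 0:
        return None
    return (syn_tot / n_valid, non_tot / n_valid)


# ---------------------------------------------------------------------------
# Mutation-option tables for the forward simulator.
# For each sense codon (indexed by SENSE_INDEX) we precompute its
# single-nucleotide neighbours that are themselves sense codons, split into
# synonymous and nonsynonymous targets. Stop-producing mutations are simply
# not offered, so simulated CDS never gain stops.
# ---------------------------------------------------------------------------

_syn_targets: list[np.ndarray] = []
_non_targets: list[np.ndarray] = []
for _c in SENSE_CODONS:
    syn_t, non_t = [], []
    for _, _, _m in _single_mutants(_c):
        if is_stop(_m):
            continue
        (syn_t if AA[_m] == AA[_c] else non_t).append(SENSE_INDEX[_m])
    _syn_targets.append(np.array(syn_t, dtype=np.int64))
    _non_targets.append(np.array(non_t, dtype=np.int64))

SYN_TARGETS: tuple[np.ndarray, ...] = tuple(_syn_targets)
NON_TARGETS: tuple[np.ndarray, ...] = tuple(_non_targets)
N_SYN_OPTIONS: np.ndarray = np.array([len(t) for t in SYN_TARGETS], dtype=np.int64)
N_NON_OPTIONS: np.ndarray = np.array([len(t) for t in NON_TARGETS], dtype=np.int64)

#: synonymous sites per sense codon, indexed like SENSE_CODONS
SENSE_SYN_SITES: np.ndarray = np.array([synonymous_sites(c) for c in SENSE_CODONS])


def codons_to_str(idx: np.ndarray) -> str:
    """Sense-codon index array -> nucleotide string."""
    return "".join(SENSE_CODONS[i] for i in idx)


def str_to_codons(seq: str) -> np.ndarray:
    """In-frame, stop-free nucleotide string -> sense-codon index array."""
    if len(seq) % 3:
        raise ValueError("CDS length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3].upper()
        if codon not in SENSE_INDEX:
            raise ValueError(f"non-sense codon {codon!r} at position {i}")
        out[i // 3] = SENSE_INDEX[codon]
    return out
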