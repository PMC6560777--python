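"""Pairwise divergence statistics: p / Poisson / gamma distances, mean
ortholog similarity matrices, and Nei-Gojobori (1986) dN/dS.

The amino-acid distances follow the classic corrections: Poisson
d = -ln(1 - p) and gamma-rates d = a*((1-p)^(-1/a) - 1) with shape
parameter a (default 4).  dN/dS uses NG86 counting: fractional
synonymous-site counts per codon under the standard genetic code,
observed differences averaged over all shortest substitution pathways
that avoid stop codons, and Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p) applied to pN and pS separately.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_core import STOP_CODONS, ClusterTable, CodonPair, Proteome

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
NT = "ACGT"

CODON_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in STOP_CODONS:
    CODON_AA[_stop] = "*"

GAPLIKE = frozenset("-.X")


# ---------------------------------------------------------------------------
# Amino-acid distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceResult:
    p: float
    d_poisson: float
    d_gamma: float
    n_sites: int


def p_distance(aligned_a: str, aligned_b: str) -> DistanceResult:
    """Proportion of differing sites after pairwise deletion of gap/X sites."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a = aligned_a.upper()
    b = aligned_b.upper()
    n = diff = 0
    for ca, cb in zip(a, b):
        if ca in GAPLIKE or cb in GAPLIKE:
            continue
        n += 1
        if ca != cb:
            diff += 1
    if n == 0:
        raise ValueError("no comparable sites after removing gaps and X")
    p = diff / n
    return DistanceResult(
        p=p,
        d_poisson=poisson_distance(p) if p < 1 else float("inf"),
        d_gamma=gamma_distance(p) if p < 1 else float("inf"),
        n_sites=n,
    )


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p)."""
    if not (0.0 <= p < 1.0):
        raise ValueError("p must be in [0, 1)")
    return -math.log(1.0 - p)


def gamma_distance(p: float, alpha: float = 4.0) -> float:
    """Gamma-rates corrected distance d = alpha * ((1-p)^(-1/alpha) - 1).

    ``alpha`` is the gamma shape parameter of among-site rate variation;
    alpha -> infinity recovers the Poisson correction.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("p must be in [0, 1)")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)


def mean_ortholog_similarity(
    proteomes: Mapping[str, Proteome],
    table: ClusterTable,
    cluster_ids: Iterable[str],
    align: bool = True,
) -> pd.DataFrame:
    """Taxon x taxon matrix of mean percent identity over single-copy
    ortholog clusters.

    Per taxon pair, the mean over spanning clusters of 100*(1 - p); the
    diagonal is 100 and pairs with no shared cluster are NaN.  Sequences
    of unequal length are globally aligned first.
    """
    from .orthology import _ALIGNER  # shared scorer configuration

    taxa = sorted(proteomes)
    sums = pd.DataFrame(0.0, index=taxa, columns=taxa)
    ns = pd.DataFrame(0, index=taxa, columns=taxa)
    for cid in cluster_ids:
        mem = [(t, p) for t, p in table.members[cid] if t in proteomes]
        for (ta, pa), (tb, pb) in itertools.combinations(mem, 2):
            if ta == tb:
                continue
            sa = proteomes[ta].records[pa]
            sb = proteomes[tb].records[pb]
            if len(sa) != len(sb):
                if not align:
                    continue
                aln = _ALIGNER.align(sa, sb)[0]
                sa, sb = str(aln[0]), str(aln[1])
            try:
                res = p_distance(sa, sb)
            except ValueError:
                continue
            ident = 100.0 * (1.0 - res.p)
            for x, y in ((ta, tb), (tb, ta)):
                sums.loc[x, y] += ident
                ns.loc[x, y] += 1
    with np.errstate(invalid="ignore"):
        out = sums / ns.replace(0, np.nan)
    for t in taxa:
        out.loc[t, t] = 100.0
    return out


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------

@dataclass
class DnDsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    omega: float | None  # None when dS == 0
    n_codons: int


@functools.lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (N, S) site counts for one codon.

    Per position, the synonymous fraction is computed over the mutations
    that do not create a stop codon; each position contributes one site
    split between N and S.
    """
    aa = CODON_AA[codon]
    n_sites = s_sites = 0.0
    for pos in range(3):
        syn = nonsyn = 0
        for alt in NT:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if mutated in STOP_CODONS:
                continue
            if CODON_AA[mutated] == aa:
                syn += 1
            else:
                nonsyn += 1
        total = syn + nonsyn
        if total == 0:  # all mutations lead to stops (cannot happen in the standard code)
            n_sites += 1.0
            continue
        s_sites += syn / total
        n_sites += 1.0 - syn / total
    return n_sites, s_sites


@functools.lru_cache(maxsize=None)
def _pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """Average (Nd, Sd) between two codons over all shortest substitution
    pathways that avoid stop codons.

    If every pathway passes through a stop, stop-crossing pathways are
    admitted as a fallback (the stop intermediate's steps still classify
    by amino-acid change, with '*' treated as a distinct amino acid).
    """
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool) -> tuple[float, float] | None:
        cur = ca
        nd = sd = 0.0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops and nxt != cb:
                return None
            if CODON_AA[cur] == CODON_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return nd, sd

    for allow_stops in (False, True):
        results = [
            r
            for order in itertools.permutations(positions)
            if (r := walk(order, allow_stops)) is not None
        ]
        if results:
            nd = sum(r[0] for r in results) / len(results)
            sd = sum(r[1] for r in results) / len(results)
            return nd, sd
    raise AssertionError("unreachable")


def ng86_counts(pair: CodonPair) -> tuple[float, float, float, float]:
    """Raw NG86 quantities (N, S, Nd, Sd) without any correction.

    Site counts are averaged over the two sequences; codons containing
    gaps or ambiguous bases are excluded.
    """
    codons = pair.codons()
    if not codons:
        raise ValueError("no comparable codons")
    N = S = Nd = Sd = 0.0
    for ca, cb in codons:
        na, sa = _codon_site_counts(ca)
        nb, sb = _codon_site_counts(cb)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = _pathway_differences(ca, cb)
        Nd += nd
        Sd += sd
    return N, S, Nd, Sd


def ng86_dnds(pair: CodonPair) -> DnDsResult:
    """Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction.

    ``omega`` is None when dS = 0.  Saturation (pN or pS >= 3/4, where the
    correction diverges) raises a ValueError.
    """
    N, S, Nd, Sd = ng86_counts(pair)
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    for name, p in (("pN", pN), ("pS", pS)):
        if p >= 0.75:
            raise ValueError(f"{name} = {p:.3f} >= 3/4: substitution saturation")
    dN = _jc_correct(pN)
    dS = _jc_correct(pS)
    omega = (dN / dS) if dS > 0 else None
    return DnDsResult(N, S, Nd, Sd, pN, pS, dN, dS, omega, len(pair.codons()))


def _jc_correct(p: float) -> float:
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def selection_class(omega: float | None, tau: float = 0.1) -> str:
    """Classify an omega estimate: purifying (< 1 - tau), neutral
    (|omega - 1| <= tau), diversifying (> 1 + tau), undefined (None)."""
    if omega is None or not math.isfinite(omega):
        return "undefined"
    if omega < 1.0 - tau:
        return "purifying"
    if omega > 1.0 + tau:
        return "diversifying"
    return "neutral"
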