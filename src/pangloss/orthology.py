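"""Desk-scale ortholog detection: similarity, reciprocal best hits, clusters.

The scorer is a global Needleman-Wunsch alignment under BLOSUM62 with
affine gaps (open -11, extend -1), normalized by the self-alignment score
of the shorter sequence so that identical sequences score 1.0 and
unrelated random proteins score near 0.  Clusters are connected components
of the reciprocal-best-hit graph; proteins without edges become
singleton clusters.  Precomputed OrthoMCL-style groups files can be
ingested instead via :func:`pangloss.io_core.read_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .io_core import ClusterTable, Proteome

DEFAULT_MIN_SCORE = 0.5


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()
_SELF_SCORE_CACHE: dict[str, float] = {}


def _self_score(seq: str) -> float:
    score = _SELF_SCORE_CACHE.get(seq)
    if score is None:
        score = float(_ALIGNER.score(seq, seq))
        if len(_SELF_SCORE_CACHE) > 100_000:
            _SELF_SCORE_CACHE.clear()
        _SELF_SCORE_CACHE[seq] = score
    return score


def pairwise_similarity(seq_a: str, seq_b: str) -> float:
    """Normalized global-alignment similarity in [0, 1].

    The raw BLOSUM62 alignment score is divided by the self-alignment
    score of the shorter sequence; negative raw scores clamp to 0.
    Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    shorter = seq_a if len(seq_a) <= len(seq_b) else seq_b
    denom = _self_score(shorter)
    if denom <= 0:  # degenerate composition; self score of real proteins is > 0
        return 0.0
    raw = float(_ALIGNER.score(seq_a, seq_b))
    return min(1.0, max(0.0, raw / denom))


def _score_matrix(
    a: Proteome, b: Proteome
) -> dict[tuple[str, str], float]:
    scores: dict[tuple[str, str], float] = {}
    for pa, sa in a.records.items():
        for pb, sb in b.records.items():
            scores[(pa, pb)] = pairwise_similarity(sa, sb)
    return scores


def reciprocal_best_hits(
    proteome_a: Proteome,
    proteome_b: Proteome,
    min_score: float = DEFAULT_MIN_SCORE,
) -> set[tuple[tuple[str, str], tuple[str, str]]]:
    """Reciprocal best hits between two proteomes.

    A pair ((taxon_a, x), (taxon_b, y)) is reported iff y is the *unique*
    top-scoring hit of x in B, x the unique top hit of y in A, and the
    score is >= ``min_score``.  Ties for best hit exclude the protein.
    """
    if not (0.0 < min_score <= 1.0):
        raise ValueError("min_score must be in (0, 1]")
    scores = _score_matrix(proteome_a, proteome_b)

    def unique_best(ids: Sequence[str], other: Sequence[str], forward: bool):
        best: dict[str, str | None] = {}
        for x in ids:
            top, top_score, tied = None, -1.0, False
            for y in other:
                s = scores[(x, y)] if forward else scores[(y, x)]
                if s > top_score:
                    top, top_score, tied = y, s, False
                elif s == top_score:
                    tied = True
            best[x] = top if (top is not None and not tied and top_score >= min_score) else None
        return best

    ids_a = list(proteome_a.records)
    ids_b = list(proteome_b.records)
    best_ab = unique_best(ids_a, ids_b, forward=True)
    best_ba = unique_best(ids_b, ids_a, forward=False)
    pairs = set()
    for x, y in best_ab.items():
        if y is not None and best_ba.get(y) == x:
            pairs.add(((proteome_a.taxon_id, x), (proteome_b.taxon_id, y)))
    return pairs


def build_clusters(
    hit_pairs: Iterable[tuple[tuple[str, str], tuple[str, str]]],
    proteomes: Mapping[str, Proteome] | Sequence[Proteome],
) -> ClusterTable:
    """Connected components of the RBH graph as a :class:`ClusterTable`.

    Every protein of every proteome appears in exactly one cluster;
    proteins with no edges become singletons.  Cluster ids are the
    lexicographically smallest member written as ``taxon|protein``.
    """
    if not isinstance(proteomes, Mapping):
        proteomes = {p.taxon_id: p for p in proteomes}
    graph = nx.Graph()
    for taxon, prot in proteomes.items():
        for pid in prot.records:
            graph.add_node((taxon, pid))
    for u, v in hit_pairs:
        if u not in graph or v not in graph:
            raise ValueError(f"hit pair references unknown protein: {u} - {v}")
        graph.add_edge(u, v)
    members: dict[str, list[tuple[str, str]]] = {}
    for component in nx.connected_components(graph):
        mem = sorted(component)
        cid = f"{mem[0][0]}|{mem[0][1]}"
        members[cid] = mem
    ordered = {cid: members[cid] for cid in sorted(members)}
    return ClusterTable.from_members(ordered, taxa=sorted(proteomes))


def cluster_proteomes(
    proteomes: Mapping[str, Proteome] | Sequence[Proteome],
    min_score: float = DEFAULT_MIN_SCORE,
) -> ClusterTable:
    """All-vs-all RBH across >= 2 proteomes, then component clustering."""
    if not isinstance(proteomes, Mapping):
        proteomes = {p.taxon_id: p for p in proteomes}
    taxa = sorted(proteomes)
    if len(taxa) < 2:
        raise ValueError("need at least two proteomes to cluster")
    pairs: set[tuple[tuple[str, str], tuple[str, str]]] = set()
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            pairs |= reciprocal_best_hits(proteomes[ta], proteomes[tb], min_score)
    return build_clusters(pairs, proteomes)
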