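"""Taxonomically restricted ("orphan") genes and their chromosomal geometry.

Orphans are defined at three scopes: genus level (present in every ingroup
species, absent from every outgroup), clade level (subset-specific to one
clade and absent from outgroups), and species level (clusters containing a
single taxon, including unclustered singletons).  The geometry analyses
ask whether orphans sit in consecutive runs along chromosomes and whether
they concentrate within a fixed window (default 100 kb) of chromosome ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_core import CladePartition, ClusterTable, GeneMap
from .pangenome import core_clusters, subset_specific


@dataclass
class OrphanSet:
    level: str  # "genus" | "clade:<label>" | "species:<taxon>"
    cluster_ids: set[str]
    genes: dict[str, list[str]] = field(default_factory=dict)  # taxon -> gene ids

    def gene_ids(self, taxon: str) -> list[str]:
        return self.genes.get(taxon, [])


@dataclass
class OrphanRun:
    chrom: str
    ordinals: tuple[int, ...]
    gene_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class OrphanClusterReport:
    singletons: list[tuple[str, str]]  # (chrom, gene_id)
    runs: list[OrphanRun]
    unmapped: list[str]

    @property
    def n_mapped(self) -> int:
        return len(self.singletons) + sum(r.size for r in self.runs)

    def size_histogram(self) -> dict[int, int]:
        """Run-size -> number of runs; size 1 entries are the singletons."""
        hist: dict[int, int] = {}
        if self.singletons:
            hist[1] = len(self.singletons)
        for run in self.runs:
            hist[run.size] = hist.get(run.size, 0) + 1
        return hist


def _genes_of(table: ClusterTable, cluster_ids: Iterable[str]) -> dict[str, list[str]]:
    genes: dict[str, list[str]] = {}
    for cid in cluster_ids:
        for taxon, protein in table.members[cid]:
            genes.setdefault(taxon, []).append(protein)
    return genes


def find_orphans(
    table: ClusterTable,
    clades: CladePartition,
    level: str,
    species_map: Mapping[str, str] | None = None,
) -> OrphanSet:
    """Find orphan clusters at a given taxonomic scope.

    ``level`` is ``"genus"``, ``"clade:<label>"`` or ``"species:<taxon>"``.
    Genus orphans require a non-empty outgroup in the table; they are by
    construction a subset of the core genome.
    """
    ingroup = sorted(t for t in table.taxa if t in clades.ingroup)
    outgroups = sorted(t for t in table.taxa if t in clades.outgroups)
    pres = table.presence()

    if level == "genus":
        if not outgroups:
            raise ValueError("genus-level orphan detection requires outgroup taxa")
        core = core_clusters(table, ingroup, species_map=species_map)
        out_rows = [table.taxa.index(t) for t in outgroups]
        cids = {
            cid
            for cid in core
            if not pres[out_rows, table.cluster_ids.index(cid)].any()
        }
        return OrphanSet("genus", cids, _genes_of(table, cids))

    if level.startswith("clade:"):
        label = level.split(":", 1)[1]
        clade_taxa = sorted(clades.clade_taxa(label) & set(table.taxa))
        if not clade_taxa:
            raise ValueError(f"no taxa in table for clade {label!r}")
        # subset-specificity already forbids presence outside the clade,
        # which covers the outgroups present in the table
        cids = subset_specific(table, clade_taxa, species_map=species_map)
        if species_map:  # map back to original-taxon membership
            cids = {c for c in cids}
        return OrphanSet(level, cids, _genes_of(table, cids))

    if level.startswith("species:"):
        taxon = level.split(":", 1)[1]
        if taxon not in table.taxa:
            raise ValueError(f"unknown taxon {taxon!r}")
        cids = set()
        for j, cid in enumerate(table.cluster_ids):
            taxa_in = {t for t, _ in table.members[cid]}
            if taxa_in == {taxon}:
                cids.add(cid)
        return OrphanSet(level, cids, _genes_of(table, cids))

    raise ValueError(f"unknown orphan level {level!r}")


def orphan_runs(
    genemap: GeneMap,
    orphan_gene_ids: Iterable[str],
    max_gap: int = 0,
) -> OrphanClusterReport:
    """Group orphan genes into chromosomal runs.

    A run is a maximal set of >= 2 orphans consecutive in chromosomal gene
    order; with ``max_gap > 0`` up to that many intervening non-orphan
    genes are tolerated inside a run.  Orphans absent from the gene map
    are excluded with a warning and listed in the report.
    """
    orphan_ids = list(dict.fromkeys(orphan_gene_ids))
    unmapped = [g for g in orphan_ids if g not in genemap]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} orphan gene(s) not in gene map, excluded: "
            f"{unmapped[:5]}{'...' if len(unmapped) > 5 else ''}",
            stacklevel=2,
        )
    mapped = [g for g in orphan_ids if g in genemap]
    orphan_set = set(mapped)

    singletons: list[tuple[str, str]] = []
    runs: list[OrphanRun] = []
    for chrom, loci in genemap.by_chrom.items():
        ordinals = [loc.ordinal for loc in loci if loc.gene_id in orphan_set]
        by_ord = {loc.ordinal: loc.gene_id for loc in loci}
        ordinals.sort()
        i = 0
        while i < len(ordinals):
            j = i
            while j + 1 < len(ordinals) and ordinals[j + 1] - ordinals[j] <= max_gap + 1:
                j += 1
            block = ordinals[i : j + 1]
            if len(block) >= 2:
                runs.append(
                    OrphanRun(
                        chrom,
                        tuple(block),
                        tuple(by_ord[o] for o in block),
                    )
                )
            else:
                singletons.append((chrom, by_ord[block[0]]))
            i = j + 1
    return OrphanClusterReport(singletons, runs, unmapped)


def subtelomeric_fraction(
    genemap: GeneMap,
    gene_ids: Iterable[str],
    window_bp: int = 100_000,
) -> tuple[float, dict[str, str]]:
    """Fraction of genes whose midpoint lies within ``window_bp`` of a
    chromosome end, plus a per-gene {subtelomeric, middle} classification.

    Distance to end is min(midpoint, length - midpoint) with 1-based
    inclusive coordinates; the boundary is inclusive (distance == window
    counts as subtelomeric).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    classes: dict[str, str] = {}
    n_sub = 0
    genes = list(gene_ids)
    for g in genes:
        loc = genemap[g]
        length = genemap.chromosomes.get(loc.chrom)
        if length is None:
            raise ValueError(f"chromosome length missing for {loc.chrom!r}")
        mid = loc.midpoint
        dist = min(mid, length - mid)
        if dist <= window_bp:
            classes[g] = "subtelomeric"
            n_sub += 1
        else:
            classes[g] = "middle"
    frac = n_sub / len(genes) if genes else 0.0
    return frac, classes
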