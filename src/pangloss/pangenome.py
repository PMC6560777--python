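"""Set-algebra analyses of the cluster table.

Core genome extraction, clade-level cluster classification, subset-specific
cluster sets, intersection (UpSet-style) counts, strain-vs-strain gene
differences, and the sequence-abundance screen used to rank species by
database representation.

"Present" means count >= 1 throughout; paralog multiplicity matters only
in :func:`single_copy_orthologs`.  Species with multiple sequenced strains
are collapsed by presence-OR before core/specificity tests when a
strain -> species map is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import OUTGROUP_LABEL, CladePartition, ClusterTable


@dataclass
class ClusterCategory:
    cluster_id: str
    category: str  # genus_wide | multi_clade | clade_only:<L> | species_only:<T> | outgroup_shared | other
    clade_counts: dict[str, int] = field(default_factory=dict)


def _collapse(table: ClusterTable, species_map: Mapping[str, str] | None) -> ClusterTable:
    if species_map is None:
        return table
    return table.collapse(species_map, how="max")


def core_clusters(
    table: ClusterTable,
    ingroup: Iterable[str],
    species_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Clusters present (count >= 1) in every ingroup species.

    With a strain -> species map, multi-strain species are collapsed by
    presence-OR before the test, so a cluster found in either strain of a
    species counts as present in that species.
    """
    table = _collapse(table, species_map)
    ingroup = sorted({species_map.get(t, t) if species_map else t for t in ingroup})
    if not ingroup:
        raise ValueError("empty ingroup")
    missing = [t for t in ingroup if t not in table.taxa]
    if missing:
        raise ValueError(f"ingroup taxa not in table: {missing}")
    pres = table.presence()
    rows = [table.taxa.index(t) for t in ingroup]
    mask = pres[rows].all(axis=0)
    return {cid for cid, ok in zip(table.cluster_ids, mask) if ok}


def single_copy_orthologs(
    table: ClusterTable,
    ingroup: Iterable[str],
    allow_missing: int = 1,
) -> set[str]:
    """Clusters single-copy in each ingroup taxon, absent from at most
    ``allow_missing`` of them, and multi-copy in none."""
    if allow_missing < 0:
        raise ValueError("allow_missing must be >= 0")
    ingroup = sorted(set(ingroup))
    rows = [table.taxa.index(t) for t in ingroup]
    sub = table.counts[rows]
    ok = (sub <= 1).all(axis=0) & ((sub == 1).sum(axis=0) >= len(ingroup) - allow_missing)
    return {cid for cid, flag in zip(table.cluster_ids, ok) if flag}


def subset_specific(
    table: ClusterTable,
    subset: Iterable[str],
    species_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Clusters found in at least all-but-one of the subset taxa and in no
    taxon outside the subset."""
    table = _collapse(table, species_map)
    subset = sorted({species_map.get(t, t) if species_map else t for t in subset})
    if not subset:
        raise ValueError("empty subset")
    missing = [t for t in subset if t not in table.taxa]
    if missing:
        raise ValueError(f"subset taxa not in table: {missing}")
    if len(subset) == len(table.taxa):
        raise ValueError("subset equals all taxa; no outside group to test against")
    pres = table.presence()
    inside = [table.taxa.index(t) for t in subset]
    outside = [i for i in range(len(table.taxa)) if table.taxa[i] not in subset]
    ok = (pres[inside].sum(axis=0) >= len(subset) - 1) & (~pres[outside].any(axis=0))
    return {cid for cid, flag in zip(table.cluster_ids, ok) if flag}


def classify_by_clade(
    table: ClusterTable,
    clades: CladePartition,
    species_map: Mapping[str, str] | None = None,
    require_all_clades: bool = True,
) -> tuple[list[ClusterCategory], pd.DataFrame]:
    """Assign each cluster a clade-distribution category and build a
    per-species summary table.

    Categories (precedence genus_wide > multi_clade > clade_only >
    species_only, computed on ingroup species presence):

    * ``genus_wide`` — present in every ingroup species;
    * ``multi_clade`` — present in >= 2 ingroup clades;
    * ``clade_only:<L>`` — ingroup presence confined to clade L, >= 2 species;
    * ``species_only:<T>`` — ingroup presence confined to one species;
    * ``outgroup_shared`` — present only in outgroup taxa;
    * ``other`` — empty clusters.

    The summary gives, per ingroup species: clusters present; clusters
    satisfying the two-species-per-clade criterion (every ingroup clade
    represented by >= 2 species when ``require_all_clades``, else its own
    clade only); clade-only clusters of its clade; clusters it is absent
    from (of those present in >= 1 ingroup species); and its total genes.
    """
    collapsed = _collapse(table, species_map)
    clades.validate_taxa(collapsed.taxa)
    pres = collapsed.presence()
    ingroup_species = [t for t in collapsed.taxa if clades.assignment[t] != OUTGROUP_LABEL]
    clade_labels = clades.clades
    clade_rows = {
        lab: [collapsed.taxa.index(t) for t in ingroup_species if clades.assignment[t] == lab]
        for lab in clade_labels
    }
    in_rows = [collapsed.taxa.index(t) for t in ingroup_species]
    out_rows = [i for i, t in enumerate(collapsed.taxa) if clades.assignment[t] == OUTGROUP_LABEL]

    categories: list[ClusterCategory] = []
    for j, cid in enumerate(collapsed.cluster_ids):
        clade_counts = {lab: int(pres[rows, j].sum()) for lab, rows in clade_rows.items()}
        n_in = int(pres[in_rows, j].sum())
        n_out = int(pres[out_rows, j].sum()) if out_rows else 0
        present_clades = [lab for lab, n in clade_counts.items() if n > 0]
        if n_in == len(ingroup_species):
            cat = "genus_wide"
        elif len(present_clades) >= 2:
            cat = "multi_clade"
        elif len(present_clades) == 1 and n_in >= 2:
            cat = f"clade_only:{present_clades[0]}"
        elif n_in == 1:
            taxon = next(
                t for t in ingroup_species if pres[collapsed.taxa.index(t), j]
            )
            cat = f"species_only:{taxon}"
        elif n_out > 0:
            cat = "outgroup_shared"
        else:
            cat = "other"
        categories.append(ClusterCategory(cid, cat, clade_counts))

    # per-species summary
    two_per_clade = np.ones(collapsed.n_clusters, dtype=bool)
    for lab, rows in clade_rows.items():
        has_two = pres[rows].sum(axis=0) >= 2
        if require_all_clades:
            two_per_clade &= has_two
    present_any_ingroup = pres[in_rows].any(axis=0)
    rows_out = []
    for t in ingroup_species:
        i = collapsed.taxa.index(t)
        lab = clades.assignment[t]
        present = pres[i]
        if not require_all_clades:
            two_per_clade_t = pres[clade_rows[lab]].sum(axis=0) >= 2
        else:
            two_per_clade_t = two_per_clade
        clade_only = np.array(
            [c.category == f"clade_only:{lab}" for c in categories]
        )
        rows_out.append(
            {
                "species": t,
                "clade": lab,
                "clusters_present": int(present.sum()),
                "two_species_each_clade": int((present & two_per_clade_t).sum()),
                "clade_only": int((present & clade_only).sum()),
                "absent_from": int((present_any_ingroup & ~present).sum()),
                "total_genes": int(collapsed.counts[i].sum()),
            }
        )
    return categories, pd.DataFrame(rows_out)


def intersection_counts(
    table: ClusterTable,
    groups: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """UpSet-style exclusive intersection counts over named taxon groups.

    For each of the 2^g - 1 non-empty group combinations, counts clusters
    present in >= 1 taxon of every included group and in 0 taxa of every
    excluded group.  Counts over all combinations sum to the number of
    clusters present in >= 1 group.
    """
    names = list(groups)
    if len(names) > 12:
        raise ValueError("more than 12 groups: combinatorial guard")
    rows = {
        name: [table.taxa.index(t) for t in taxa]
        for name, taxa in ((n, list(groups[n])) for n in names)
    }
    pres = table.presence()
    hit = {name: pres[r].any(axis=0) for name, r in rows.items()}
    out = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            mask = np.ones(table.n_clusters, dtype=bool)
            for name in names:
                mask &= hit[name] if name in combo else ~hit[name]
            out.append({"groups": "&".join(combo), "degree": k, "n_clusters": int(mask.sum())})
    return pd.DataFrame(out)


@dataclass
class StrainDifference:
    taxon_a: str
    taxon_b: str
    n_a_only: int
    n_b_only: int
    n_shared_a: int  # genes of a in clusters shared with b
    n_shared_b: int
    total_a: int
    total_b: int

    @property
    def pct_a_only(self) -> int:
        return round(100.0 * self.n_a_only / self.total_a)

    @property
    def pct_b_only(self) -> int:
        return round(100.0 * self.n_b_only / self.total_b)


def strain_difference(
    table: ClusterTable,
    taxon_a: str,
    taxon_b: str,
    totals: Mapping[str, int] | None = None,
) -> StrainDifference:
    """Gene-level difference between two strains.

    ``a_only`` counts genes of A in clusters with zero B members, plus A's
    unclustered genes when per-strain gene totals are supplied (unclustered
    = total - clustered).  Percentages are reported against each strain's
    total gene count, rounded to the nearest integer.
    """
    for t in (taxon_a, taxon_b):
        if t not in table.taxa:
            raise ValueError(f"unknown taxon {t!r}")
    row_a = table.taxon_row(taxon_a)
    row_b = table.taxon_row(taxon_b)
    a_only = int(row_a[row_b == 0].sum())
    b_only = int(row_b[row_a == 0].sum())
    shared_a = int(row_a[(row_a > 0) & (row_b > 0)].sum())
    shared_b = int(row_b[(row_a > 0) & (row_b > 0)].sum())
    total_a = totals[taxon_a] if totals else int(row_a.sum())
    total_b = totals[taxon_b] if totals else int(row_b.sum())
    a_only += max(0, total_a - int(row_a.sum()))
    b_only += max(0, total_b - int(row_b.sum()))
    return StrainDifference(
        taxon_a, taxon_b, a_only, b_only, shared_a, shared_b, total_a, total_b
    )


def screen_species_abundance(
    records: Mapping[str, int] | Sequence[tuple[str, int]],
    rare_below: int = 50,
    common_above: int = 100,
) -> pd.DataFrame:
    """Rank species by sequence abundance and label rarity classes.

    Returns a DataFrame sorted by descending count with integer-rounded
    share-of-total percentages and class labels: ``rare`` (n < rare_below),
    ``common`` (n > common_above), else ``intermediate``.
    """
    if isinstance(records, Mapping):
        records = list(records.items())
    counts = {name: int(n) for name, n in records}
    if any(n < 0 for n in counts.values()):
        raise ValueError("negative sequence counts")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("total sequence count is zero")
    rows = []
    for name, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        cls = "rare" if n < rare_below else ("common" if n > common_above else "intermediate")
        rows.append(
            {
                "species": name,
                "n_sequences": n,
                "share_pct": round(100.0 * n / total),
                "share_exact": 100.0 * n / total,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)
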