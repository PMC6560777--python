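"""Synthetic input generator with full truth labels.

Produces the inputs the analysis assumes, with known ground truth:

* gene-family presence evolved by stochastic gain/loss along a dated tree,
  plus planted core, clade-restricted, genus-orphan and species-orphan
  families with forced presence patterns;
* proteomes in which members of a family diverge from a family-specific
  ancestral sequence by per-site substitution, while distinct families are
  mutually unrelated (independent random ancestors), so that restricted
  families share no detectable similarity with outgroup proteins;
* planted small secreted cysteine-rich proteins (generic SSCPs,
  class-II-type hydrophobins, cerato-platanins) and decoys;
* chromosome layouts with orphan genes planted as singletons and as
  consecutive runs of requested sizes, a chosen share of them within the
  subtelomeric window;
* codon-alignment pairs evolved under a selectable dN/dS ratio.

All randomness derives from a single integer seed, split deterministically
per sub-generator, so a fixed config yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_core import (
    STOP_CODONS,
    CladePartition,
    ClusterTable,
    CodonPair,
    GeneLocus,
    GeneMap,
    Proteome,
    TimeTree,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_CYS = AA20.replace("C", "")
NT = "ACGT"
SENSE_CODONS = [
    a + b + c
    for a in NT
    for b in NT
    for c in NT
    if a + b + c not in STOP_CODONS
]

#: Signal-peptide prefix satisfying the secretion heuristic: charged
#: n-region (K in positions 1-5), 8-residue hydrophobic h-region at
#: positions 6-13, small residues at -3/-1 of the implied cleavage site.
SIGNAL_PREFIX = "MKRQT" + "LLLLLLLL" + "AQS"

#: Prefix violating the heuristic (acidic, no hydrophobic window).
NONSECRETED_PREFIX = "MDDEDEDDEDDEDEDD"


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class PlantedCounts:
    core: int = 10
    per_clade: int = 4
    genus_orphan: int = 6
    species_orphan: int = 2  # per ingroup species
    sscp: int = 4
    hydrophobin: int = 2
    ceratoplatanin: int = 1
    decoy: int = 6

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"planted count {name} must be >= 0")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Rates are events per family per Mya; ``divergence_scale`` is expected
    amino-acid substitutions per site per Mya.
    """

    tree: TimeTree
    clades: CladePartition
    species_map: dict[str, str] = field(default_factory=dict)
    gain_rate: float = 0.05
    loss_rate: float = 0.002
    n_root_families: int = 40
    planted: PlantedCounts = field(default_factory=PlantedCounts)
    mean_protein_len: int = 120
    divergence_scale: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_root_families < 0:
            raise ValueError("n_root_families must be >= 0")
        if self.divergence_scale < 0:
            raise ValueError("divergence_scale must be >= 0")
        self.planted.validate()

    def species_of(self, taxon: str) -> str:
        return self.species_map.get(taxon, taxon)

    def ingroup_species(self) -> list[str]:
        seen: list[str] = []
        for t in self.tree.leaf_labels:
            if t in self.clades.ingroup:
                s = self.species_of(t)
                if s not in seen:
                    seen.append(s)
        return seen


@dataclass
class Truth:
    """Ground-truth labels for one synthetic dataset."""

    cluster_category: dict[str, str] = field(default_factory=dict)
    origin_node: dict[str, str] = field(default_factory=dict)
    branch_gains: dict[tuple[str, str], int] = field(default_factory=dict)
    branch_losses: dict[tuple[str, str], int] = field(default_factory=dict)
    sscp_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    orphan_genes: dict[str, list[str]] = field(default_factory=dict)
    run_size_hist: dict[str, dict[int, int]] = field(default_factory=dict)
    subtelomeric_fraction: dict[str, float] = field(default_factory=dict)

    def clusters_in_category(self, category: str) -> set[str]:
        return {c for c, cat in self.cluster_category.items() if cat == category}

    def to_json(self, path) -> None:
        payload = {
            "cluster_category": self.cluster_category,
            "origin_node": self.origin_node,
            "branch_gains": {f"{p}->{c}": n for (p, c), n in self.branch_gains.items()},
            "branch_losses": {f"{p}->{c}": n for (p, c), n in self.branch_losses.items()},
            "sscp_labels": self.sscp_labels,
            "orphan_genes": self.orphan_genes,
            "run_size_hist": {
                t: {str(k): v for k, v in h.items()} for t, h in self.run_size_hist.items()
            },
            "subtelomeric_fraction": self.subtelomeric_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Dated ultrametric tree: three ingroup clades of two species (one species
#: sequenced as two strains), two outgroups.  Depths in Mya: strain split 2,
#: species splits 20-25, ingroup crown 60, outgroup splits 200 and 250.
DEFAULT_NEWICK = (
    "((((SL1:25,SL2:25):35,((HV1:20,(HV2a:2,HV2b:2):18):30,"
    "(ST1:22,ST2:22):28):10):140,OG2:200):50,OG1:250):0;"
)

DEFAULT_CLADES = {
    "SL1": "SL",
    "SL2": "SL",
    "HV1": "HV",
    "HV2a": "HV",
    "HV2b": "HV",
    "ST1": "ST",
    "ST2": "ST",
    "OG1": "OUTGROUP",
    "OG2": "OUTGROUP",
}

DEFAULT_SPECIES_MAP = {"HV2a": "HV2", "HV2b": "HV2"}


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(
        tree=TimeTree.from_newick_string(DEFAULT_NEWICK),
        clades=CladePartition(assignment=dict(DEFAULT_CLADES)),
        species_map=dict(DEFAULT_SPECIES_MAP),
        seed=seed,
    )


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def random_timetree(
    n_leaves: int, depth: float = 100.0, seed: int = 0
) -> TimeTree:
    """Random ultrametric rooted binary tree with ``n_leaves`` leaves
    labelled T01.. and total root-to-leaf depth ``depth`` Mya."""
    if n_leaves < 2:
        raise ValueError("need >= 2 leaves")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    heights = np.sort(rng.uniform(0.05 * depth, depth, size=n_leaves - 1))
    heights[-1] = depth
    # coalescent-style sequential merging at increasing heights
    nodes: list[tuple[str, float]] = [(f"T{i + 1:02d}", 0.0) for i in range(n_leaves)]
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{h - ha:.6f},{nb}:{h - hb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append((merged, h))
    newick = nodes[0][0] + ":0;"
    return TimeTree.from_newick_string(newick)


# ---------------------------------------------------------------------------
# Family evolution
# ---------------------------------------------------------------------------

def simulate_family_evolution(config: SimConfig) -> tuple[ClusterTable, Truth]:
    """Evolve family presence/absence down the tree and plant labelled
    categories.

    On a branch of length b a present family is lost with probability
    1 - exp(-loss_rate * b); new families arise as a Poisson(gain_rate * b)
    draw, are present at the branch's child and persist downwards absent
    subsequent loss.  Planted categories get forced presence patterns and
    are never lost: core families occupy every leaf, genus orphans every
    ingroup leaf, clade families every leaf of their clade, species
    orphans every strain of their species.
    """
    tree = config.tree
    rng = _rng(config.seed, 1)
    truth = Truth()

    presence: dict[str, set[str]] = {}  # family -> leaf labels
    root_name = tree.node_name(tree.root)

    root_families = [f"R{i:04d}" for i in range(config.n_root_families)]
    for fam in root_families:
        truth.cluster_category[fam] = "stochastic_root"
        truth.origin_node[fam] = root_name

    # node -> set of families present when the traversal reaches it
    state: dict[int, set[str]] = {id(tree.root): set(root_families)}
    gained_counter = 0
    for parent, child, length in tree.edges():
        pname, cname = tree.node_name(parent), tree.node_name(child)
        cur = set(state[id(parent)])
        gains = losses = 0
        p_loss = 1.0 - np.exp(-config.loss_rate * length) if length > 0 else 0.0
        for fam in sorted(cur):
            if p_loss > 0 and rng.random() < p_loss:
                cur.discard(fam)
                losses += 1
        n_new = int(rng.poisson(config.gain_rate * length)) if length > 0 else 0
        for _ in range(n_new):
            fam = f"N{gained_counter:04d}"
            gained_counter += 1
            truth.cluster_category[fam] = "stochastic_gain"
            truth.origin_node[fam] = cname
            cur.add(fam)
            gains += 1
        truth.branch_gains[(pname, cname)] = gains
        truth.branch_losses[(pname, cname)] = losses
        state[id(child)] = cur
        if child.is_leaf():
            leaf = child.taxon.label
            for fam in cur:
                presence.setdefault(fam, set()).add(leaf)

    # families lost everywhere still exist in truth but have no members;
    # drop them from the table (a cluster needs >= 1 member)
    leaves = tree.leaf_labels
    ingroup_leaves = [t for t in leaves if t in config.clades.ingroup]

    def plant(fam: str, category: str, members: Sequence[str], origin: str) -> None:
        truth.cluster_category[fam] = category
        truth.origin_node[fam] = origin
        presence[fam] = set(members)

    p = config.planted
    for i in range(p.core):
        plant(f"C{i:04d}", "core", leaves, root_name)
    if p.genus_orphan:
        mrca = tree.mrca(ingroup_leaves)
        mname = tree.node_name(mrca)
        for i in range(p.genus_orphan):
            fam = f"G{i:04d}"
            plant(fam, "genus_orphan", ingroup_leaves, mname)
        if mrca.parent_node is not None:
            key = (tree.node_name(mrca.parent_node), mname)
            truth.branch_gains[key] = truth.branch_gains.get(key, 0) + p.genus_orphan
    for label in config.clades.clades:
        taxa = [t for t in leaves if config.clades.assignment[t] == label]
        if not taxa:
            continue
        mrca = tree.mrca(taxa) if len(taxa) > 1 else tree.mrca(taxa)
        mname = tree.node_name(mrca)
        for i in range(p.per_clade):
            fam = f"L{label}{i:03d}"
            plant(fam, f"clade:{label}", taxa, mname)
        if p.per_clade and mrca.parent_node is not None:
            key = (tree.node_name(mrca.parent_node), mname)
            truth.branch_gains[key] = truth.branch_gains.get(key, 0) + p.per_clade
    for species in config.ingroup_species():
        strains = [t for t in ingroup_leaves if config.species_of(t) == species]
        mrca = tree.mrca(strains)
        mname = tree.node_name(mrca)
        for i in range(p.species_orphan):
            fam = f"S{species}{i:03d}"
            plant(fam, f"species_orphan:{species}", strains, mname)
        if p.species_orphan and mrca.parent_node is not None:
            key = (tree.node_name(mrca.parent_node), mname)
            truth.branch_gains[key] = truth.branch_gains.get(key, 0) + p.species_orphan

    members = {
        fam: [(taxon, fam) for taxon in sorted(present)]
        for fam, present in sorted(presence.items())
        if present
    }
    table = ClusterTable.from_members(members, taxa=leaves)
    return table, truth


# ---------------------------------------------------------------------------
# Proteome emission
# ---------------------------------------------------------------------------

def emit_proteomes(
    table: ClusterTable,
    truth: Truth,
    config: SimConfig,
) -> dict[str, Proteome]:
    """One protein per (taxon, present family).

    Each family draws an independent random ancestral sequence at its
    origin node; the copy in each leaf substitutes every site with
    probability 1 - exp(-divergence_scale * path), where path is the
    origin-to-leaf distance in Mya.  Families are mutually unrelated, so
    taxon-restricted families share no similarity with any other protein.
    """
    proteomes = {t: Proteome(taxon_id=t) for t in table.taxa}
    node_by_name = {
        config.tree.node_name(n): n for n in config.tree.tree.preorder_node_iter()
    }
    for fidx, fam in enumerate(table.cluster_ids):
        rng = _rng(config.seed, 1000 + fidx)
        length = max(50, int(rng.poisson(config.mean_protein_len)))
        ancestor = rng.choice(list(AA20), size=length)
        origin = node_by_name[truth.origin_node[fam]]
        for taxon, pid in table.members[fam]:
            path = config.tree.path_length(origin, taxon)
            p_sub = 1.0 - np.exp(-config.divergence_scale * path)
            seq = ancestor.copy()
            if p_sub > 0:
                hits = rng.random(length) < p_sub
                for i in np.nonzero(hits)[0]:
                    alts = [a for a in AA20 if a != seq[i]]
                    seq[i] = alts[rng.integers(len(alts))]
            proteomes[taxon].add(pid, "".join(seq))
    return proteomes


# ---------------------------------------------------------------------------
# SSCP planting
# ---------------------------------------------------------------------------

def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_NO_CYS), size=n)) if n > 0 else ""


def _with_cys_at(rng: np.random.Generator, length: int, cys_pos: Sequence[int]) -> str:
    """Mature region of ``length`` residues with cysteines exactly at the
    given 0-based positions."""
    res = list(_random_residues(rng, length))
    for p in cys_pos:
        res[p] = "C"
    return "".join(res)


def plant_sscp(
    proteome: Proteome,
    counts: PlantedCounts | Mapping[str, int],
    seed: int,
) -> tuple[Proteome, dict[str, str]]:
    """Append planted SSCP-class proteins and decoys to a proteome.

    Returns the proteome (mutated in place) and a protein-id -> truth
    label map with labels hydrophobin / ceratoplatanin / sscp / decoy.
    """
    if isinstance(counts, Mapping):
        counts = PlantedCounts(
            sscp=counts.get("sscp", 0),
            hydrophobin=counts.get("hydrophobin", 0),
            ceratoplatanin=counts.get("ceratoplatanin", 0),
            decoy=counts.get("decoy", 0),
            core=0,
            per_clade=0,
            genus_orphan=0,
            species_orphan=0,
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    labels: dict[str, str] = {}

    def add(pid: str, seq: str, label: str) -> None:
        if len(seq) >= 300 and label != "decoy":
            raise ValueError(f"planted {label} {pid} is {len(seq)} aa (pattern "
                             "impossible below the 300-aa bound at this length)")
        proteome.add(pid, seq)
        labels[pid] = label

    prefix = SIGNAL_PREFIX  # 16 residues, no cysteine

    for i in range(counts.hydrophobin):
        # 8 cysteines with C2/C3 and C6/C7 adjacent; total length ~110 aa
        mature_len = 90 + int(rng.integers(0, 10))
        # inter-cysteine gaps C1-C2 .. C6-C7; zeros make the C2/C3 and
        # C6/C7 adjacent doublets of the class-II pattern
        gaps = [8, 0, 10, 12, 14, 0]
        pos = [5]
        for g in gaps:
            pos.append(pos[-1] + g + 1)
        pos.append(pos[-1] + 9)
        seq = prefix + _with_cys_at(rng, mature_len, pos)
        add(f"hfb_{proteome.taxon_id}_{i:02d}", seq, "hydrophobin")

    for i in range(counts.ceratoplatanin):
        mature_len = 55 + int(rng.integers(0, 8))
        pos = sorted(rng.choice(np.arange(2, mature_len - 2), size=4, replace=False))
        # keep all spacings >= 2 so no accidental CC doublet
        pos = [2, 14, 30, 44]
        seq = prefix + _with_cys_at(rng, mature_len, pos)
        add(f"cp_{proteome.taxon_id}_{i:02d}", seq, "ceratoplatanin")

    for i in range(counts.sscp):
        # generic SSCP: six well-separated cysteines, neither special pattern
        mature_len = 75 + int(rng.integers(0, 15))
        pos = [3, 15, 27, 40, 52, 64]
        seq = prefix + _with_cys_at(rng, mature_len, pos)
        add(f"sscp_{proteome.taxon_id}_{i:02d}", seq, "sscp")

    for i in range(counts.decoy):
        kind = i % 3
        if kind == 0:  # length exactly 300: fails the strict length bound
            mature_len = 300 - len(prefix)
            pos = list(range(4, 4 + 2 * 16, 2))  # 16 cysteines, >= 5%
            seq = prefix + _with_cys_at(rng, mature_len, pos)
        elif kind == 1:  # cysteine-poor: below the 5% fraction
            mature_len = 100
            pos = [10, 40, 70]  # 3 C / 116 aa ~ 2.6%
            seq = prefix + _with_cys_at(rng, mature_len, pos)
        else:  # cysteine-rich but not secreted
            mature_len = 80
            pos = [3, 15, 27, 40, 52, 64]
            seq = NONSECRETED_PREFIX + _with_cys_at(rng, mature_len, pos)
        add(f"decoy_{proteome.taxon_id}_{i:02d}", seq, "decoy")

    return proteome, labels


# ---------------------------------------------------------------------------
# Gene-map layout
# ---------------------------------------------------------------------------

@dataclass
class GenomeLayout:
    """Chromosome layout specification for orphan-geometry fixtures."""

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 4_000_000), ("chr2", 3_000_000)]
    )
    n_singletons: int = 12
    cluster_sizes: dict[int, int] = field(
        default_factory=lambda: {2: 4, 3: 2, 8: 1}
    )
    subtelomeric_fraction: float = 0.10
    gene_len: int = 1_200
    spacing: int = 1_800
    window_bp: int = 100_000

    @property
    def n_orphans(self) -> int:
        return self.n_singletons + sum(s * k for s, k in self.cluster_sizes.items())


def emit_gene_map(
    taxon: str,
    layout: GenomeLayout,
    orphan_ids: Sequence[str] | None,
    seed: int,
) -> tuple[GeneMap, Truth]:
    """Place orphan genes on chromosomes per the layout.

    Orphan runs of the requested sizes are separated by at least one
    non-orphan filler gene; a share of orphan genes matching
    ``layout.subtelomeric_fraction`` (to unit granularity) is placed with
    gene midpoints inside the subtelomeric window at either chromosome
    end.  Truth records the actual planted run-size histogram and
    subtelomeric gene fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    total = layout.n_orphans
    if orphan_ids is None:
        orphan_ids = [f"orph_{i:04d}" for i in range(total)]
    orphan_ids = list(orphan_ids)
    if len(orphan_ids) != total:
        raise ValueError(
            f"layout wants {total} orphan genes but {len(orphan_ids)} ids given"
        )

    units: list[int] = [1] * layout.n_singletons
    for size, k in sorted(layout.cluster_sizes.items()):
        if size < 2:
            raise ValueError("cluster sizes must be >= 2")
        units.extend([size] * k)
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    target_genes = layout.subtelomeric_fraction * total
    sub_flags = []
    placed_sub = 0
    for size in units:
        if placed_sub + size <= target_genes + 1e-9:
            sub_flags.append(True)
            placed_sub += size
        else:
            sub_flags.append(False)

    chrom_ids = [c for c, _ in layout.chromosomes]
    chrom_len = dict(layout.chromosomes)
    step = layout.gene_len + layout.spacing
    cursors = {c: {"sub_start": 2_000, "mid": None, "sub_end": None} for c in chrom_ids}
    genes: list[GeneLocus] = []
    fill_counter = 0
    orphan_iter = iter(orphan_ids)
    truth = Truth()
    placed_orphans: list[str] = []
    n_sub_genes = 0

    def place_gene(chrom: str, zone: str, gene_id: str) -> None:
        nonlocal fill_counter
        cur = cursors[chrom]
        if zone == "sub_end" and cur["sub_end"] is None:
            cur["sub_end"] = chrom_len[chrom] - layout.window_bp + 2_000
        if zone == "mid" and cur["mid"] is None:
            cur["mid"] = layout.window_bp + 200_000
        start = cur[zone]
        end = start + layout.gene_len - 1
        limit = {
            "sub_start": layout.window_bp * 2 - layout.gene_len,  # midpoint <= window
            "mid": chrom_len[chrom] - layout.window_bp - 200_000,
            "sub_end": chrom_len[chrom] - layout.gene_len,
        }[zone]
        if zone == "sub_start" and (start + end) / 2 > layout.window_bp:
            raise ValueError(f"layout infeasible: subtelomeric zone of {chrom} overflows")
        if end > (chrom_len[chrom] if zone == "sub_end" else limit):
            raise ValueError(f"layout infeasible: zone {zone} of {chrom} overflows")
        genes.append(GeneLocus(gene_id, chrom, start, end))
        cur[zone] = start + step

    ci = 0
    side = 0
    for size, is_sub in zip(units, sub_flags):
        chrom = chrom_ids[ci % len(chrom_ids)]
        ci += 1
        if is_sub:
            zone = "sub_start" if side % 2 == 0 else "sub_end"
            side += 1
        else:
            zone = "mid"
        for _ in range(size):
            gid = next(orphan_iter)
            place_gene(chrom, zone, gid)
            placed_orphans.append(gid)
            if is_sub:
                n_sub_genes += 1
        place_gene(chrom, zone, f"fill_{fill_counter:04d}")  # separator
        fill_counter += 1
    # a few extra background genes in each chromosome middle
    for chrom in chrom_ids:
        for _ in range(3):
            place_gene(chrom, "mid", f"fill_{fill_counter:04d}")
            fill_counter += 1

    genemap = GeneMap(taxon, chrom_len, genes)
    hist: dict[int, int] = {}
    for size in units:
        hist[size] = hist.get(size, 0) + 1
    truth.orphan_genes[taxon] = placed_orphans
    truth.run_size_hist[taxon] = hist
    truth.subtelomeric_fraction[taxon] = n_sub_genes / total if total else 0.0
    return genemap, truth


# ---------------------------------------------------------------------------
# Codon pair simulation
# ---------------------------------------------------------------------------

def simulate_codon_pair(
    omega: float,
    t: float,
    kappa: float = 1.0,
    length: int = 300,
    seed: int = 0,
) -> CodonPair:
    """Two sequences diverged from a common ancestor under a codon process.

    ``t`` is the total expected number of proposed mutations per
    nucleotide site separating the pair (split evenly between lineages);
    proposals hitting stop codons are rejected; nonsynonymous proposals
    are accepted with relative probability ``omega`` (synonymous with
    min(1, 1/omega), so the acceptance ratio is omega for any omega > 0);
    ``kappa`` weights transitions over transversions.
    """
    if omega <= 0 or t < 0:
        raise ValueError("omega must be > 0 and t >= 0")
    if length % 3 != 0:
        raise ValueError("length must be divisible by 3")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    n_codons = length // 3
    ancestor = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    from .molevol import CODON_AA

    acc_nonsyn = min(1.0, omega)
    acc_syn = min(1.0, 1.0 / omega)

    def evolve(codons: list[str]) -> list[str]:
        codons = list(codons)
        n_prop = rng.poisson(0.5 * t * length)
        for _ in range(n_prop):
            site = int(rng.integers(length))
            ci, pos = divmod(site, 3)
            codon = codons[ci]
            old = codon[pos]
            ts = transitions[old]
            tvs = [b for b in NT if b != old and b != ts]
            weights = np.array([kappa, 1.0, 1.0])
            weights /= weights.sum()
            new = [ts, tvs[0], tvs[1]][int(rng.choice(3, p=weights))]
            mutated = codon[:pos] + new + codon[pos + 1 :]
            if mutated in STOP_CODONS:
                continue
            if CODON_AA[mutated] == CODON_AA[codon]:
                if acc_syn < 1.0 and rng.random() >= acc_syn:
                    continue
            else:
                if acc_nonsyn < 1.0 and rng.random() >= acc_nonsyn:
                    continue
            codons[ci] = mutated
        return codons

    seq_a = "".join(evolve(ancestor))
    seq_b = "".join(evolve(ancestor))
    return CodonPair(seq_a, seq_b)
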