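"""Domain types and readers/writers for the formats the pipeline touches.

The central object is the :class:`ClusterTable`, a taxon x ortholog-cluster
gene-count matrix with explicit per-cluster membership.  Everything else —
proteomes, clade partitions, dated trees, chromosomal gene maps and aligned
codon pairs — is a thin validated container around standard-library or
Biopython/DendroPy structures.

Coordinate convention: gene-map coordinates are 1-based inclusive (GFF3
convention).  All window arithmetic elsewhere in the package assumes this.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

@dataclass
class Proteome:
    """An ordered set of amino-acid sequences for one taxon.

    Sequences are uppercase over the 20-letter alphabet plus ``X`` for
    unknown residues.  Protein ids are unique within the taxon.
    """

    taxon_id: str
    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"protein {pid!r} contains non-amino-acid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.items())

    def add(self, protein_id: str, sequence: str) -> None:
        if protein_id in self.records:
            raise ValueError(f"duplicate protein id {protein_id!r}")
        seq = sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for protein {protein_id!r}")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {protein_id!r} contains non-amino-acid characters {sorted(bad)}"
            )
        self.records[protein_id] = seq


def read_fasta(path: str | Path, taxon_id: str | None = None) -> Proteome:
    """Read an amino-acid FASTA file into a :class:`Proteome`.

    The token before the first whitespace in each header is the protein id.
    Sequences are uppercased.  Duplicate ids and empty sequences are
    rejected with a diagnostic naming the offending id.
    """
    path = Path(path)
    if taxon_id is None:
        taxon_id = path.stem
    proteome = Proteome(taxon_id=taxon_id)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if rec.id in proteome.records:
            raise FormatError(f"{path}: duplicate protein id {rec.id!r}")
        if not seq:
            raise FormatError(f"{path}: empty sequence for protein {rec.id!r}")
        proteome.add(rec.id, seq)
    return proteome


def write_fasta(proteome: Proteome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in proteome.records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# ClusterTable
# ---------------------------------------------------------------------------

class ClusterTable:
    """Taxon x cluster gene-count matrix with per-cluster membership.

    ``counts[t, c]`` is the number of genes of taxon ``t`` in cluster ``c``.
    Each (taxon, protein) pair appears in at most one cluster.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        cluster_ids: Sequence[str],
        counts: np.ndarray,
        members: Mapping[str, list[tuple[str, str]]],
    ) -> None:
        self.taxa = list(taxa)
        self.cluster_ids = list(cluster_ids)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(self.taxa), len(self.cluster_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.cluster_ids)} clusters"
            )
        if (counts < 0).any():
            raise ValueError("negative counts")
        self.counts = counts
        self.members = {cid: list(members.get(cid, [])) for cid in self.cluster_ids}
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self._cluster_index = {c: j for j, c in enumerate(self.cluster_ids)}
        self._validate()

    def _validate(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for cid, mem in self.members.items():
            per_taxon: dict[str, int] = {}
            for taxon, protein in mem:
                key = (taxon, protein)
                if key in seen:
                    raise ValueError(
                        f"protein {taxon}|{protein} assigned to both "
                        f"{seen[key]} and {cid}"
                    )
                seen[key] = cid
                per_taxon[taxon] = per_taxon.get(taxon, 0) + 1
            j = self._cluster_index[cid]
            for taxon, n in per_taxon.items():
                if taxon not in self._taxon_index:
                    raise ValueError(f"cluster {cid} references unknown taxon {taxon!r}")
                if self.counts[self._taxon_index[taxon], j] != n:
                    raise ValueError(
                        f"cluster {cid}: count for {taxon} is "
                        f"{self.counts[self._taxon_index[taxon], j]} but has {n} members"
                    )
            if int(self.counts[:, j].sum()) != len(mem):
                raise ValueError(f"cluster {cid}: counts do not sum to member count")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_members(
        cls,
        members: Mapping[str, Iterable[tuple[str, str]]],
        taxa: Sequence[str] | None = None,
    ) -> "ClusterTable":
        members = {cid: list(mem) for cid, mem in members.items()}
        if taxa is None:
            seen: list[str] = []
            for mem in members.values():
                for taxon, _ in mem:
                    if taxon not in seen:
                        seen.append(taxon)
            taxa = sorted(seen)
        cluster_ids = list(members)
        counts = np.zeros((len(taxa), len(cluster_ids)), dtype=np.int64)
        tix = {t: i for i, t in enumerate(taxa)}
        for j, cid in enumerate(cluster_ids):
            for taxon, _ in members[cid]:
                counts[tix[taxon], j] += 1
        return cls(taxa, cluster_ids, counts, members)

    # -- accessors ---------------------------------------------------------

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def presence(self) -> np.ndarray:
        """Boolean taxa x clusters matrix: count >= 1."""
        return self.counts > 0

    def count(self, taxon: str, cluster_id: str) -> int:
        return int(self.counts[self._taxon_index[taxon], self._cluster_index[cluster_id]])

    def taxon_total(self, taxon: str) -> int:
        return int(self.counts[self._taxon_index[taxon]].sum())

    def taxon_row(self, taxon: str) -> np.ndarray:
        return self.counts[self._taxon_index[taxon]]

    def collapse(self, mapping: Mapping[str, str], how: str = "max") -> "ClusterTable":
        """Collapse taxa into groups (e.g. strains into species).

        ``how='max'`` keeps the maximum count per group (presence-OR on the
        presence matrix); ``how='sum'`` adds counts.  Membership lists are
        concatenated; protein ids are prefixed with the original taxon to
        keep them unique within the collapsed group.
        """
        groups: list[str] = []
        for t in self.taxa:
            g = mapping.get(t, t)
            if g not in groups:
                groups.append(g)
        counts = np.zeros((len(groups), self.n_clusters), dtype=np.int64)
        gix = {g: i for i, g in enumerate(groups)}
        for t in self.taxa:
            g = mapping.get(t, t)
            row = self.counts[self._taxon_index[t]]
            if how == "sum":
                counts[gix[g]] += row
            else:
                counts[gix[g]] = np.maximum(counts[gix[g]], row)
        members: dict[str, list[tuple[str, str]]] = {cid: [] for cid in self.cluster_ids}
        if how == "sum":
            for cid, mem in self.members.items():
                members[cid] = [(mapping.get(t, t), f"{t}|{p}") for t, p in mem]
        else:
            # max-collapse: membership is no longer count-consistent, keep
            # the argmax strain's members per group as representatives
            for j, cid in enumerate(self.cluster_ids):
                per_group: dict[str, tuple[int, str]] = {}
                for t in self.taxa:
                    g = mapping.get(t, t)
                    c = int(self.counts[self._taxon_index[t], j])
                    if c > per_group.get(g, (0, ""))[0]:
                        per_group[g] = (c, t)
                for g, (_, t) in per_group.items():
                    members[cid].extend(
                        (g, f"{t}|{p}") for tt, p in self.members[cid] if tt == t
                    )
        return ClusterTable(groups, self.cluster_ids, counts, members)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.taxa, columns=self.cluster_ids)


def read_groups(path: str | Path, separator: str = "|") -> ClusterTable:
    """Read OrthoMCL-style groups text: ``clusterID: taxon|protein ...``."""
    path = Path(path)
    members: dict[str, list[tuple[str, str]]] = {}
    assigned: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(f"{path}:{lineno}: missing ':' separator")
            cid, _, rest = line.partition(":")
            cid = cid.strip()
            if not cid:
                raise FormatError(f"{path}:{lineno}: empty cluster id")
            if cid in members:
                raise FormatError(f"{path}:{lineno}: duplicate cluster id {cid!r}")
            mem: list[tuple[str, str]] = []
            for token in rest.split():
                if separator not in token:
                    raise FormatError(
                        f"{path}:{lineno}: token {token!r} lacks "
                        f"taxon{separator}protein separator"
                    )
                taxon, _, protein = token.partition(separator)
                key = (taxon, protein)
                if key in assigned:
                    raise FormatError(
                        f"{path}:{lineno}: protein {token!r} already in "
                        f"cluster {assigned[key]}"
                    )
                assigned[key] = cid
                mem.append((taxon, protein))
            members[cid] = mem
    return ClusterTable.from_members(members)


def write_groups(table: ClusterTable, path: str | Path, separator: str = "|") -> None:
    with open(path, "w") as fh:
        for cid in table.cluster_ids:
            tokens = " ".join(f"{t}{separator}{p}" for t, p in table.members[cid])
            fh.write(f"{cid}: {tokens}\n")


# ---------------------------------------------------------------------------
# CladePartition
# ---------------------------------------------------------------------------

OUTGROUP_LABEL = "OUTGROUP"


@dataclass
class CladePartition:
    """Taxon -> clade assignment with an explicit ingroup.

    Outgroup taxa carry the label ``OUTGROUP``; clade labels for the
    ingroup are free strings (SL / HV / ST in the fungal application).
    """

    assignment: dict[str, str]
    ingroup: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.ingroup:
            self.ingroup = {
                t for t, c in self.assignment.items() if c != OUTGROUP_LABEL
            }
        bad = {t for t in self.ingroup if self.assignment.get(t) == OUTGROUP_LABEL}
        if bad:
            raise ValueError(f"taxa {sorted(bad)} are both ingroup and OUTGROUP")

    @property
    def outgroups(self) -> set[str]:
        return {t for t, c in self.assignment.items() if c == OUTGROUP_LABEL}

    @property
    def clades(self) -> list[str]:
        seen: list[str] = []
        for t, c in self.assignment.items():
            if c != OUTGROUP_LABEL and c not in seen:
                seen.append(c)
        return seen

    def clade_of(self, taxon: str) -> str:
        try:
            return self.assignment[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no clade assignment") from None

    def clade_taxa(self, label: str) -> set[str]:
        return {t for t, c in self.assignment.items() if c == label}

    def validate_taxa(self, taxa: Iterable[str]) -> None:
        missing = [t for t in taxa if t not in self.assignment]
        if missing:
            raise ValueError(f"taxa without clade assignment: {missing}")


def read_clades(path: str | Path) -> CladePartition:
    """Read a 2-column TSV ``taxon<TAB>clade`` (clade OUTGROUP marks outgroups)."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected taxon<TAB>clade")
            if parts[0] == "taxon":  # header row
                continue
            assignment[parts[0]] = parts[1]
    return CladePartition(assignment=assignment)


def write_clades(partition: CladePartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tclade\n")
        for taxon, clade in partition.assignment.items():
            fh.write(f"{taxon}\t{clade}\n")


# ---------------------------------------------------------------------------
# TimeTree
# ---------------------------------------------------------------------------

class TimeTree:
    """A rooted tree whose leaves are taxa and branch lengths are in Mya."""

    def __init__(self, tree: dendropy.Tree) -> None:
        root = tree.seed_node
        if len(root.child_nodes()) > 2 and not tree.is_rooted:
            raise ValueError(
                "tree is unrooted (multifurcating root without rooting tag)"
            )
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue
            if edge.length is None:
                raise ValueError(
                    f"branch above {self._node_name(edge.head_node)} has no length"
                )
            if not math.isfinite(edge.length) or edge.length < 0:
                raise ValueError("branch lengths must be finite and >= 0")
        self.tree = tree
        self._label_internal()

    @staticmethod
    def _node_name(node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or "<internal>"

    def _label_internal(self) -> None:
        i = 0
        for node in self.tree.preorder_node_iter():
            if node.taxon is None and not node.label:
                node.label = f"N{i}"
                i += 1

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def node_name(self, node: dendropy.Node) -> str:
        return self._node_name(node)

    def edges(self) -> list[tuple[dendropy.Node, dendropy.Node, float]]:
        """(parent, child, length) for every non-root edge, preorder."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                out.append((node.parent_node, node, float(node.edge.length)))
        return out

    def mrca(self, taxa: Iterable[str]) -> dendropy.Node:
        labels = list(taxa)
        if len(labels) == 1:
            return self.tree.find_node_with_taxon_label(labels[0])
        return self.tree.mrca(taxon_labels=labels)

    def leaf_path_lengths(self) -> dict[str, float]:
        """Root-to-leaf path length (Mya) per leaf label."""
        depth: dict[int, float] = {id(self.root): 0.0}
        out: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length)
            if node.is_leaf():
                out[node.taxon.label] = depth[id(node)]
        return out

    def path_length(self, node: dendropy.Node, leaf_label: str) -> float:
        """Path length from ``node`` down to the named leaf."""
        leaf = self.tree.find_node_with_taxon_label(leaf_label)
        total = 0.0
        cur = leaf
        while cur is not node:
            if cur.parent_node is None:
                raise ValueError(f"{leaf_label} is not a descendant of {self._node_name(node)}")
            total += float(cur.edge.length)
            cur = cur.parent_node
        return total

    def write_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=False)

    @classmethod
    def from_newick_string(cls, newick: str) -> "TimeTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        if not tree.is_rooted and len(tree.seed_node.child_nodes()) <= 2:
            tree.is_rooted = True
        return cls(tree)


def read_newick(path: str | Path) -> TimeTree:
    """Read a rooted Newick tree with branch lengths in Mya."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    if not tree.is_rooted and len(tree.seed_node.child_nodes()) <= 2:
        tree.is_rooted = True  # bifurcating root: treat as rooted
    return TimeTree(tree)


# ---------------------------------------------------------------------------
# GeneMap
# ---------------------------------------------------------------------------

@dataclass
class GeneLocus:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    ordinal: int = 0  # 1-based index in gene order along the chromosome
    strand: str = "+"

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class GeneMap:
    """Ordered gene loci per chromosome, with chromosome lengths in bp."""

    def __init__(
        self,
        taxon_id: str,
        chromosomes: Mapping[str, int],
        loci: Iterable[GeneLocus],
    ) -> None:
        self.taxon_id = taxon_id
        self.chromosomes = dict(chromosomes)
        loci = list(loci)
        for loc in loci:
            if loc.chrom not in self.chromosomes:
                raise ValueError(f"gene {loc.gene_id}: unknown chromosome {loc.chrom!r}")
            length = self.chromosomes[loc.chrom]
            if not (1 <= loc.start <= loc.end <= length):
                raise ValueError(
                    f"gene {loc.gene_id}: coordinates {loc.start}-{loc.end} "
                    f"outside chromosome {loc.chrom} (length {length})"
                )
        # assign ordinals by start position within each chromosome
        self.loci: dict[str, GeneLocus] = {}
        by_chrom: dict[str, list[GeneLocus]] = {}
        for loc in loci:
            if loc.gene_id in self.loci:
                raise ValueError(f"duplicate gene id {loc.gene_id!r}")
            self.loci[loc.gene_id] = loc
            by_chrom.setdefault(loc.chrom, []).append(loc)
        for chrom, locs in by_chrom.items():
            locs.sort(key=lambda l: (l.start, l.gene_id))
            for i, loc in enumerate(locs, start=1):
                loc.ordinal = i
        self.by_chrom = by_chrom

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.loci

    def __getitem__(self, gene_id: str) -> GeneLocus:
        return self.loci[gene_id]


def read_genemap(path: str | Path, taxon_id: str | None = None) -> GeneMap:
    """Read the gene-map TSV dialect.

    Header section lines ``#chrom <id> <length>`` give chromosome lengths;
    data rows are ``gene_id  chrom  start  end  [strand]`` (1-based
    inclusive).  A ``gene_id``-led header row is skipped if present.
    """
    path = Path(path)
    chromosomes: dict[str, int] = {}
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#chrom"):
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"{path}:{lineno}: expected '#chrom <id> <length>'")
                chromosomes[parts[1]] = int(parts[2])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":
                continue
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected gene_id, chrom, start, end[, strand]"
                )
            strand = parts[4] if len(parts) > 4 else "+"
            try:
                start, end = int(parts[2]), int(parts[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            loci.append(GeneLocus(parts[0], parts[1], start, end, strand=strand))
    try:
        return GeneMap(taxon_id or path.stem, chromosomes, loci)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_genemap(genemap: GeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genemap.chromosomes.items():
            fh.write(f"#chrom {chrom} {length}\n")
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for chrom in genemap.chromosomes:
            for loc in genemap.by_chrom.get(chrom, []):
                fh.write(
                    f"{loc.gene_id}\t{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.strand}\n"
                )


# ---------------------------------------------------------------------------
# CodonPair
# ---------------------------------------------------------------------------

@dataclass
class CodonPair:
    """Two aligned coding nucleotide sequences (length divisible by 3).

    Gap characters ``-`` are allowed; codons containing a gap or ambiguous
    base in either sequence are excluded from analysis.  Internal stop
    codons are rejected.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        n_codons = len(self.seq_a) // 3
        for name, seq in (("a", self.seq_a), ("b", self.seq_b)):
            for i in range(n_codons):
                codon = seq[3 * i : 3 * i + 3]
                if codon in STOP_CODONS and i < n_codons - 1:
                    raise ValueError(
                        f"internal stop codon {codon} at codon {i + 1} in sequence {name}"
                    )

    def codons(self) -> list[tuple[str, str]]:
        """Comparable codon pairs: both codons gap-free ACGT, neither a stop."""
        out = []
        for i in range(len(self.seq_a) // 3):
            ca = self.seq_a[3 * i : 3 * i + 3]
            cb = self.seq_b[3 * i : 3 * i + 3]
            if set(ca) <= set("ACGT") and set(cb) <= set("ACGT"):
                if ca not in STOP_CODONS and cb not in STOP_CODONS:
                    out.append((ca, cb))
        return out


def read_codon_pairs(path: str | Path) -> list[tuple[str, CodonPair]]:
    """Read consecutive pairs of records from a nucleotide FASTA as CodonPairs."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise FormatError(f"{path}: odd number of records; expected aligned pairs")
    pairs = []
    for i in range(0, len(records), 2):
        a, b = records[i], records[i + 1]
        pairs.append((f"{a.id}~{b.id}", CodonPair(str(a.seq), str(b.seq))))
    return pairs
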