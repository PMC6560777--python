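"""Small secreted cysteine-rich protein (SSCP) classification.

A protein qualifies as an SSCP when it is shorter than 300 residues
(strict), contains at least 5% cysteine (inclusive), and is secreted.
Within the qualifying set, class-II-type hydrophobins carry exactly eight
cysteines with the 2nd/3rd and 6th/7th forming adjacent CC doublets, and
cerato-platanins carry exactly four cysteines.  Remaining qualifiers are
generic SSCPs.  Classes are mutually exclusive with precedence
hydrophobin > cerato-platanin > sscp.

Secretion is decided by a deterministic N-terminal signal-peptide
heuristic, or overridden by externally supplied per-protein calls
(e.g. from a dedicated predictor) when provided.

Unknown residues (X) are excluded from cysteine counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .io_core import Proteome

HYDROPHOBIC = frozenset("AILMFVW")
SMALL = frozenset("AGS")

MAX_LEN = 300
MIN_CYS_FRAC = 0.05


@dataclass
class SSCPRecord:
    protein_id: str
    length: int
    n_cys: int
    cys_positions: tuple[int, ...]  # 1-based
    secreted: bool
    secretion_source: str  # "heuristic" | "external"
    passes_filter: bool
    label: str  # "hydrophobin" | "ceratoplatanin" | "sscp" | "none"

    @property
    def cys_fraction(self) -> float:
        return self.n_cys / self.length


def predict_signal_peptide(sequence: str) -> bool:
    """Deterministic stand-in for an N-terminal signal-peptide predictor.

    True iff, within the first 30 residues: (i) at least one K/R occurs in
    positions 1-5 (the positively charged n-region); (ii) a window of 8
    consecutive residues inside positions 6-25 has >= 6 hydrophobic
    residues (A,I,L,M,F,V,W — the h-region); (iii) small residues (A,G,S)
    occupy positions -3 and -1 relative to a cleavage site placed three
    residues after the first such hydrophobic window ends.

    Sequences shorter than 25 residues return False.
    """
    seq = sequence.upper()
    if len(seq) < 25:
        return False
    head = seq[:30]
    if not any(c in "KR" for c in head[:5]):
        return False
    # positions are 1-based; window of 8 must lie within positions 6..25
    for w_start in range(6, 25 - 8 + 2):  # 1-based start, window fits in 6..25
        window = head[w_start - 1 : w_start + 7]
        if len(window) < 8:
            break
        if sum(c in HYDROPHOBIC for c in window) >= 6:
            cleavage = w_start + 7 + 4  # first position after window, plus 3
            if cleavage > len(seq):
                return False
            m3, m1 = cleavage - 3, cleavage - 1
            return seq[m3 - 1] in SMALL and seq[m1 - 1] in SMALL
    return False


def sscp_filter(
    protein_id: str,
    sequence: str,
    max_len: int = MAX_LEN,
    min_cys_frac: float = MIN_CYS_FRAC,
    secreted: bool | None = None,
) -> SSCPRecord:
    """Apply the SSCP size/composition/secretion filter to one protein.

    Passes iff length < ``max_len`` (strict), cysteine fraction >=
    ``min_cys_frac`` (inclusive), and the protein is secreted.  The
    cysteine fraction is n_cys / length with X residues excluded from the
    numerator.  ``secreted=None`` invokes the heuristic; an explicit
    boolean records an external call.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError(f"empty sequence for protein {protein_id!r}")
    positions = tuple(i + 1 for i, c in enumerate(seq) if c == "C")
    length = len(seq)
    if secreted is None:
        is_secreted = predict_signal_peptide(seq)
        source = "heuristic"
    else:
        is_secreted = bool(secreted)
        source = "external"
    passes = (
        length < max_len
        and len(positions) / length >= min_cys_frac
        and is_secreted
    )
    record = SSCPRecord(
        protein_id=protein_id,
        length=length,
        n_cys=len(positions),
        cys_positions=positions,
        secreted=is_secreted,
        secretion_source=source,
        passes_filter=passes,
        label="none",
    )
    if passes:
        if classify_hydrophobin(record):
            record.label = "hydrophobin"
        elif classify_ceratoplatanin(record):
            record.label = "ceratoplatanin"
        else:
            record.label = "sscp"
    return record


def classify_hydrophobin(record: SSCPRecord) -> bool:
    """Class-II-type hydrophobin pattern: exactly 8 cysteines with C2/C3
    and C6/C7 directly adjacent (CC doublets)."""
    if record.n_cys != 8:
        return False
    c = record.cys_positions
    return c[2] == c[1] + 1 and c[6] == c[5] + 1


def classify_ceratoplatanin(record: SSCPRecord) -> bool:
    """Cerato-platanin pattern: exactly 4 cysteines (homology confirmation
    against a reference database is out of scope)."""
    return record.n_cys == 4


def read_secretion_calls(path: str | Path) -> dict[str, bool]:
    """Read external per-protein secretion calls: TSV ``protein_id<TAB>0|1``
    (or true/false/yes/no)."""
    calls: dict[str, bool] = {}
    truthy = {"1", "true", "yes", "y", "secreted"}
    falsy = {"0", "false", "no", "n", "not_secreted"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected protein_id<TAB>call")
            val = parts[1].strip().lower()
            if val in truthy:
                calls[parts[0]] = True
            elif val in falsy:
                calls[parts[0]] = False
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized call {parts[1]!r}")
    return calls


def classify_proteome(
    proteome: Proteome,
    secretion_calls: Mapping[str, bool] | None = None,
    max_len: int = MAX_LEN,
    min_cys_frac: float = MIN_CYS_FRAC,
) -> list[SSCPRecord]:
    records = []
    for pid, seq in proteome.records.items():
        ext = secretion_calls.get(pid) if secretion_calls else None
        records.append(
            sscp_filter(pid, seq, max_len=max_len, min_cys_frac=min_cys_frac, secreted=ext)
        )
    return records


def sscp_census(
    proteomes: Mapping[str, Proteome] | Proteome,
    secretion_calls: Mapping[str, Mapping[str, bool]] | None = None,
    max_len: int = MAX_LEN,
    min_cys_frac: float = MIN_CYS_FRAC,
) -> pd.DataFrame:
    """Per-taxon counts of sscp / hydrophobin / cerato-platanin classes."""
    if isinstance(proteomes, Proteome):
        proteomes = {proteomes.taxon_id: proteomes}
    rows = []
    for taxon in sorted(proteomes):
        calls = secretion_calls.get(taxon) if secretion_calls else None
        records = classify_proteome(
            proteomes[taxon], calls, max_len=max_len, min_cys_frac=min_cys_frac
        )
        counts = {"sscp": 0, "hydrophobin": 0, "ceratoplatanin": 0}
        for rec in records:
            if rec.label in counts:
                counts[rec.label] += 1
        rows.append({"taxon": taxon, **counts})
    return pd.DataFrame(rows)


def spacing_profile(record: SSCPRecord) -> tuple[int, ...]:
    """Inter-cysteine spacings (residues between consecutive cysteines),
    emitted for manual inspection of hydrophobin subtypes."""
    c = record.cys_positions
    return tuple(c[i + 1] - c[i] - 1 for i in range(len(c) - 1))
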