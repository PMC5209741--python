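"""Alignment-level diversity statistics and simple indel coding.

Implements the classical quantities used to contrast functional and
pseudogene ITS copies: variable and parsimony-informative site counts, the
average number of pairwise nucleotide differences k, and nucleotide
diversity Pi (per-site average of pairwise differences).  Ambiguity codes
are treated as missing throughout; the default deletion policy is complete
deletion (any column holding a gap or ambiguity is excluded globally), with
pairwise deletion available by option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core import ALIGNED_ALPHABET, InputError, ItsScreenError

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Alignment:
    """A rectangular gapped alignment with optional functional-class labels."""

    ids: list[str]
    seqs: list[str]
    class_labels: dict[str, str] | None = None  # clone_id -> {F, P}

    def __post_init__(self) -> None:
        if not self.seqs:
            raise InputError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise InputError(f"ragged alignment: row lengths {sorted(lengths)}")
        for cid, seq in zip(self.ids, self.seqs):
            bad = set(seq) - ALIGNED_ALPHABET
            if bad:
                raise InputError(f"row {cid!r}: non-IUPAC characters {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    @property
    def column_count(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        return np.array([np.frombuffer(s.encode(), dtype="S1") for s in self.seqs])

    def subset(self, ids: list[str]) -> "Alignment":
        index = {cid: i for i, cid in enumerate(self.ids)}
        rows = [index[c] for c in ids]
        return Alignment([self.ids[i] for i in rows], [self.seqs[i] for i in rows],
                         class_labels=self.class_labels)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        return Alignment(self.ids, [s[start:end] for s in self.seqs],
                         class_labels=self.class_labels)

    @classmethod
    def from_fasta(cls, path: str | Path, class_labels: dict[str, str] | None = None) -> "Alignment":
        ids, seqs = [], []
        for record in SeqIO.parse(str(path), "fasta"):
            ids.append(record.id)
            seqs.append(str(record.seq).upper().replace("U", "T"))
        return cls(ids, seqs, class_labels=class_labels)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cid, seq in zip(self.ids, self.seqs):
                fh.write(f">{cid}\n{seq}\n")


@dataclass
class DiversityStats:
    n_sequences: int
    length_used: int
    S: int                  # variable sites
    PI: int                 # parsimony-informative sites
    k: float                # mean pairwise differences
    Pi: float               # nucleotide diversity per site
    pct_variable: float = field(init=False)
    pct_informative: float = field(init=False)

    def __post_init__(self) -> None:
        self.pct_variable = round(100.0 * self.S / self.length_used, 1) if self.length_used else 0.0
        self.pct_informative = round(100.0 * self.PI / self.length_used, 1) if self.length_used else 0.0


def _base_counts(arr: np.ndarray) -> np.ndarray:
    """Per-column counts of A/C/G/T (shape 4 × n_columns)."""
    return np.array([(arr == b).sum(axis=0) for b in _BASES])


def count_site_classes(alignment: Alignment) -> tuple[int, int, int, tuple[float, float]]:
    """Count variable and parsimony-informative sites.

    A site is variable iff at least two distinct unambiguous bases occur
    (gaps and ambiguity codes ignored); parsimony-informative iff at least
    two distinct bases each occur in at least two sequences.

    Returns ``(S, PI, length, (pct_variable, pct_informative))`` with
    percentages rounded to 1 decimal.
    """
    if alignment.n_sequences < 2:
        raise ItsScreenError("count_site_classes needs >= 2 sequences")
    length = alignment.column_count
    if length == 0:
        raise ItsScreenError("alignment of length 0")
    counts = _base_counts(alignment.to_array())
    S = int((((counts > 0).sum(axis=0)) >= 2).sum())
    PI = int((((counts >= 2).sum(axis=0)) >= 2).sum())
    return S, PI, length, (round(100.0 * S / length, 1), round(100.0 * PI / length, 1))


def pairwise_diversity(alignment: Alignment, deletion_policy: str = "complete") -> DiversityStats:
    """Average pairwise differences k and nucleotide diversity Pi.

    Under complete deletion (default) every column holding a gap or an
    ambiguity code in any sequence is excluded globally, so Pi equals
    k / length_used exactly.  Under pairwise deletion each pair is compared
    over its own unambiguous columns and Pi is the mean of per-pair
    difference fractions.
    """
    if alignment.n_sequences < 2:
        raise ItsScreenError("pairwise_diversity needs >= 2 sequences")
    if deletion_policy not in {"complete", "pairwise"}:
        raise ValueError(f"unknown deletion policy {deletion_policy!r}")
    arr = alignment.to_array()
    unambiguous = np.isin(arr, _BASES)

    if deletion_policy == "complete":
        used = unambiguous.all(axis=0)
        if not used.any():
            raise ItsScreenError("no comparable sites under complete deletion")
        sub = arr[:, used]
        n = sub.shape[0]
        diffs = [np.count_nonzero(sub[i] != sub[j]) for i, j in combinations(range(n), 2)]
        k = float(np.mean(diffs))
        length_used = int(used.sum())
        pi = k / length_used
        sub_aln = Alignment(alignment.ids, ["".join(row.astype(str)) for row in sub.astype("U1")])
        S, PI, _, _ = count_site_classes(sub_aln)
    else:
        n = arr.shape[0]
        diffs, ratios = [], []
        for i, j in combinations(range(n), 2):
            comparable = unambiguous[i] & unambiguous[j]
            m = int(comparable.sum())
            if m == 0:
                raise ItsScreenError(f"no comparable sites between rows {i} and {j}")
            d = int(np.count_nonzero(arr[i, comparable] != arr[j, comparable]))
            diffs.append(d)
            ratios.append(d / m)
        k = float(np.mean(diffs))
        pi = float(np.mean(ratios))
        length_used = alignment.column_count
        S, PI, _, _ = count_site_classes(alignment)

    return DiversityStats(n_sequences=alignment.n_sequences, length_used=length_used,
                          S=S, PI=PI, k=k, Pi=pi)


def class_contrast(alignment: Alignment,
                   labels: dict[str, str] | None = None,
                   regions: dict[str, tuple[int, int]] | None = None,
                   deletion_policy: str = "complete") -> dict[str, dict[str, DiversityStats | None]]:
    """Diversity per functional class (F/P) and alignment partition.

    ``regions`` maps partition names to 0-based half-open column intervals;
    default is the entire alignment under the name "ITS".  A class with
    fewer than 2 members yields ``None`` cells.
    """
    labels = labels if labels is not None else alignment.class_labels
    if not labels:
        raise ItsScreenError("class_contrast requires F/P labels")
    regions = regions or {"ITS": (0, alignment.column_count)}
    by_class = {"F": [c for c in alignment.ids if labels.get(c) == "F"],
                "P": [c for c in alignment.ids if labels.get(c) == "P"]}
    if not by_class["F"] and not by_class["P"]:
        raise ItsScreenError("no labelled sequences")

    table: dict[str, dict[str, DiversityStats | None]] = {}
    for name, (start, end) in regions.items():
        table[name] = {}
        window = alignment.slice_columns(start, end)
        for cls, members in by_class.items():
            if len(members) < 2:
                table[name][cls] = None
                continue
            try:
                table[name][cls] = pairwise_diversity(window.subset(members), deletion_policy)
            except ItsScreenError:
                table[name][cls] = None
    return table


def render_contrast_table(table: dict[str, dict[str, DiversityStats | None]],
                          *, header: str | None = None) -> str:
    """Render the per-region F/P contrast as TSV (regions × classes × {Pi, k})."""
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append("region\tclass\tn\tlength_used\tS\tPI\tk\tPi")
    for region, cells in table.items():
        for cls in ("F", "P"):
            stats = cells.get(cls)
            if stats is None:
                lines.append(f"{region}\t{cls}\tNA\tNA\tNA\tNA\tNA\tNA")
            else:
                lines.append(
                    f"{region}\t{cls}\t{stats.n_sequences}\t{stats.length_used}\t"
                    f"{stats.S}\t{stats.PI}\t{stats.k:.3f}\t{stats.Pi:.3f}"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Simple indel coding

def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def simple_indel_code(alignment: Alignment) -> tuple[list[tuple[int, int]], list[list[str]]]:
    """Code alignment gaps as binary characters (simple indel coding).

    Each distinct gap (identical start and end, 0-based half-open) becomes
    one character, ordered by (start, end).  A sequence scores "1" iff it
    carries exactly that gap, "0" iff it has contiguous bases across the
    span, and "?" when one of its gaps strictly contains or partially
    overlaps the span.

    Returns ``(characters, matrix)`` with one matrix row per sequence.
    """
    per_row_runs = [set(_gap_runs(s)) for s in alignment.seqs]
    characters = sorted(set().union(*per_row_runs)) if per_row_runs else []
    matrix: list[list[str]] = []
    for seq, runs in zip(alignment.seqs, per_row_runs):
        row = []
        for start, end in characters:
            if (start, end) in runs:
                row.append("1")
            elif "-" not in seq[start:end]:
                row.append("0")
            else:
                row.append("?")
        matrix.append(row)
    return characters, matrix


def render_indel_matrix(alignment: Alignment, *, header: str | None = None) -> str:
    """Indel characters as TSV, columns named g<start+1>_<end> (1-based inclusive)."""
    characters, matrix = simple_indel_code(alignment)
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append("clone_id\t" + "\t".join(f"g{a + 1}_{b}" for a, b in characters))
    for cid, row in zip(alignment.ids, matrix):
        lines.append(cid + "\t" + "\t".join(row))
    return "\n".join(lines) + "\n"


def render_indel_nexus(alignment: Alignment) -> str:
    """Indel characters as a NEXUS-style standard characters block."""
    characters, matrix = simple_indel_code(alignment)
    width = max((len(c) for c in alignment.ids), default=1) + 2
    lines = [
        "#NEXUS",
        "BEGIN CHARACTERS;",
        f"  DIMENSIONS NCHAR={len(characters)};",
        '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
        "  MATRIX",
    ]
    for cid, row in zip(alignment.ids, matrix):
        lines.append(f"    {cid:<{width}}{''.join(row)}")
    lines.extend(["  ;", "END;"])
    return "\n".join(lines) + "\n"
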