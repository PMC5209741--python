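"""Reading and writing of clone sets, sample maps and partition tables.

FASTA parsing goes through Biopython; plain and gzip-compressed files are
accepted.  Clone-to-sample mapping defaults to stripping the trailing
``-<cloneNumber>`` from the record ID (``L.bicolor-1-3`` → sample
``L.bicolor-1``), overridable by an explicit two-column TSV map.
"""

from __future__ import annotations

import gzip
import json
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .core import InputError, ItsClone, Partition, REGION_NAMES

_CLONE_SUFFIX = re.compile(r"-\d+$")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def derive_sample_id(clone_id: str) -> str:
    """Strip a trailing ``-<number>`` clone counter from a clone ID."""
    stripped = _CLONE_SUFFIX.sub("", clone_id)
    return stripped if stripped else clone_id


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (clone_id, sample_id); '#' lines are comments."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if fields[0] in mapping:
                raise InputError(f"{path}:{lineno}: duplicate clone_id {fields[0]!r}")
            mapping[fields[0]] = fields[1]
    return mapping


def read_clones(fasta_path: str | Path, sample_map_path: str | Path | None = None) -> list[ItsClone]:
    """Read a clone FASTA into :class:`ItsClone` records, order preserved.

    Sequences are uppercased and U→T normalized.  Sample membership comes
    from the map file when given, otherwise from the ID-pattern rule.

    Raises
    ------
    InputError
        on an empty file, a duplicated record ID, or a clone absent from an
        explicit sample map.
    """
    mapping = read_sample_map(sample_map_path) if sample_map_path is not None else None
    clones: list[ItsClone] = []
    seen: set[str] = set()
    with _open_text(fasta_path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in seen:
                raise InputError(f"duplicate FASTA record ID {record.id!r}")
            seen.add(record.id)
            if mapping is not None:
                if record.id not in mapping:
                    raise InputError(f"clone {record.id!r} missing from sample map")
                sample_id = mapping[record.id]
            else:
                sample_id = derive_sample_id(record.id)
            clones.append(ItsClone(record.id, sample_id, str(record.seq)))
    if not clones:
        raise InputError(f"no FASTA records in {fasta_path}")
    return clones


def write_clones(clones: Iterable[ItsClone], path: str | Path) -> None:
    with open(path, "w") as fh:
        for clone in clones:
            fh.write(f">{clone.clone_id}\n{clone.sequence}\n")


def write_sample_map(clones: Iterable[ItsClone], path: str | Path) -> None:
    with open(path, "w") as fh:
        for clone in clones:
            fh.write(f"{clone.clone_id}\t{clone.sample_id}\n")


# ---------------------------------------------------------------------------
# Partition tables (BED-like TSV, 0-based half-open; and JSON)

def write_partitions_tsv(clones: Iterable[ItsClone], path: str | Path, *, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("clone_id\tregion\tstart\tend\n")
        for clone in clones:
            if clone.partition is None:
                continue
            for region in REGION_NAMES:
                a, b = clone.partition.region(region)
                fh.write(f"{clone.clone_id}\t{region}\t{a}\t{b}\n")


def write_partitions_json(clones: Iterable[ItsClone], path: str | Path) -> None:
    payload = {}
    for clone in clones:
        if clone.partition is None:
            continue
        p = clone.partition
        payload[clone.clone_id] = {
            "ITS1": list(p.its1),
            "5.8S": list(p.s58),
            "ITS2": list(p.its2),
            "truncated_left": p.truncated_left,
            "truncated_right": p.truncated_right,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_partitions_json(path: str | Path) -> dict[str, Partition]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        cid: Partition(
            tuple(d["ITS1"]), tuple(d["5.8S"]), tuple(d["ITS2"]),
            truncated_left=d.get("truncated_left", False),
            truncated_right=d.get("truncated_right", False),
        )
        for cid, d in payload.items()
    }


def read_class_labels(path: str | Path) -> dict[str, str]:
    """Read a clone_id → functional-class (F|P) TSV."""
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or fields[1] not in {"F", "P"}:
                raise InputError(f"{path}:{lineno}: expected 'clone_id<TAB>F|P'")
            labels[fields[0]] = fields[1]
    return labels
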