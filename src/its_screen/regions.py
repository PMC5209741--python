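"""Region delimiting and haplotype bookkeeping for clone sets.

ITS1/5.8S/ITS2 boundaries are anchored by the best local alignments of three
reference blocks (18S tail, 5.8S gene, 26S head); the aligned 5.8S span,
extended by any unaligned reference stubs, becomes the 5.8S interval.  A
missing flank sets a truncation flag and the boundary falls at the sequence
end.
"""

from __future__ import annotations

from ._align import locate_anchor
from .core import CollapseResult, DelimitError, InputError, ItsClone, Partition, ReferenceSet

#: Minimum penalized identity (alignment score / reference length) for the
#: 5.8S anchor; unrelated sequence scores near 0 under this measure.
S58_IDENTITY_FLOOR = 0.5
#: Below this, a flank anchor is considered absent (truncated clone).
FLANK_IDENTITY_FLOOR = 0.5


def delimit_regions(clone: ItsClone, refs: ReferenceSet) -> Partition:
    """Delimit ITS1/5.8S/ITS2 on an ungapped clone.

    Raises
    ------
    DelimitError
        if the 5.8S anchor aligns below the identity floor (default 50%),
        or a region would come out empty.
    """
    seq = clone.sequence
    if "-" in seq:
        raise InputError(f"clone {clone.clone_id!r}: gapped sequence cannot be delimited")

    hit = locate_anchor(refs.ref_5_8S, seq)
    if hit is None or hit.identity < S58_IDENTITY_FLOOR:
        raise DelimitError(
            f"clone {clone.clone_id!r}: cannot delimit (5.8S anchor identity "
            f"{0.0 if hit is None else hit.identity:.2f} < {S58_IDENTITY_FLOOR})"
        )
    # Extend the aligned span by unaligned reference stubs so terminal
    # substitutions trimmed off by the local alignment do not shift boundaries.
    s58_start = max(0, hit.target_start - hit.ref_start)
    s58_end = min(len(seq), hit.target_end + (hit.ref_length - hit.ref_end))

    truncated_left = truncated_right = False

    left = seq[:s58_start]
    tail_hit = locate_anchor(refs.ref_18S_tail, left)
    if tail_hit is not None and tail_hit.identity >= FLANK_IDENTITY_FLOOR:
        its1_start = min(s58_start, tail_hit.target_end + (tail_hit.ref_length - tail_hit.ref_end))
    else:
        its1_start = 0
        truncated_left = True

    right = seq[s58_end:]
    head_hit = locate_anchor(refs.ref_26S_head, right)
    if head_hit is not None and head_hit.identity >= FLANK_IDENTITY_FLOOR:
        its2_end = s58_end + max(0, head_hit.target_start - head_hit.ref_start)
    else:
        its2_end = len(seq)
        truncated_right = True

    if its1_start >= s58_start:
        raise DelimitError(f"clone {clone.clone_id!r}: cannot delimit (empty ITS1)")
    if its2_end <= s58_end:
        raise DelimitError(f"clone {clone.clone_id!r}: cannot delimit (empty ITS2)")

    return Partition(
        its1=(its1_start, s58_start),
        s58=(s58_start, s58_end),
        its2=(s58_end, its2_end),
        truncated_left=truncated_left,
        truncated_right=truncated_right,
    )


def delimit_all(clones: list[ItsClone], refs: ReferenceSet) -> list[ItsClone]:
    """Delimit every clone in place; returns the same list for chaining."""
    for clone in clones:
        clone.partition = delimit_regions(clone, refs)
    return clones


def collapse_distinct(clones: list[ItsClone]) -> CollapseResult:
    """Group clones by exact sequence identity (haplotype collapse).

    Group order follows the first occurrence of each distinct sequence.
    """
    groups: dict[str, list[str]] = {}
    for clone in clones:
        groups.setdefault(clone.sequence, []).append(clone.clone_id)
    members = list(groups.values())
    return CollapseResult(n_total=len(clones), n_distinct=len(members), groups=members)


def region_length_summary(clones: list[ItsClone]) -> dict[str, dict]:
    """Min/max lengths (bp) per region with the clone IDs attaining them.

    Reports ITS1, 5.8S, ITS2, the entire ITS region (ITS1 start through ITS2
    end) and the total clone length including flanks.
    """
    if not clones:
        raise InputError("no clones")
    if any(c.partition is None for c in clones):
        raise InputError("all clones must be delimited before length summary")

    def lengths(clone: ItsClone) -> dict[str, int]:
        p = clone.partition
        a, b = p.entire
        return {
            "ITS1": p.length("ITS1"),
            "5.8S": p.length("5.8S"),
            "ITS2": p.length("ITS2"),
            "entire": b - a,
            "total": len(clone.sequence),
        }

    summary: dict[str, dict] = {}
    for region in ("ITS1", "5.8S", "ITS2", "entire", "total"):
        best_min = best_max = None
        for clone in clones:
            n = lengths(clone)[region]
            if best_min is None or n < best_min[0]:
                best_min = (n, clone.clone_id)
            if best_max is None or n > best_max[0]:
                best_max = (n, clone.clone_id)
        summary[region] = {
            "min": best_min[0], "min_clone": best_min[1],
            "max": best_max[0], "max_clone": best_max[1],
        }
    return summary
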