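"""Thin pairwise-alignment helpers shared by region delimiting and the
5.8S motif/helix checks (Biopython ``PairwiseAligner`` underneath).

Two primitives are needed:

* a *local* anchor search: where does a short reference block (18S tail,
  5.8S gene, 26S head) sit on a clone;
* a *global* alignment image: a per-position map from reference 5.8S
  coordinates onto a clone's 5.8S, through which motif spans and forced
  helix pairs are projected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # Affine gaps: opening costs 2, extending 0.5, so the long deletions seen
    # in decayed rDNA copies are bridged rather than splitting the anchor.
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner

_LOCAL = _make_aligner("local")
_GLOBAL = _make_aligner("global")


@dataclass(frozen=True)
class AnchorHit:
    """Best local placement of a reference block on a target sequence."""

    target_start: int
    target_end: int
    ref_start: int
    ref_end: int
    matches: int
    ref_length: int
    score: float = 0.0

    @property
    def identity(self) -> float:
        """Penalized identity: alignment score over the full reference length.

        Mismatches and gaps subtract from the score, so an unrelated target
        scores near 0 even though cheap gap extension lets it collect raw
        matches; a true anchor stays close to its raw match fraction.
        """
        return max(0.0, self.score) / self.ref_length if self.ref_length else 0.0


def _count_matches(alignment, target: str, ref: str) -> int:
    t_blocks, r_blocks = alignment.aligned
    matches = 0
    for (ts, te), (rs, re) in zip(t_blocks, r_blocks):
        matches += sum(a == b for a, b in zip(target[ts:te], ref[rs:re]))
    return matches


def locate_anchor(ref: str, target: str) -> AnchorHit | None:
    """Locally align ``ref`` within ``target``; ``None`` if nothing aligns."""
    if not target or not ref:
        return None
    alignments = _LOCAL.align(target, ref)
    if alignments.score <= 0:
        return None
    alignment = alignments[0]
    t_blocks, r_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return None
    return AnchorHit(
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
        ref_start=int(r_blocks[0][0]),
        ref_end=int(r_blocks[-1][1]),
        matches=_count_matches(alignment, target, ref),
        ref_length=len(ref),
        score=float(alignments.score),
    )


def global_map(ref: str, query: str) -> tuple[float, np.ndarray]:
    """Globally align ``query`` to ``ref``.

    Returns ``(identity, image)`` where ``identity`` is the fraction of
    reference positions matched and ``image[i]`` is the 0-based query index
    aligned to reference position ``i`` (-1 where the reference position
    falls in a query gap).
    """
    image = np.full(len(ref), -1, dtype=int)
    if not query:
        return 0.0, image
    alignment = _GLOBAL.align(ref, query)[0]
    indices = alignment.indices  # shape (2, n_columns); -1 marks gaps
    ref_idx, query_idx = indices[0], indices[1]
    both = (ref_idx >= 0) & (query_idx >= 0)
    image[ref_idx[both]] = query_idx[both]
    matches = sum(ref[i] == query[j] for i, j in zip(ref_idx[both], query_idx[both]))
    identity = matches / len(ref)
    return identity, image
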