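"""Chimeric-clone detection: similarity profiles and a MaxChi-style
maximum chi-squared breakpoint test with a permutation null.

For a (child, parent A, parent B) triplet of aligned sequences, the
informative sites are the columns where the parents disagree and the child
matches exactly one of them.  A recombination breakpoint shows up as a
discontinuity in the run of matched parents along those sites; the MaxChi
statistic slides a window over the informative-site sequence, splits it in
half, and takes the maximum 2×2 chi-squared of (side × matched parent).
Significance comes from random permutations of the match labels, which is
the exact exchangeability null and automatically accounts for the
maximization over split positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import ItsScreenError

MIN_INFORMATIVE_SITES = 8


@dataclass(frozen=True)
class ScanConfig:
    window: int = 30          # bp for similarity windows; informative sites for MaxChi
    step: int = 5             # bp between similarity windows
    permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 10:
            raise ValueError("window must be >= 10")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.permutations < 100:
            raise ValueError("permutations must be >= 100")


@dataclass
class ChimeraReport:
    child_id: str
    parent_a_id: str
    parent_b_id: str
    breakpoint: int | None      # 1-based alignment column of the estimated crossover
    max_chi2: float
    p_value: float
    n_informative: int
    verdict: str = "clean"      # recombinant | clean
    reason: str = ""
    p_corrected: float | None = None
    profile: "SimilarityProfile | None" = None


@dataclass
class SimilarityProfile:
    """Per-window percent identity of the child to each parent (NaN = masked)."""

    window_starts: np.ndarray   # 0-based column of each window start
    to_parent_a: np.ndarray
    to_parent_b: np.ndarray


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype="S1")


def _comparable(*rows: np.ndarray) -> np.ndarray:
    mask = np.ones(rows[0].shape, dtype=bool)
    allowed = np.frombuffer(b"ACGT", dtype="S1")
    for row in rows:
        mask &= np.isin(row, allowed)
    return mask


def similarity_profile(child: str, parent_a: str, parent_b: str,
                       config: ScanConfig = ScanConfig()) -> SimilarityProfile:
    """Sliding-window percent identity of the child to each parent.

    Only columns where child and parent are both unambiguous count; windows
    with fewer than 50% comparable sites are masked (NaN).
    """
    if not (len(child) == len(parent_a) == len(parent_b)):
        raise ItsScreenError("similarity_profile requires equal-length aligned sequences")
    c, a, b = _encode(child), _encode(parent_a), _encode(parent_b)
    length = len(child)
    starts, id_a, id_b = [], [], []
    for start in range(0, length - config.window + 1, config.step):
        sl = slice(start, start + config.window)
        out = []
        for parent in (a, b):
            mask = _comparable(c[sl], parent[sl])
            m = int(mask.sum())
            if m < config.window / 2:
                out.append(np.nan)
            else:
                out.append(100.0 * np.count_nonzero(c[sl][mask] == parent[sl][mask]) / m)
        starts.append(start)
        id_a.append(out[0])
        id_b.append(out[1])
    profile = SimilarityProfile(np.array(starts), np.array(id_a), np.array(id_b))
    if np.isnan(profile.to_parent_a).all() and np.isnan(profile.to_parent_b).all():
        raise ItsScreenError("all similarity windows are masked")
    return profile


def informative_sites(child: str, parent_a: str, parent_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Columns where the parents disagree and the child matches exactly one.

    Returns ``(columns, labels)``: 0-based column indices and a 0/1 vector
    (1 = child matches parent A).
    """
    c, a, b = _encode(child), _encode(parent_a), _encode(parent_b)
    mask = _comparable(c, a, b) & (a != b) & ((c == a) | (c == b))
    cols = np.flatnonzero(mask)
    labels = (c[cols] == a[cols]).astype(np.int64)
    return cols, labels


def _chi2_2x2(left_ones: np.ndarray, half: int, total_ones: np.ndarray, window: int) -> np.ndarray:
    """Chi-squared of the (side × matched parent) 2×2 table, no continuity
    correction; 0 where a margin is empty."""
    a = left_ones                    # left, parent A
    b = half - a                     # left, parent B
    c = total_ones - a               # right, parent A
    d = (window - half) - c          # right, parent B
    num = window * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    return chi2.astype(float)


def _max_chi2_scan(labels: np.ndarray, half: int) -> tuple[float, int]:
    """Max chi-squared over all sliding-window splits; returns (stat, split).

    ``split`` is the informative-site index of the first right-side site of
    the maximizing window.
    """
    n = len(labels)
    prefix = np.concatenate([[0], np.cumsum(labels)])
    centers = np.arange(half, n - half + 1)
    left_ones = prefix[centers] - prefix[centers - half]
    total_ones = prefix[centers + half] - prefix[centers - half]
    chi2 = _chi2_2x2(left_ones, half, total_ones, 2 * half)
    best = int(np.argmax(chi2))
    return float(chi2[best]), int(centers[best])


def _max_chi2_null(labels: np.ndarray, half: int, permutations: int,
                   rng: np.random.Generator) -> np.ndarray:
    n = len(labels)
    perm = np.tile(labels, (permutations, 1))
    perm = rng.permuted(perm, axis=1)
    prefix = np.concatenate([np.zeros((permutations, 1), dtype=np.int64),
                             np.cumsum(perm, axis=1)], axis=1)
    centers = np.arange(half, n - half + 1)
    left_ones = prefix[:, centers] - prefix[:, centers - half]
    total_ones = prefix[:, centers + half] - prefix[:, centers - half]
    chi2 = _chi2_2x2(left_ones, half, total_ones, 2 * half)
    return chi2.max(axis=1)


def maxchi_breakpoint(child: str, parent_a: str, parent_b: str,
                      config: ScanConfig = ScanConfig(),
                      *, child_id: str = "child", parent_a_id: str = "parentA",
                      parent_b_id: str = "parentB",
                      rng: np.random.Generator | None = None,
                      attach_profile: bool = False) -> ChimeraReport:
    """MaxChi permutation test for one aligned triplet.

    The window is measured in informative sites (half to each side of a
    candidate split).  ``p_value`` is the fraction of label permutations
    whose maximum chi-squared reaches the observed one; the verdict is
    recombinant iff ``p_value <= config.alpha``.
    """
    if not (len(child) == len(parent_a) == len(parent_b)):
        raise ItsScreenError("maxchi_breakpoint requires equal-length aligned sequences")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cols, labels = informative_sites(child, parent_a, parent_b)
    report = ChimeraReport(child_id, parent_a_id, parent_b_id, breakpoint=None,
                           max_chi2=0.0, p_value=1.0, n_informative=len(cols))
    if attach_profile:
        report.profile = similarity_profile(child, parent_a, parent_b, config)
    if len(cols) < MIN_INFORMATIVE_SITES:
        report.reason = "insufficient signal"
        return report

    half = max(2, min(config.window // 2, len(labels) // 2))
    stat, split = _max_chi2_scan(labels, half)
    null = _max_chi2_null(labels, half, config.permutations, rng)
    p = float(np.count_nonzero(null >= stat) / config.permutations)

    report.max_chi2 = stat
    report.p_value = p
    # Crossover estimate: the alignment column midway between the informative
    # sites flanking the maximizing split (1-based).
    report.breakpoint = int((cols[split - 1] + cols[split]) // 2) + 1
    if p <= config.alpha:
        report.verdict = "recombinant"
    return report


def _identity(x: np.ndarray, y: np.ndarray) -> float:
    mask = _comparable(x, y)
    m = int(mask.sum())
    return np.count_nonzero(x[mask] == y[mask]) / m if m else 0.0


def scan_dataset(alignment_ids: list[str], alignment_seqs: list[str],
                 config: ScanConfig = ScanConfig(),
                 candidate_parents: list[str] | None = None,
                 max_pairs: int = 200) -> list[ChimeraReport]:
    """Scan every clone of an aligned set for chimeric origin.

    For each child the candidate parents (default: all distinct other
    clones) are ranked by identity to the child, the closest pairs are
    enumerated up to ``max_pairs``, and the minimum-p report is kept.  A
    Bonferroni correction across children is applied on top of the raw
    per-child p-value; the verdict uses the corrected value.
    """
    encoded = {cid: _encode(s) for cid, s in zip(alignment_ids, alignment_seqs)}
    seqs = dict(zip(alignment_ids, alignment_seqs))
    # distinct sequences only: duplicates of the child are useless parents
    first_of_seq: dict[str, str] = {}
    for cid in alignment_ids:
        first_of_seq.setdefault(seqs[cid], cid)
    distinct_ids = list(first_of_seq.values())

    # number of candidates whose pairings stay within the pair cap
    m = 2
    while (m + 1) * m // 2 <= max_pairs:
        m += 1

    reports: list[ChimeraReport] = []
    for child_index, child_id in enumerate(alignment_ids):
        rng = np.random.default_rng([config.seed, child_index])
        candidates = [c for c in (candidate_parents or distinct_ids)
                      if c != child_id and seqs[c] != seqs[child_id]]
        ranked = sorted(
            candidates,
            key=lambda c: (-_identity(encoded[child_id], encoded[c]), c),
        )[:m]
        best: ChimeraReport | None = None
        for pa, pb in combinations(ranked, 2):
            report = maxchi_breakpoint(
                seqs[child_id], seqs[pa], seqs[pb], config,
                child_id=child_id, parent_a_id=pa, parent_b_id=pb, rng=rng,
            )
            if best is None or (report.p_value, report.reason) < (best.p_value, best.reason):
                best = report
        if best is None:
            best = ChimeraReport(child_id, "", "", None, 0.0, 1.0, 0,
                                 reason="no candidate parents")
        reports.append(best)

    n_children = len(reports)
    for report in reports:
        report.p_corrected = min(1.0, report.p_value * n_children)
        significant = (not report.reason) and report.p_corrected <= config.alpha
        report.verdict = "recombinant" if significant else "clean"

    # Event attribution: a MaxChi signal belongs to the whole triplet, so a
    # parent of a genuine chimera also lights up when the chimera sits in
    # its best pair.  Attribute each event to the strongest signal: demote a
    # call whose best pair contains another called clone with a strictly
    # greater max chi-squared.
    initially_called = {r.child_id: r.max_chi2 for r in reports if r.verdict == "recombinant"}
    for report in reports:
        if report.child_id not in initially_called:
            continue
        for member in (report.parent_a_id, report.parent_b_id):
            if initially_called.get(member, -1.0) > report.max_chi2:
                report.verdict = "clean"
                report.reason = f"signal attributed to {member}"
                break
    return reports


def render_scan_table(reports: list[ChimeraReport], *, header: str | None = None) -> str:
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append("child\tparent_a\tparent_b\tn_informative\tbreakpoint\tmax_chi2\tp_raw\tp_corrected\tverdict\treason")
    for r in reports:
        bp = "NA" if r.breakpoint is None else str(r.breakpoint)
        pc = "NA" if r.p_corrected is None else f"{r.p_corrected:.4g}"
        lines.append(
            f"{r.child_id}\t{r.parent_a_id}\t{r.parent_b_id}\t{r.n_informative}\t{bp}\t"
            f"{r.max_chi2:.3f}\t{r.p_value:.4g}\t{pc}\t{r.verdict}\t{r.reason}"
        )
    return "\n".join(lines) + "\n"


def render_profile_table(report: ChimeraReport, *, header: str | None = None) -> str:
    """Per-window similarity profile of one triplet as TSV (for plotting)."""
    if report.profile is None:
        raise ItsScreenError("report carries no profile; rerun with attach_profile=True")
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append("window_start\tidentity_to_parent_a\tidentity_to_parent_b")
    p = report.profile
    for start, ia, ib in zip(p.window_starts, p.to_parent_a, p.to_parent_b):
        fa = "NA" if np.isnan(ia) else f"{ia:.2f}"
        fb = "NA" if np.isnan(ib) else f"{ib:.2f}"
        lines.append(f"{int(start) + 1}\t{fa}\t{fb}")
    return "\n".join(lines) + "\n"
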