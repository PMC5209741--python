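"""Pseudogene evidence screen: GC profiles, conserved 5.8S motifs, helix
foldability, and the combined functional/pseudogene verdict.

Three independent evidence streams are computed per clone, mirroring how
rDNA pseudogenes are diagnosed in the plant literature:

* per-region GC content, flagged when clearly below the within-sample
  baseline (methylation-driven C→T / G→A deamination erodes GC in
  non-functional copies);
* the three angiosperm-invariant 5.8S motifs M1/M2/M3, scanned for
  substitutions or missing spans;
* foldability of the five conserved 5.8S helices B4–B8, tested as a
  deterministic base-pairing feasibility check (Watson–Crick or G·U wobble
  at every forced reference pair, projected onto the clone through a global
  alignment) rather than by free-energy minimization.

A clone is called a pseudogene when any criterion triggers (OR policy,
configurable minimum count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from ._align import global_map
from .core import (
    ItsClone,
    ItsScreenError,
    PAIRING,
    ReferenceSet,
    UNAMBIGUOUS,
)

# ---------------------------------------------------------------------------
# Published constants

#: Angiosperm-conserved 5.8S motifs (5'→3').
MOTIFS: dict[str, str] = {
    "M1": "CGATGAAGAACGTAGC",
    "M2": "GAATTGCAGAATCC",
    "M3": "TTTGAACGCA",
}

#: Forced base-pair blocks of the five conserved 5.8S helices.  Each block
#: (i, j, k) pairs reference positions i..i+k-1 with j..j-k+1 (1-based).
HELIX_CONSTRAINTS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "B4": ((45, 105, 3),),
    "B5": ((48, 61, 3),),
    "B6": ((69, 96, 3),),
    "B7": ((110, 118, 3),),
    "B8": ((119, 142, 4), (126, 135, 3)),
}

HELIX_ORDER = ("B4", "B5", "B6", "B7", "B8")

#: Identity floor below which a 5.8S cannot be aligned for helix checks.
HELIX_ALIGN_FLOOR = 0.40

#: Default GC deficit (percentage points) that triggers a low-GC flag.
DEFAULT_DELTA_PP = 2.0


def forced_pairs(helix: str) -> list[tuple[int, int]]:
    """All (i, j) forced 1-based reference position pairs of one helix."""
    pairs = []
    for i, j, k in HELIX_CONSTRAINTS[helix]:
        for t in range(k):
            pairs.append((i + t, j - t))
    return pairs


# ---------------------------------------------------------------------------
# Evidence records

@dataclass
class MotifReport:
    name: str
    status: str  # conserved | changed | partially_missing | all_missing
    change_positions: list[int] = field(default_factory=list)  # 1-based in motif
    missing_range: tuple[int, int] | None = None  # 1-based inclusive

    def format(self) -> str:
        """Render in the evidence-table notation ("nt-7,12", "missing 4-16")."""
        if self.status == "conserved":
            return "conserved"
        if self.status == "all_missing":
            return "all missing"
        parts = []
        if self.change_positions:
            parts.append("nt-" + ",".join(str(p) for p in self.change_positions))
        if self.missing_range is not None:
            parts.append(f"missing {self.missing_range[0]}-{self.missing_range[1]}")
        return "; ".join(parts)


@dataclass
class GcProfile:
    its1_pct: float
    s58_pct: float
    its2_pct: float
    flags: set[str] = field(default_factory=set)  # subset of {ITS1, 5.8S, ITS2}

    def pct(self, region: str) -> float:
        return {"ITS1": self.its1_pct, "5.8S": self.s58_pct, "ITS2": self.its2_pct}[region]


@dataclass
class PseudogeneEvidence:
    clone_id: str
    sample_id: str
    gc: GcProfile
    motifs: dict[str, MotifReport]
    helix_pattern: str
    verdict: str = "functional"
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Operations

def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases only, 0–100.

    Ambiguity codes and gaps are excluded from numerator and denominator.
    """
    counts = {b: 0 for b in "ACGT"}
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ItsScreenError("gc_content: no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / total


def scan_motif(s58_seq: str, name: str, refs: ReferenceSet) -> MotifReport:
    """Scan a clone 5.8S (gaps stripped) for one conserved motif.

    An exact substring hit is conserved regardless of context.  Otherwise the
    motif's span on the reference 5.8S is projected onto the clone through a
    global alignment; substitutions are reported 1-based within the motif and
    positions falling in clone gaps are reported missing.
    """
    motif = MOTIFS[name]
    s58_seq = s58_seq.replace("-", "")
    if s58_seq.count(motif) >= 1:
        return MotifReport(name, "conserved")

    offset = refs.ref_5_8S.find(motif)  # ReferenceSet invariant: exactly one hit
    if offset < 0:
        raise ItsScreenError(f"reference 5.8S lacks motif {name}")
    _, image = global_map(refs.ref_5_8S, s58_seq)

    changes: list[int] = []
    missing: list[int] = []
    for k, want in enumerate(motif):
        q = image[offset + k]
        if q < 0:
            missing.append(k + 1)
        elif s58_seq[q] != want:
            changes.append(k + 1)
    if len(missing) == len(motif):
        return MotifReport(name, "all_missing")
    if missing:
        return MotifReport(
            name, "partially_missing",
            change_positions=changes,
            missing_range=(min(missing), max(missing)),
        )
    if changes:
        return MotifReport(name, "changed", change_positions=changes)
    return MotifReport(name, "conserved")


def check_helices(s58_seq: str, refs: ReferenceSet,
                  constraints: dict | None = None) -> tuple[str, bool]:
    """Test foldability of helices B4–B8 on a clone 5.8S.

    Returns ``(pattern, aligned_ok)`` where ``pattern`` is the 5-character
    B4..B8 string over {X, -}: a helix scores "X" iff every forced reference
    pair projects onto two non-gap clone bases forming a Watson–Crick or G·U
    pair.  If the clone cannot be aligned to the reference (identity < 40%)
    all helices score "-" and ``aligned_ok`` is False.
    """
    constraints = constraints or HELIX_CONSTRAINTS
    s58_seq = s58_seq.replace("-", "")
    identity, image = global_map(refs.ref_5_8S, s58_seq)
    if identity < HELIX_ALIGN_FLOOR:
        return "-" * len(constraints), False

    pattern = []
    for helix in HELIX_ORDER:
        ok = True
        for i, j, k in constraints[helix]:
            for t in range(k):
                qi, qj = image[i + t - 1], image[j - t - 1]
                if qi < 0 or qj < 0 or (s58_seq[qi], s58_seq[qj]) not in PAIRING:
                    ok = False
        pattern.append("X" if ok else "-")
    return "".join(pattern), True


def _is_clean(motifs: dict[str, MotifReport], helix_pattern: str) -> bool:
    return all(m.status == "conserved" for m in motifs.values()) and "-" not in helix_pattern


def flag_low_gc(evidences: list[PseudogeneEvidence], delta_pp: float = DEFAULT_DELTA_PP) -> None:
    """Set per-region low-GC flags in place (two-pass, within-sample baseline).

    The baseline per sample and region is the median GC of co-sample clones
    that pass the motif and helix criteria; if none pass, all co-sample
    clones define it; samples with fewer than 3 clones fall back to the
    global median.  A clone is flagged in a region iff its GC is more than
    ``delta_pp`` percentage points below the baseline.
    """
    if delta_pp <= 0:
        raise ItsScreenError("delta_pp must be > 0")
    by_sample: dict[str, list[PseudogeneEvidence]] = {}
    for ev in evidences:
        by_sample.setdefault(ev.sample_id, []).append(ev)

    clean_all = [ev for ev in evidences if _is_clean(ev.motifs, ev.helix_pattern)]
    global_pool = clean_all if clean_all else evidences

    for region in ("ITS1", "5.8S", "ITS2"):
        global_baseline = median(ev.gc.pct(region) for ev in global_pool)
        for sample, members in by_sample.items():
            if len(members) < 3:
                baseline = global_baseline
            else:
                clean = [ev for ev in members if _is_clean(ev.motifs, ev.helix_pattern)]
                pool = clean if clean else members
                baseline = median(ev.gc.pct(region) for ev in pool)
            for ev in members:
                if ev.gc.pct(region) < baseline - delta_pp:
                    ev.gc.flags.add(region)


def classify_clone(evidence: PseudogeneEvidence, min_criteria: int = 1) -> PseudogeneEvidence:
    """Combine evidence streams into a verdict (in place; returns evidence).

    Default policy: pseudogene iff at least one criterion triggers — a
    low-GC region, a non-conserved motif, or an unfoldable helix.  Raising
    ``min_criteria`` demands that many triggered criteria.
    """
    reasons: list[str] = []
    for region in sorted(evidence.gc.flags):
        reasons.append(f"low_gc:{region}")
    for name in ("M1", "M2", "M3"):
        report = evidence.motifs[name]
        if report.status != "conserved":
            reasons.append(f"motif:{name}:{report.format()}")
    for helix, state in zip(HELIX_ORDER, evidence.helix_pattern):
        if state == "-":
            reasons.append(f"helix:{helix}")
    evidence.reasons = reasons
    evidence.verdict = "pseudogene" if len(reasons) >= min_criteria else "functional"
    return evidence


def screen_clones(clones: list[ItsClone], refs: ReferenceSet, *,
                  delta_pp: float = DEFAULT_DELTA_PP,
                  min_criteria: int = 1) -> list[PseudogeneEvidence]:
    """Run the full evidence screen on delimited clones."""
    evidences: list[PseudogeneEvidence] = []
    for clone in clones:
        if clone.partition is None:
            raise ItsScreenError(f"clone {clone.clone_id!r} is not delimited")
        p = clone.partition
        gc = GcProfile(
            its1_pct=gc_content(p.extract(clone.sequence, "ITS1")),
            s58_pct=gc_content(p.extract(clone.sequence, "5.8S")),
            its2_pct=gc_content(p.extract(clone.sequence, "ITS2")),
        )
        s58 = p.extract(clone.sequence, "5.8S")
        motifs = {name: scan_motif(s58, name, refs) for name in ("M1", "M2", "M3")}
        pattern, _ = check_helices(s58, refs)
        evidences.append(PseudogeneEvidence(
            clone_id=clone.clone_id, sample_id=clone.sample_id,
            gc=gc, motifs=motifs, helix_pattern=pattern,
        ))
    flag_low_gc(evidences, delta_pp=delta_pp)
    for ev in evidences:
        classify_clone(ev, min_criteria=min_criteria)
    return evidences


# ---------------------------------------------------------------------------
# Evidence table rendering (one row per clone, flags as '*' suffixes)

_TABLE_COLUMNS = ("clone_id", "sample_id", "gc_its1", "gc_5.8s", "gc_its2",
                  "m1", "m2", "m3", "helices", "verdict")


def render_evidence_table(evidences: list[PseudogeneEvidence], *, header: str | None = None) -> str:
    """Render evidence records as TSV text.

    GC values print to 2 decimals with a ``*`` suffix replacing the
    literature's boldface for flagged regions; motif columns use the
    ``conserved`` / ``nt-…`` / ``missing i-j`` / ``all missing`` notation.
    """
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append("\t".join(_TABLE_COLUMNS))
    for ev in evidences:
        cells = [ev.clone_id, ev.sample_id]
        for region in ("ITS1", "5.8S", "ITS2"):
            star = "*" if region in ev.gc.flags else ""
            cells.append(f"{ev.gc.pct(region):.2f}{star}")
        for name in ("M1", "M2", "M3"):
            cells.append(ev.motifs[name].format())
        cells.append(ev.helix_pattern)
        cells.append(ev.verdict)
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def _parse_motif_cell(name: str, cell: str) -> MotifReport:
    if cell == "conserved":
        return MotifReport(name, "conserved")
    if cell == "all missing":
        return MotifReport(name, "all_missing")
    changes: list[int] = []
    missing: tuple[int, int] | None = None
    for part in cell.split("; "):
        if part.startswith("nt-"):
            changes = [int(x) for x in part[3:].split(",")]
        elif part.startswith("missing "):
            a, b = part[len("missing "):].split("-")
            missing = (int(a), int(b))
    status = "partially_missing" if missing is not None else "changed"
    return MotifReport(name, status, change_positions=changes, missing_range=missing)


def parse_evidence_table(text: str) -> list[PseudogeneEvidence]:
    """Inverse of :func:`render_evidence_table` (round-trip stable)."""
    evidences = []
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    for line in rows[1:]:
        cells = line.split("\t")
        flags = set()
        pcts = []
        for region, cell in zip(("ITS1", "5.8S", "ITS2"), cells[2:5]):
            if cell.endswith("*"):
                flags.add(region)
                cell = cell[:-1]
            pcts.append(float(cell))
        gc = GcProfile(*pcts, flags=flags)
        motifs = {name: _parse_motif_cell(name, cell)
                  for name, cell in zip(("M1", "M2", "M3"), cells[5:8])}
        ev = PseudogeneEvidence(
            clone_id=cells[0], sample_id=cells[1], gc=gc, motifs=motifs,
            helix_pattern=cells[8], verdict=cells[9],
        )
        classify_clone(ev)  # rebuild reasons; verdict recomputed identically
        evidences.append(ev)
    return evidences
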