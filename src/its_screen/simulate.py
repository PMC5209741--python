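"""Synthetic rDNA clone-set generator with ground-truth labels.

The generator emulates the statistical structure the screening pipeline
assumes, without any sequence download:

* a functional ITS1–5.8S–ITS2 unit: a synthetic 5.8S (~160 bp, GC ≈ 54%)
  carrying the three conserved motifs exactly once each and satisfying all
  forced helix pairs by construction, flanked by GC-rich spacers (≈ 62%)
  and short 18S/26S stubs;
* functional clones: low substitution rate, with the 5.8S (and flanks) held
  near-invariant by purifying selection;
* pseudogene clones: an elevated substitution rate everywhere plus a
  CpG-deamination overlay (substitutions hitting C/G in CpG or GpC context
  are biased to C→T / G→A, eroding GC), explicit motif and helix lesions,
  and geometric-length deletions;
* recombinant clones: spliced from two divergent (pseudogene-grade) parent
  clones at a recorded breakpoint.

Indels are modelled as deletions only (matching the large published ITS
deletions), so every emitted clone has an exact gapped row in ancestral
coordinates and the generator can emit a true alignment directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import COMPLEMENT, ItsClone, ItsScreenError, Partition, ReferenceSet
from .diversity import Alignment
from .screen import HELIX_CONSTRAINTS, HELIX_ORDER, MOTIFS, PAIRING, forced_pairs

DEFAULT_REFERENCE_SEED = 7

_BASES = np.array(list("ACGT"))

#: Fixed 1-based offsets of the motifs on the synthetic reference 5.8S.
_MOTIF_OFFSETS = {"M1": 10, "M2": 27, "M3": 75}
_S58_LENGTH = 160
_ITS1_LENGTH = 230
_ITS2_LENGTH = 210
_FLANK_LENGTH = 25


# ---------------------------------------------------------------------------
# Reference construction

@dataclass(frozen=True)
class ReferenceUnit:
    """Synthetic ancestral ITS unit plus the anchor ReferenceSet."""

    refs: ReferenceSet
    sequence: str            # 18S tail + ITS1 + 5.8S + ITS2 + 26S head
    partition: Partition     # region intervals on the ancestral sequence

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        """Alignment-column intervals (0-based half-open), incl. entire ITS."""
        p = self.partition
        return {"ITS1": p.its1, "5.8S": p.s58, "ITS2": p.its2, "ITS": p.entire}


def _draw(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at]))


def make_reference_unit(seed: int = DEFAULT_REFERENCE_SEED) -> ReferenceUnit:
    """Build the synthetic constraint-satisfying reference unit.

    The 5.8S carries M1/M2/M3 exactly once each, in order, at fixed offsets,
    and every forced helix pair is Watson–Crick by construction.  Two calls
    with the same seed return identical sequences.
    """
    rng = np.random.default_rng(seed)
    s58 = None
    for _ in range(100):
        candidate = list(_draw(rng, _S58_LENGTH, gc=0.54))
        for name, offset in _MOTIF_OFFSETS.items():
            motif = MOTIFS[name]
            candidate[offset - 1:offset - 1 + len(motif)] = list(motif)
        for helix in HELIX_ORDER:
            for i, j in forced_pairs(helix):
                candidate[j - 1] = COMPLEMENT[candidate[i - 1]]
        text = "".join(candidate)
        if all(text.count(MOTIFS[name]) == 1 for name in MOTIFS):
            s58 = text
            break
    if s58 is None:  # pragma: no cover - astronomically unlikely
        raise ItsScreenError("could not build a motif-unique reference 5.8S")

    its1 = _draw(rng, _ITS1_LENGTH, gc=0.62)
    its2 = _draw(rng, _ITS2_LENGTH, gc=0.62)
    tail = _draw(rng, _FLANK_LENGTH, gc=0.50)
    head = _draw(rng, _FLANK_LENGTH, gc=0.50)

    sequence = tail + its1 + s58 + its2 + head
    a = _FLANK_LENGTH
    b = a + _ITS1_LENGTH
    c = b + _S58_LENGTH
    d = c + _ITS2_LENGTH
    partition = Partition(its1=(a, b), s58=(b, c), its2=(c, d))
    refs = ReferenceSet(ref_5_8S=s58, ref_18S_tail=tail, ref_26S_head=head)
    return ReferenceUnit(refs=refs, sequence=sequence, partition=partition)


# ---------------------------------------------------------------------------
# Simulation parameters and truth records

@dataclass(frozen=True)
class SimParams:
    """Generator settings; every stochastic call is driven by ``seed``.

    ``base_rate`` is substitutions/site for functional spacers;
    functional 5.8S and flanks mutate at ``base_rate × s58_rate_factor``
    (purifying selection).  Pseudogenes mutate at
    ``base_rate × pseudo_rate_multiplier`` everywhere, with the CpG
    deamination overlay, and may additionally receive explicit motif
    lesions, helix-pair disruptions and deletions.  ``indel_rate`` is the
    expected number of deletions per pseudogene clone.
    """

    n_samples: int = 10
    clones_per_sample: int = 10
    base_rate: float = 0.005
    pseudo_rate_multiplier: float = 5.0
    cpg_transition_bias: float = 0.8
    pseudo_fraction: float = 0.3
    recombinant_fraction: float = 0.05
    indel_rate: float = 0.2
    deletion_mean_length: float = 8.0
    motif_lesion_prob: float = 0.8
    helix_lesion_prob: float = 0.6
    s58_rate_factor: float = 0.075
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.base_rate, self.pseudo_rate_multiplier, self.indel_rate) < 0:
            raise ItsScreenError("rates must be >= 0")
        for name in ("cpg_transition_bias", "pseudo_fraction", "recombinant_fraction",
                     "motif_lesion_prob", "helix_lesion_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ItsScreenError(f"{name} must lie in [0, 1]")
        if self.pseudo_fraction + self.recombinant_fraction > 1.0:
            raise ItsScreenError("pseudo_fraction + recombinant_fraction exceeds 1")
        if self.n_samples < 1 or self.clones_per_sample < 1:
            raise ItsScreenError("need at least one sample and one clone per sample")


@dataclass
class SimTruth:
    clone_id: str
    label: str                      # functional | pseudogene | recombinant
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None   # 1-based alignment column, last parent-A column
    lesions: list[str] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    clones: list[ItsClone]
    truth: dict[str, SimTruth]
    alignment: Alignment            # gapped rows in ancestral coordinates
    regions: dict[str, tuple[int, int]]
    reference: ReferenceUnit
    params: SimParams

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for clone in self.clones:
                fh.write(f">{clone.clone_id}\n{clone.sequence}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("clone_id\tlabel\tparent_a\tparent_b\tbreakpoint\tlesions\n")
            for clone in self.clones:
                t = self.truth[clone.clone_id]
                fh.write(
                    f"{t.clone_id}\t{t.label}\t{t.parent_a or 'NA'}\t{t.parent_b or 'NA'}\t"
                    f"{t.breakpoint if t.breakpoint is not None else 'NA'}\t"
                    f"{';'.join(t.lesions) or 'NA'}\n"
                )

    def write_regions_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("region\tstart\tend\n")
            for name, (a, b) in self.regions.items():
                fh.write(f"{name}\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Mutation machinery

def _cpg_context(sequence: str) -> np.ndarray:
    """True where a C or G sits in a CpG or GpC dinucleotide."""
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    is_c, is_g = arr == b"C", arr == b"G"
    g_right = np.concatenate([is_g[1:], [False]])
    g_left = np.concatenate([[False], is_g[:-1]])
    c_right = np.concatenate([is_c[1:], [False]])
    c_left = np.concatenate([[False], is_c[:-1]])
    return (is_c & (g_right | g_left)) | (is_g & (c_right | c_left))


def mutate_sequence(sequence: str, rates, rng: np.random.Generator,
                    cpg_bias: float = 0.0) -> str:
    """Apply independent per-site substitutions.

    ``rates`` is a scalar or a per-site array of substitution probabilities.
    With ``cpg_bias`` > 0, a substitution hitting a C/G in CpG or GpC
    context becomes the deamination product (C→T, G→A) with that
    probability; all other substitutions pick uniformly among the three
    alternative bases.
    """
    arr = np.array(list(sequence))
    length = len(sequence)
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (length,))
    hits = np.flatnonzero(rng.random(length) < rates)
    if hits.size == 0:
        return sequence
    context = _cpg_context(sequence) if cpg_bias > 0 else None
    for i in hits:
        base = arr[i]
        if context is not None and context[i] and rng.random() < cpg_bias:
            arr[i] = "T" if base == "C" else "A"
        else:
            choices = [b for b in "ACGT" if b != base]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _rate_profile(unit: ReferenceUnit, spacer_rate: float, conserved_rate: float) -> np.ndarray:
    rates = np.full(len(unit.sequence), conserved_rate)
    for region in ("ITS1", "ITS2"):
        a, b = unit.partition.region(region)
        rates[a:b] = spacer_rate
    return rates


def _inject_motif_lesion(row: list[str], unit: ReferenceUnit,
                         rng: np.random.Generator) -> list[str]:
    name = ("M1", "M2", "M3")[rng.integers(3)]
    motif = MOTIFS[name]
    s58_start = unit.partition.s58[0]
    n_hits = int(rng.integers(1, 3))
    positions = sorted(rng.choice(len(motif), size=n_hits, replace=False))
    records = []
    for pos in positions:
        col = s58_start + _MOTIF_OFFSETS[name] - 1 + pos
        current = row[col]
        choices = [b for b in "ACGT" if b != current]
        row[col] = choices[rng.integers(3)]
        records.append(f"motif:{name}:nt-{pos + 1}")
    return records


def _inject_helix_lesion(row: list[str], unit: ReferenceUnit,
                         rng: np.random.Generator) -> list[str]:
    helix = HELIX_ORDER[rng.integers(len(HELIX_ORDER))]
    pairs = forced_pairs(helix)
    i, j = pairs[rng.integers(len(pairs))]
    s58_start = unit.partition.s58[0]
    col_i, col_j = s58_start + i - 1, s58_start + j - 1
    partner = row[col_j]
    current = row[col_i]
    non_pairing = [b for b in "ACGT" if b != current
                   and (partner == "-" or (b, partner) not in PAIRING)]
    if non_pairing:
        row[col_i] = non_pairing[rng.integers(len(non_pairing))]
    return [f"helix:{helix}"]


def _inject_deletions(row: list[str], params: SimParams,
                      rng: np.random.Generator) -> list[str]:
    records = []
    n_del = rng.poisson(params.indel_rate)
    length = len(row)
    for _ in range(n_del):
        size = int(rng.geometric(1.0 / params.deletion_mean_length))
        size = min(size, length // 4)
        start = int(rng.integers(_FLANK_LENGTH, length - _FLANK_LENGTH - size))
        row[start:start + size] = ["-"] * size
        records.append(f"deletion:{start + 1}-{start + size}")
    return records


def _ungapped_partition(row: str, partition: Partition) -> Partition | None:
    """Project ancestral-coordinate region intervals onto the ungapped clone."""
    present = np.array([ch != "-" for ch in row])
    prefix = np.concatenate([[0], np.cumsum(present)])

    def project(interval):
        a, b = interval
        return int(prefix[a]), int(prefix[b])

    try:
        return Partition(
            its1=project(partition.its1),
            s58=project(partition.s58),
            its2=project(partition.its2),
        )
    except ValueError:  # a region was deleted entirely
        return None


# ---------------------------------------------------------------------------
# Clone-set simulation

def simulate_clone_set(params: SimParams,
                       reference: ReferenceUnit | None = None) -> SimulatedDataset:
    """Generate a labelled clone set (clones, truth, true alignment).

    Deterministic given ``params.seed``: the same parameters always emit
    byte-identical FASTA and truth tables.
    """
    unit = reference if reference is not None else make_reference_unit()
    rng = np.random.default_rng(params.seed)
    ancestor = unit.sequence

    functional_rates = _rate_profile(unit, params.base_rate,
                                     params.base_rate * params.s58_rate_factor)
    pseudo_rate = params.base_rate * params.pseudo_rate_multiplier

    n_total = params.n_samples * params.clones_per_sample
    n_recomb = int(round(n_total * params.recombinant_fraction))
    n_pseudo = int(round(n_total * params.pseudo_fraction))
    labels = (["recombinant"] * n_recomb + ["pseudogene"] * n_pseudo
              + ["functional"] * (n_total - n_recomb - n_pseudo))
    rng.shuffle(labels)

    slots = [(f"S{s + 1:02d}", i + 1)
             for s in range(params.n_samples) for i in range(params.clones_per_sample)]

    rows: dict[str, str] = {}
    order: list[str] = []
    truth: dict[str, SimTruth] = {}
    recombinant_slots: list[tuple[str, str]] = []

    for (sample, index), label in zip(slots, labels):
        clone_id = f"{sample}-{index}"
        order.append(clone_id)
        if label == "recombinant":
            recombinant_slots.append((clone_id, sample))
            continue
        if label == "functional":
            rows[clone_id] = mutate_sequence(ancestor, functional_rates, rng)
            truth[clone_id] = SimTruth(clone_id, "functional")
        else:
            row = list(mutate_sequence(ancestor, pseudo_rate, rng,
                                       cpg_bias=params.cpg_transition_bias))
            lesions: list[str] = []
            if rng.random() < params.motif_lesion_prob:
                lesions += _inject_motif_lesion(row, unit, rng)
            if rng.random() < params.helix_lesion_prob:
                lesions += _inject_helix_lesion(row, unit, rng)
            lesions += _inject_deletions(row, params, rng)
            rows[clone_id] = "".join(row)
            truth[clone_id] = SimTruth(clone_id, "pseudogene", lesions=lesions)

    # Recombinants: splice two divergent parents (preferably pseudogene
    # clones from different samples, mirroring how chimeric rDNA copies
    # mostly arise between already-divergent paralogs).
    pseudo_ids = [cid for cid in order if cid in truth and truth[cid].label == "pseudogene"]
    donor_pool = pseudo_ids if len(pseudo_ids) >= 2 else [c for c in order if c in rows]
    for clone_id, sample in recombinant_slots:
        if len(donor_pool) < 2:
            raise ItsScreenError("recombinant_fraction > 0 requires at least two donor clones")
        cross_sample = [(a, b) for a in donor_pool for b in donor_pool
                        if a < b and a.rsplit("-", 1)[0] != b.rsplit("-", 1)[0]]
        pool = cross_sample if cross_sample else [
            (a, b) for a in donor_pool for b in donor_pool if a < b]
        pa, pb = pool[rng.integers(len(pool))]
        breakpoint = int(rng.integers(150, len(ancestor) - 150))
        rows[clone_id] = rows[pa][:breakpoint] + rows[pb][breakpoint:]
        truth[clone_id] = SimTruth(clone_id, "recombinant", parent_a=pa, parent_b=pb,
                                   breakpoint=breakpoint)

    clones: list[ItsClone] = []
    for clone_id in order:
        row = rows[clone_id]
        clone = ItsClone(clone_id, clone_id.rsplit("-", 1)[0], row.replace("-", ""))
        clone.partition = _ungapped_partition(row, unit.partition)
        clones.append(clone)

    class_labels = {cid: ("F" if truth[cid].label == "functional" else "P")
                    for cid in order if truth[cid].label != "recombinant"}
    alignment = Alignment(order, [rows[cid] for cid in order], class_labels=class_labels)
    return SimulatedDataset(clones=clones, truth=truth, alignment=alignment,
                            regions=unit.regions, reference=unit, params=params)


# ---------------------------------------------------------------------------
# Triplet fixtures for the recombination test

def simulate_null_triplet(seed: int, divergence: float = 0.05,
                          reference: ReferenceUnit | None = None) -> tuple[str, str, str]:
    """A recombination-free triplet: child and both parents are independent
    lineages from one ancestral sequence (the child descends from a single
    parental lineage; no splicing).  Keeps the informative-site match labels
    i.i.d., which is the permutation test's exchangeability null."""
    unit = reference if reference is not None else make_reference_unit()
    rng = np.random.default_rng([seed, 101])
    child = mutate_sequence(unit.sequence, divergence, rng)
    parent_a = mutate_sequence(unit.sequence, divergence, rng)
    parent_b = mutate_sequence(unit.sequence, divergence, rng)
    return child, parent_a, parent_b


def simulate_chimera_triplet(seed: int, divergence: float = 0.05,
                             reference: ReferenceUnit | None = None,
                             ) -> tuple[str, str, str, int]:
    """A planted chimera: child = parent A left of the breakpoint, parent B
    right of it.  Returns (child, parent_a, parent_b, breakpoint) with the
    breakpoint as the 1-based last alignment column inherited from A."""
    unit = reference if reference is not None else make_reference_unit()
    rng = np.random.default_rng([seed, 202])
    parent_a = mutate_sequence(unit.sequence, divergence, rng)
    parent_b = mutate_sequence(unit.sequence, divergence, rng)
    breakpoint = int(rng.integers(150, len(unit.sequence) - 150))
    child = parent_a[:breakpoint] + parent_b[breakpoint:]
    return child, parent_a, parent_b, breakpoint


# ---------------------------------------------------------------------------
# Fixed-count alignment fixtures

def make_count_fixture(length: int, n_variable: int, n_pi: int, n_seqs: int,
                       seed: int = 0) -> Alignment:
    """Build an alignment with exactly ``n_variable`` variable columns of
    which exactly ``n_pi`` are parsimony-informative.

    Parsimony-informative columns carry a 2 vs (n-2) base split; variable
    but uninformative columns carry a singleton difference; all other
    columns are constant.
    """
    if n_seqs < 4:
        raise ItsScreenError("make_count_fixture needs n_seqs >= 4")
    if not (0 <= n_pi <= n_variable <= length):
        raise ItsScreenError("need 0 <= n_pi <= n_variable <= length")
    rng = np.random.default_rng(seed)
    base = rng.choice(_BASES, size=length)
    matrix = np.tile(base, (n_seqs, 1))
    columns = rng.choice(length, size=n_variable, replace=False)
    for rank, col in enumerate(columns):
        alternatives = [b for b in "ACGT" if b != base[col]]
        alt = alternatives[rng.integers(3)]
        if rank < n_pi:
            matrix[0:2, col] = alt
        else:
            matrix[0, col] = alt
    ids = [f"seq{i + 1}" for i in range(n_seqs)]
    return Alignment(ids, ["".join(row) for row in matrix])
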