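import pytest
from hypothesis import given
from hypothesis import strategies as st

from its_screen.core import ItsScreenError, ItsClone, reverse_complement
from its_screen.screen import (
    GcProfile,
    MOTIFS,
    MotifReport,
    PseudogeneEvidence,
    check_helices,
    classify_clone,
    flag_low_gc,
    forced_pairs,
    gc_content,
    parse_evidence_table,
    render_evidence_table,
    scan_motif,
    screen_clones,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=300)


# ---------------------------------------------------------------------------
# GC content

def test_gc_content_basic():
    assert gc_content("GGCC") == 100.0
    assert gc_content("AATT") == 0.0
    assert gc_content("ACGT") == 50.0


def test_gc_content_ignores_ambiguity_and_gaps():
    assert gc_content("GC--NNRY") == 100.0
    with pytest.raises(ItsScreenError):
        gc_content("NNN-")


@given(DNA)
def test_gc_content_reverse_complement_invariant(seq):
    assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


@given(DNA)
def test_gc_content_concatenation_invariant(seq):
    assert gc_content(seq + seq) == pytest.approx(gc_content(seq))


# ---------------------------------------------------------------------------
# Motif scan

def test_scan_motif_conserved_on_reference(refs):
    for name in ("M1", "M2", "M3"):
        assert scan_motif(refs.ref_5_8S, name, refs).status == "conserved"


def test_scan_motif_reports_substitution_position(refs):
    motif = MOTIFS["M2"]
    offset = refs.ref_5_8S.find(motif)
    for k in (0, 6, len(motif) - 1):
        s58 = list(refs.ref_5_8S)
        s58[offset + k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s58[offset + k]]
        report = scan_motif("".join(s58), "M2", refs)
        assert report.status == "changed"
        assert report.change_positions == [k + 1]
        assert report.format() == f"nt-{k + 1}"


def test_scan_motif_partial_deletion(refs):
    motif = MOTIFS["M1"]
    offset = refs.ref_5_8S.find(motif)
    # delete motif positions 4..8 (1-based)
    s58 = refs.ref_5_8S[: offset + 3] + refs.ref_5_8S[offset + 8:]
    report = scan_motif(s58, "M1", refs)
    assert report.status == "partially_missing"
    assert report.missing_range is not None
    lo, hi = report.missing_range
    assert hi - lo + 1 >= 5  # at least the deleted span is reported missing
    assert "missing" in report.format()


def test_scan_motif_all_missing(refs):
    motif = MOTIFS["M3"]
    offset = refs.ref_5_8S.find(motif)
    s58 = refs.ref_5_8S[: offset - 4] + refs.ref_5_8S[offset + len(motif) + 4:]
    report = scan_motif(s58, "M3", refs)
    assert report.status == "all_missing"
    assert report.format() == "all missing"


def test_motif_report_formats():
    assert MotifReport("M1", "conserved").format() == "conserved"
    assert MotifReport("M1", "changed", change_positions=[7, 12]).format() == "nt-7,12"
    assert MotifReport("M1", "partially_missing",
                       missing_range=(4, 16)).format() == "missing 4-16"


# ---------------------------------------------------------------------------
# Helix checks

def test_reference_folds_all_helices(refs):
    pattern, aligned_ok = check_helices(refs.ref_5_8S, refs)
    assert pattern == "XXXXX"
    assert aligned_ok


def test_single_pair_disruption_flips_one_helix(refs):
    from its_screen.core import PAIRING

    i, j = forced_pairs("B6")[0]
    s58 = list(refs.ref_5_8S)
    partner = s58[j - 1]
    s58[i - 1] = next(b for b in "ACGT"
                      if b != s58[i - 1] and (b, partner) not in PAIRING)
    pattern, aligned_ok = check_helices("".join(s58), refs)
    assert aligned_ok
    assert pattern == "XX-XX"


def test_unalignable_sequence_scores_all_dashes(refs):
    # a 10 bp fragment can match at most 10/160 reference positions
    pattern, aligned_ok = check_helices("ACGTACGTAC", refs)
    assert pattern == "-----"
    assert not aligned_ok


# ---------------------------------------------------------------------------
# Low-GC flags and verdicts

def _evidence(cid, sample, gc58, motifs_ok=True, pattern="XXXXX"):
    status = "conserved" if motifs_ok else "changed"
    motifs = {n: MotifReport(n, status) for n in ("M1", "M2", "M3")}
    return PseudogeneEvidence(
        clone_id=cid, sample_id=sample,
        gc=GcProfile(its1_pct=60.0, s58_pct=gc58, its2_pct=60.0),
        motifs=motifs, helix_pattern=pattern,
    )


def test_flag_low_gc_within_sample_median():
    evidences = [
        _evidence("a-1", "a", 55.0),
        _evidence("a-2", "a", 55.2),
        _evidence("a-3", "a", 54.8),
        _evidence("a-4", "a", 48.0),  # 7 pp below the co-sample median
    ]
    flag_low_gc(evidences, delta_pp=2.0)
    assert evidences[3].gc.flags == {"5.8S"}
    assert all(not ev.gc.flags for ev in evidences[:3])


def test_flag_low_gc_baseline_excludes_lesioned_clones():
    # three lesioned low-GC clones must not drag the baseline down
    evidences = [
        _evidence("a-1", "a", 55.0),
        _evidence("a-2", "a", 55.0),
        _evidence("a-3", "a", 47.0, motifs_ok=False),
        _evidence("a-4", "a", 46.0, motifs_ok=False),
        _evidence("a-5", "a", 45.0, motifs_ok=False),
    ]
    flag_low_gc(evidences, delta_pp=2.0)
    assert all("5.8S" in ev.gc.flags for ev in evidences[2:])


def test_flag_low_gc_small_sample_uses_global_baseline():
    evidences = [
        _evidence("a-1", "a", 55.0),
        _evidence("a-2", "a", 55.0),
        _evidence("a-3", "a", 55.0),
        _evidence("b-1", "b", 40.0),  # alone in its sample
    ]
    flag_low_gc(evidences, delta_pp=2.0)
    assert "5.8S" in evidences[3].gc.flags


def test_flag_low_gc_rejects_bad_delta():
    with pytest.raises(ItsScreenError):
        flag_low_gc([], delta_pp=0.0)


def test_classify_or_policy_and_min_criteria():
    clean = classify_clone(_evidence("a-1", "a", 55.0))
    assert clean.verdict == "functional" and clean.reasons == []

    ev = _evidence("a-2", "a", 55.0, pattern="XX-XX")
    assert classify_clone(ev).verdict == "pseudogene"
    assert ev.reasons == ["helix:B6"]

    two = _evidence("a-3", "a", 55.0, motifs_ok=False, pattern="X-XXX")
    assert classify_clone(two, min_criteria=4).verdict == "pseudogene"
    only_one = classify_clone(_evidence("a-4", "a", 55.0, pattern="XX-XX"),
                              min_criteria=2)
    assert only_one.verdict == "functional"


def test_screen_clones_functional_reference(unit):
    clones = [ItsClone(f"S01-{i}", "S01", unit.sequence) for i in range(1, 4)]
    for clone in clones:
        clone.partition = unit.partition
    evidences = screen_clones(clones, unit.refs)
    assert all(ev.verdict == "functional" for ev in evidences)
    assert all(ev.helix_pattern == "XXXXX" for ev in evidences)


def test_screen_clones_requires_partition(unit):
    with pytest.raises(ItsScreenError, match="not delimited"):
        screen_clones([ItsClone("S01-1", "S01", unit.sequence)], unit.refs)


# ---------------------------------------------------------------------------
# Evidence table round trip

def test_evidence_table_roundtrip():
    evidences = [
        classify_clone(_evidence("a-1", "a", 55.12)),
        classify_clone(_evidence("a-2", "a", 47.25, motifs_ok=False, pattern="X-X-X")),
    ]
    evidences[1].gc.flags.add("5.8S")
    classify_clone(evidences[1])
    text = render_evidence_table(evidences, header="unit test")
    assert text.startswith("# unit test\n")
    back = parse_evidence_table(text)
    assert [ev.clone_id for ev in back] == ["a-1", "a-2"]
    assert back[1].gc.flags == {"5.8S"}
    assert back[1].verdict == "pseudogene"
    assert back[0].verdict == "functional"
    assert render_evidence_table(back, header="unit test") == text
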