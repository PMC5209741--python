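"""Stage wiring: delimit → screen → diversity → recombination, plus the
machine-readable run summary.  The CLI is a thin shell over this module.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .core import InputError, ItsScreenError
from .diversity import Alignment, class_contrast, count_site_classes, render_contrast_table, \
    render_indel_matrix, render_indel_nexus
from .io import read_class_labels, read_clones, write_partitions_json, write_partitions_tsv
from .recombination import ScanConfig, render_scan_table, scan_dataset
from .regions import collapse_distinct, delimit_all, region_length_summary
from .screen import render_evidence_table, screen_clones
from .simulate import SimParams, make_reference_unit, simulate_clone_set

log = logging.getLogger("its_screen")

STAGES = ("delimit", "screen", "diversity", "recomb")


@dataclass
class RunConfig:
    out_dir: Path
    fasta: Path | None = None
    samples: Path | None = None
    aligned: Path | None = None
    labels: Path | None = None
    regions: Path | None = None
    stages: tuple[str, ...] = STAGES
    simulate: SimParams | None = None
    seed: int = 0
    delta_pp: float = 2.0
    min_criteria: int = 1
    window: int = 30
    step: int = 5
    permutations: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("fasta", "samples", "aligned", "labels", "regions"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))


def _header(config: RunConfig, stage: str) -> str:
    return f"its-screen {__version__} | stage={stage} | seed={config.seed}"


def _read_regions_tsv(path: Path) -> dict[str, tuple[int, int]]:
    regions = {}
    for line in path.read_text().splitlines()[1:]:
        if not line or line.startswith("#"):
            continue
        name, a, b = line.split("\t")
        regions[name] = (int(a), int(b))
    return regions


def _check_inputs(config: RunConfig) -> None:
    needed: list[Path | None] = []
    if config.simulate is None:
        if "delimit" in config.stages or "screen" in config.stages:
            needed.append(config.fasta)
            if config.fasta is None:
                raise InputError("stages delimit/screen need --fasta")
        if "diversity" in config.stages or "recomb" in config.stages:
            if config.aligned is None:
                raise InputError("stages diversity/recomb need --aligned")
            needed.append(config.aligned)
    needed.extend([config.samples, config.labels, config.regions])
    for path in needed:
        if path is not None and not path.exists():
            raise InputError(f"input not found: {path}")


def summarize(clones, evidences, reports, length_summary) -> dict:
    """Totals per sample and overall: clones, distinct clones, pseudogenes
    (with a reason histogram), recombinants, region length ranges."""
    collapse = collapse_distinct(clones)
    reason_hist: dict[str, int] = {}
    pseudo_ids = []
    for ev in evidences or []:
        if ev.verdict == "pseudogene":
            pseudo_ids.append(ev.clone_id)
            for reason in ev.reasons:
                key = reason.split(":")[0]
                reason_hist[key] = reason_hist.get(key, 0) + 1
    per_sample: dict[str, dict] = {}
    for clone in clones:
        entry = per_sample.setdefault(clone.sample_id, {"clones": 0, "pseudogenes": 0})
        entry["clones"] += 1
        if clone.clone_id in set(pseudo_ids):
            entry["pseudogenes"] += 1
    recombinants = [r.child_id for r in reports or [] if r.verdict == "recombinant"]
    return {
        "clones": collapse.n_total,
        "distinct_clones": collapse.n_distinct,
        "pseudogenes": len(pseudo_ids),
        "pseudogene_ids": sorted(pseudo_ids),
        "pseudogene_reason_histogram": dict(sorted(reason_hist.items())),
        "recombinants": len(recombinants),
        "recombinant_ids": sorted(recombinants),
        "region_length_ranges": length_summary,
        "per_sample": per_sample,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the summary dict.

    Raises :class:`InputError` for missing/unusable inputs (CLI exit 2) and
    other :class:`ItsScreenError` subclasses for stage failures (CLI exit 1).
    Partial artifacts are kept; MANIFEST.tsv records completion state.
    """
    _check_inputs(config)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str]] = []
    manifest_path = out / "MANIFEST.tsv"

    def flush_manifest() -> None:
        with open(manifest_path, "w") as fh:
            fh.write("stage\tstatus\n")
            for stage, status in manifest:
                fh.write(f"{stage}\t{status}\n")

    unit = make_reference_unit()
    fasta, samples, aligned = config.fasta, config.samples, config.aligned
    regions = None
    truth_labels = None

    try:
        if config.simulate is not None:
            ds = simulate_clone_set(config.simulate, reference=unit)
            ds.write_fasta(out / "clones.fasta")
            ds.write_truth_tsv(out / "truth.tsv")
            ds.write_regions_tsv(out / "regions.tsv")
            ds.alignment.write_fasta(out / "aligned.fasta")
            fasta = out / "clones.fasta"
            aligned = out / "aligned.fasta"
            samples = None
            regions = ds.regions
            truth_labels = ds.alignment.class_labels
            manifest.append(("simulate", "ok"))
            log.info("simulate: %d clones", len(ds.clones))

        clones = evidences = reports = length_summary = None

        if "delimit" in config.stages or "screen" in config.stages:
            clones = read_clones(fasta, samples)
            delimit_all(clones, unit.refs)
            write_partitions_tsv(clones, out / "partitions.tsv",
                                 header=_header(config, "delimit"))
            write_partitions_json(clones, out / "partitions.json")
            length_summary = region_length_summary(clones)
            manifest.append(("delimit", "ok"))
            log.info("delimit: %d clones", len(clones))

        if "screen" in config.stages:
            evidences = screen_clones(clones, unit.refs, delta_pp=config.delta_pp,
                                      min_criteria=config.min_criteria)
            (out / "evidence.tsv").write_text(
                render_evidence_table(evidences, header=_header(config, "screen")))
            payload = [
                {"clone_id": ev.clone_id, "sample_id": ev.sample_id,
                 "gc": {"ITS1": ev.gc.its1_pct, "5.8S": ev.gc.s58_pct,
                        "ITS2": ev.gc.its2_pct, "flags": sorted(ev.gc.flags)},
                 "motifs": {name: ev.motifs[name].format() for name in ("M1", "M2", "M3")},
                 "helices": ev.helix_pattern, "verdict": ev.verdict,
                 "reasons": ev.reasons}
                for ev in evidences
            ]
            (out / "evidence.json").write_text(json.dumps(payload, indent=1) + "\n")
            manifest.append(("screen", "ok"))
            log.info("screen: %d pseudogenes",
                     sum(ev.verdict == "pseudogene" for ev in evidences))

        if "diversity" in config.stages:
            labels = None
            if config.labels is not None:
                labels = read_class_labels(config.labels)
            elif evidences is not None:
                labels = {ev.clone_id: ("P" if ev.verdict == "pseudogene" else "F")
                          for ev in evidences}
            elif truth_labels is not None:
                labels = truth_labels
            alignment = Alignment.from_fasta(aligned, class_labels=labels)
            if config.regions is not None:
                regions = _read_regions_tsv(config.regions)
            S, PI, length, (pv, pi) = count_site_classes(alignment)
            (out / "site_classes.tsv").write_text(
                f"# {_header(config, 'diversity')}\n"
                "length\tS\tPI\tpct_variable\tpct_informative\n"
                f"{length}\t{S}\t{PI}\t{pv}\t{pi}\n")
            if labels:
                table = class_contrast(alignment, labels, regions=regions)
                (out / "diversity.tsv").write_text(
                    render_contrast_table(table, header=_header(config, "diversity")))
            (out / "indel_characters.tsv").write_text(
                render_indel_matrix(alignment, header=_header(config, "diversity")))
            (out / "indel_characters.nex").write_text(render_indel_nexus(alignment))
            manifest.append(("diversity", "ok"))

        if "recomb" in config.stages:
            alignment = Alignment.from_fasta(aligned)
            scan_config = ScanConfig(window=config.window, step=config.step,
                                     permutations=config.permutations,
                                     alpha=config.alpha, seed=config.seed)
            reports = scan_dataset(alignment.ids, alignment.seqs, scan_config)
            (out / "recombination.tsv").write_text(
                render_scan_table(reports, header=_header(config, "recomb")))
            manifest.append(("recomb", "ok"))
            log.info("recomb: %d recombinant calls",
                     sum(r.verdict == "recombinant" for r in reports))

        if clones is None:
            alignment = Alignment.from_fasta(aligned)
            clones = read_clones(aligned)
            length_summary = None

        summary = summarize(clones, evidences, reports, length_summary)
        summary["_meta"] = {
            "version": __version__,
            "seed": config.seed,
            "stages": list(config.stages),
            "config": {
                "delta_pp": config.delta_pp, "min_criteria": config.min_criteria,
                "window": config.window, "step": config.step,
                "permutations": config.permutations, "alpha": config.alpha,
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
        manifest.append(("summary", "ok"))
        flush_manifest()
        return summary
    except ItsScreenError:
        manifest.append(("FAILED", "see stderr"))
        flush_manifest()
        raise


def configure_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())
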