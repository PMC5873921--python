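"""Linear pipeline orchestration: simulate -> circularize -> compare ->
polish -> annotate -> conserve, from one declarative YAML config.

The stage order is fixed (the workflow is strictly linear); each stage
writes its artifacts under the output directory and registers them in a
run manifest with SHA-256 checksums, so a re-run with the same config
and seed reproduces every artifact byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import (
    classify_regions,
    extract_candidates,
    find_primer_sites,
    find_scr,
    write_candidate_tsv,
    write_gff3,
)
from .circularize import (
    circularize_report,
    detect_end_overlap,
    find_and_trim_vector,
    trim_and_circularize,
)
from .compare import (
    align_pair,
    check_structure,
    classify_differences,
    error_rates,
    write_differences_tsv,
)
from .conservation import read_pairwise_alignment, window_conservation, write_windows_tsv
from .contig import Contig, read_single_fasta, write_fasta
from .polish import apply_targets, build_pileup, call_indel_targets, polish_report, write_targets_tsv
from .simulate import (
    SimParams,
    TruthLedger,
    make_bac_construct,
    make_reference_sets,
    realign_reads,
    simulate_draft_assembly,
    simulate_short_reads,
)

log = logging.getLogger("bacfinish")

STAGE_ORDER = ["simulate", "circularize", "compare", "polish", "annotate", "conserve"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


_STAGE_KEYS = {
    "simulate": {"enabled", "params"},
    "circularize": {"enabled", "input", "vector", "min_overlap", "min_identity"},
    "compare": {"enabled", "a", "b", "alignment_out"},
    "polish": {"enabled", "draft", "sam", "min_depth", "min_fraction"},
    "annotate": {"enabled", "contig", "primers", "srk_refs", "ark3_refs",
                 "max_mismatch", "threshold"},
    "conserve": {"enabled", "alignment", "window", "step"},
}


@dataclass
class RunConfig:
    """Declarative pipeline configuration (strict: unknown keys rejected)."""

    seed: int = 0
    outdir: str = "bacfinish_out"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        allowed_top = {"seed", "outdir", "stages"}
        unknown = set(raw) - allowed_top
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages", {})
        for name, block in stages.items():
            if name not in STAGE_ORDER:
                raise ConfigError(f"unknown stage {name!r}")
            bad = set(block or {}) - _STAGE_KEYS[name]
            if bad:
                raise ConfigError(f"stage {name!r}: unknown keys {sorted(bad)}")
        return cls(seed=int(raw.get("seed", 0)), outdir=str(raw.get("outdir", "bacfinish_out")),
                   stages=stages)

    def enabled(self, stage: str) -> bool:
        block = self.stages.get(stage)
        return bool(block and block.get("enabled", True))

    def opt(self, stage: str, key: str, default=None):
        return (self.stages.get(stage) or {}).get(key, default)


def demo_config(outdir: str, seed: int = 42, insert_len: int = 30_000) -> RunConfig:
    """A self-contained synthetic demonstration configuration."""
    return RunConfig.from_dict(
        {
            "seed": seed,
            "outdir": outdir,
            "stages": {
                "simulate": {
                    "enabled": True,
                    "params": {
                        "insert_len": insert_len,
                        "overlap_len": 5000,
                        "indel_rate": 5.7e-5,
                        "n_read_pairs": max(2000, insert_len // 10),
                    },
                },
                "circularize": {"enabled": True, "min_overlap": 500},
                "compare": {"enabled": True},
                "polish": {"enabled": True},
                "annotate": {"enabled": True},
                "conserve": {"enabled": True},
            },
        }
    )


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data = {
            "bacfinish_version": __version__,
            "seed": config.seed,
            "stages": {},
            "files": {},
        }

    def add_file(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["files"][str(path.relative_to(self.outdir))] = digest

    def add_stage(self, name: str, info: dict) -> None:
        self.data["stages"][name] = info

    def write(self) -> None:
        (self.outdir / "manifest.json").write_text(json.dumps(self.data, indent=2))


def _preflight(config: RunConfig) -> None:
    """Fail before execution when an enabled stage lacks its inputs."""
    sim_on = config.enabled("simulate")
    circ_on = config.enabled("circularize")
    if config.enabled("circularize") and not sim_on:
        if not config.opt("circularize", "input") or not config.opt("circularize", "vector"):
            raise ConfigError("circularize enabled without simulate: needs 'input' and 'vector'")
    if config.enabled("compare") and not sim_on:
        a, b = config.opt("compare", "a"), config.opt("compare", "b")
        if not (a and b) and not (circ_on and (a or b)):
            raise ConfigError("compare enabled but two assemblies are not available")
    if config.enabled("polish") and not sim_on:
        if not config.opt("polish", "draft") or not config.opt("polish", "sam"):
            raise ConfigError("polish enabled without simulate: needs 'draft' and 'sam'")
    if config.enabled("annotate") and not sim_on and not circ_on:
        if not config.opt("annotate", "contig"):
            raise ConfigError("annotate enabled without an input contig")
    if config.enabled("conserve") and not config.opt("conserve", "alignment"):
        if not config.enabled("compare"):
            raise ConfigError("conserve enabled without an alignment source")
    for stage in STAGE_ORDER:
        for key in ("input", "vector", "a", "b", "draft", "sam", "contig", "alignment"):
            p = config.opt(stage, key)
            if isinstance(p, str) and not Path(p).exists():
                raise ConfigError(f"stage {stage!r}: input path {p!r} does not exist")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order; returns the run report."""
    _preflight(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    report: dict = {"outdir": str(outdir), "stages": {}}
    state: dict = {}

    t0 = time.time()
    for stage in STAGE_ORDER:
        if not config.enabled(stage):
            continue
        log.info("[%s] starting", stage)
        try:
            info = _STAGE_FUNCS[stage](config, outdir, state, manifest)
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc
        manifest.add_stage(stage, info)
        report["stages"][stage] = info
        log.info("[%s] done", stage)
    report["wall_time_s"] = round(time.time() - t0, 2)
    manifest.write()
    manifest.add_file(outdir / "manifest.json")
    return report


def _stage_simulate(config: RunConfig, outdir: Path, state: dict, manifest: _Manifest) -> dict:
    overrides = config.opt("simulate", "params") or {}
    valid = {f.name for f in dataclasses.fields(SimParams)}
    bad = set(overrides) - valid
    if bad:
        raise ConfigError(f"simulate.params: unknown keys {sorted(bad)}")
    params = SimParams(seed=config.seed, **overrides)
    construct, ledger = make_bac_construct(params)
    draft, ledger = simulate_draft_assembly(construct, ledger, params)
    reads, ledger = simulate_short_reads(
        Contig("truth_template", ledger.template_seq), params, ledger
    )
    sam_text = realign_reads(reads, draft)

    files = {
        "construct.fasta": lambda p: write_fasta(construct, p),
        "draft.fasta": lambda p: write_fasta(draft, p),
        "truth_insert.fasta": lambda p: write_fasta(
            Contig("truth_insert", ledger.insert_seq), p
        ),
        "vector.fasta": lambda p: write_fasta(Contig("vector", ledger.vector_seq), p),
        "reads_1.fastq": lambda p: Path(p).write_text(reads.fastq1()),
        "reads_2.fastq": lambda p: Path(p).write_text(reads.fastq2()),
        "reads_vs_draft.sam": lambda p: Path(p).write_text(sam_text),
        "truth_ledger.json": lambda p: ledger.write(p),
    }
    for name, writer in files.items():
        writer(outdir / name)
        manifest.add_file(outdir / name)
    state.update(
        construct=construct, draft=draft, ledger=ledger, reads=reads, params=params,
        sam_path=outdir / "reads_vs_draft.sam",
    )
    return {
        "construct_len": len(construct),
        "draft_len": len(draft),
        "n_injected_edits": len(ledger.injected_edits),
        "n_read_pairs": reads.n_pairs,
        "expected_depth": round(reads.expected_depth, 1),
    }


def _stage_circularize(config: RunConfig, outdir: Path, state: dict, manifest: _Manifest) -> dict:
    if config.opt("circularize", "input"):
        draft = read_single_fasta(config.opt("circularize", "input"))
        vector = read_single_fasta(config.opt("circularize", "vector"))
    else:
        draft = state["draft"]
        vector = Contig("vector", state["ledger"].vector_seq)
    min_overlap = int(config.opt("circularize", "min_overlap", 500))
    min_identity = float(config.opt("circularize", "min_identity", 0.95))
    hit = detect_end_overlap(draft, min_overlap, min_identity)
    if hit is None:
        raise ValueError("no end-overlap found; is the input a linear circle assembly?")
    circle = trim_and_circularize(draft, hit)
    insert, warned = find_and_trim_vector(circle, vector, min_identity)
    write_fasta(insert, outdir / "insert.fasta")
    (outdir / "circularize_report.json").write_text(circularize_report(hit, draft, insert))
    manifest.add_file(outdir / "insert.fasta")
    manifest.add_file(outdir / "circularize_report.json")
    state["insert"] = insert
    return {
        "overlap_len": hit.length,
        "overlap_identity": round(hit.identity, 5),
        "vector_found": not warned,
        "insert_len": len(insert),
    }


def _stage_compare(config: RunConfig, outdir: Path, state: dict, manifest: _Manifest) -> dict:
    a_path, b_path = config.opt("compare", "a"), config.opt("compare", "b")
    a = read_single_fasta(a_path) if a_path else state["insert"]
    b = read_single_fasta(b_path) if b_path else Contig(
        "truth_insert", state["ledger"].insert_seq
    )
    structure = check_structure(a, b)
    aln = align_pair(a, b)
    diffs = classify_differences(aln)
    rates = error_rates(diffs, aln.aln_len)
    write_differences_tsv(diffs, outdir / "differences.tsv")
    (outdir / "error_rates.json").write_text(rates.to_json())
    (outdir / "structure.json").write_text(structure.to_json())
    aln_fa = outdir / "pairwise_alignment.fasta"
    aln_fa.write_text(f">{a.id}\n{aln.gapped_a}\n>{b.id}\n{aln.gapped_b}\n")
    for f in ("differences.tsv", "error_rates.json", "structure.json", "pairwise_alignment.fasta"):
        manifest.add_file(outdir / f)
    state["alignment_fasta"] = aln_fa
    return {
        "aln_len": aln.aln_len,
        "n_snp": rates.n_snp,
        "n_indel": rates.n_indel,
        "indel_rate_2sf": rates.to_dict()["indel_rate_2sf"],
        "collinear": structure.collinear,
    }


def _stage_polish(config: RunConfig, outdir: Path, state: dict, manifest: _Manifest) -> dict:
    draft_path, sam_path = config.opt("polish", "draft"), config.opt("polish", "sam")
    draft = read_single_fasta(draft_path) if draft_path else state["draft"]
    sam = sam_path or state["sam_path"]
    pileup = build_pileup(sam, draft)
    targets, snps = call_indel_targets(
        pileup,
        int(config.opt("polish", "min_depth", 10)),
        float(config.opt("polish", "min_fraction", 0.7)),
    )
    corrected, _cmap = apply_targets(draft, targets)
    rep = polish_report(targets, len(draft))
    write_fasta(corrected, outdir / "polished.fasta")
    write_targets_tsv(targets, outdir / "indel_targets.tsv")
    (outdir / "polish_report.json").write_text(rep.to_json())
    for f in ("polished.fasta", "indel_targets.tsv", "polish_report.json"):
        manifest.add_file(outdir / f)
    return {
        "n_targets": len(targets),
        "n_snp_disagreements": len(snps),
        "indel_rate_2sf": rep.to_dict()["indel_rate_2sf"],
        "polished_len": len(corrected),
    }


def _stage_annotate(config: RunConfig, outdir: Path, state: dict, manifest: _Manifest) -> dict:
    contig_path = config.opt("annotate", "contig")
    contig = read_single_fasta(contig_path) if contig_path else state.get(
        "insert", state.get("draft")
    )
    if config.opt("annotate", "primers"):
        from Bio import SeqIO

        primers = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(config.opt("annotate", "primers"), "fasta")
        }
    else:
        p = state["params"]
        primers = {"SLGF": p.primer_fwd, "SLGR": p.primer_rev}
    if config.opt("annotate", "srk_refs"):
        from .contig import read_fasta

        srk_refs = read_fasta(config.opt("annotate", "srk_refs"))
        ark3_refs = read_fasta(config.opt("annotate", "ark3_refs"))
    else:
        srk_refs, ark3_refs = make_reference_sets(state["ledger"], state["params"])
    hits = find_primer_sites(contig, primers, int(config.opt("annotate", "max_mismatch", 3)))
    regions = extract_candidates(contig, hits)
    classify_regions(contig, regions, srk_refs, ark3_refs,
                     float(config.opt("annotate", "threshold", 0.90)))
    scr = find_scr(contig)
    write_gff3(contig, hits, regions, scr, outdir / "annotation.gff3")
    write_candidate_tsv(regions, outdir / "candidates.tsv")
    manifest.add_file(outdir / "annotation.gff3")
    manifest.add_file(outdir / "candidates.tsv")
    return {
        "n_primer_hits": len(hits),
        "n_candidates": len(regions),
        "n_srk_verdicts": sum(1 for r in regions if r.verdict == "srk"),
        "n_scr_hits": len(scr),
    }


def _stage_conserve(config: RunConfig, outdir: Path, state: dict, manifest: _Manifest) -> dict:
    source = config.opt("conserve", "alignment") or state["alignment_fasta"]
    aln = read_pairwise_alignment(source)
    windows = window_conservation(
        aln,
        int(config.opt("conserve", "window", 250)),
        config.opt("conserve", "step"),
    )
    write_windows_tsv(windows, outdir / "conservation_windows.tsv")
    manifest.add_file(outdir / "conservation_windows.tsv")
    mean = sum(w.conserved_fraction for w in windows) / len(windows)
    return {"n_windows": len(windows), "mean_conserved_fraction": round(mean, 4)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "circularize": _stage_circularize,
    "compare": _stage_compare,
    "polish": _stage_polish,
    "annotate": _stage_annotate,
    "conserve": _stage_conserve,
}


def setup_logging(outdir: Path | None = None, verbose: bool = False) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(outdir / "run.log"))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
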