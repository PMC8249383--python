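"""End-to-end orchestration of the dominance-modifier discovery chain.

Stage order mirrors the discovery logic: find inverted repeats on the B-like
(dominant-candidate) haplotype, screen them for sRNA expression, filter for
hairpin structure, extract the expressed sRNAs of retained precursors and
scan the A-like haplotype for wobble-scored targets. Optional stages compute
SRK diversity from coding alignments and S-haplotype presence calls from
depth tables. Re-running with an identical config and inputs reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .annotation import classify_coverage
from .hairpin import HairpinCriteria, screen_candidates
from .inverted_repeats import IRParams, find_inverted_repeats
from .io import Interval, load_reads, read_depth_table, read_fasta, write_gff3
from .popgen import CodingAlignment, diversity
from .srna import filter_reads, map_reads, quantify
from .targets import TargetHit, WobbleScoreScheme, merge_hit_regions, scan_targets

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Unknown or invalid pipeline configuration."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs and parameters of a pipeline run.

    Defaults equal the study parameters where the study states them
    (inverted-repeat scoring, hairpin thresholds, wobble scoring matrix and
    cutoff); the expression threshold is this package's declared default.
    """

    b_fasta: str = ""
    a_fasta: str = ""
    reads: str = ""
    adapter: str | None = None
    ir: IRParams = field(default_factory=IRParams)
    hairpin: HairpinCriteria = field(default_factory=HairpinCriteria)
    scheme: WobbleScoreScheme = field(default_factory=WobbleScoreScheme)
    min_expression: float = 5.0
    max_mismatches: int = 0
    unique_only: bool = False
    alignments: Mapping[str, str] = field(default_factory=dict)
    depth_tables: Mapping[str, str] = field(default_factory=dict)
    min_depth: int = 1
    breadth_threshold: float = 0.9
    seed: int = 1
    outdir: str = "results/pipeline"
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["alignments"] = dict(self.alignments)
        d["depth_tables"] = dict(self.depth_tables)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version}")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        for key, sub in (("ir", IRParams), ("hairpin", HairpinCriteria), ("scheme", WobbleScoreScheme)):
            if key in data and isinstance(data[key], Mapping):
                sub_known = {f.name for f in fields(sub)}
                sub_unknown = set(data[key]) - sub_known
                if sub_unknown:
                    raise ConfigError(f"unknown keys in {key!r}: {sorted(sub_unknown)}")
                data[key] = sub(**data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


@dataclass
class RunReport:
    counts: dict[str, int]
    target_regions: list[dict[str, Any]]
    diversity: dict[str, dict[str, float]]
    coverage: dict[str, dict[str, Any]]
    log: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": self.counts,
            "target_regions": self.target_regions,
            "diversity": self.diversity,
            "coverage": self.coverage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def tetraploid_fraction(n_tetraploid: int, n_screened: int) -> float:
    """Proportion of tetraploids among screened F2 offspring (worked example:
    105 tetraploids out of 589 screened F2s ~ 0.18)."""
    if n_screened <= 0 or not (0 <= n_tetraploid <= n_screened):
        raise ValueError("need 0 <= n_tetraploid <= n_screened, n_screened > 0")
    return n_tetraploid / n_screened


def run_all(cfg: PipelineConfig) -> RunReport:
    """Run the full discovery chain; returns per-stage counts and target regions."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name: str):
        log.append(f"stage={name}")
        return name

    current = stage("load_inputs")
    try:
        b_seqs = read_fasta(cfg.b_fasta)
        a_seqs = read_fasta(cfg.a_fasta)
        raw_reads = load_reads(cfg.reads)
        log.append(
            f"  b_seqs={len(b_seqs)} a_seqs={len(a_seqs)} raw_reads={raw_reads.total_copies}"
        )

        current = stage("find_inverted_repeats")
        log.append(f"  params={cfg.ir}")
        irs = []
        for seq in b_seqs:
            irs.extend(find_inverted_repeats(seq, cfg.ir))
        log.append(f"  inverted_repeats={len(irs)}")

        current = stage("map_small_rna")
        filtered = filter_reads(raw_reads, adapter=cfg.adapter)
        mapped = map_reads(filtered, b_seqs, cfg.max_mismatches)
        precursors = [
            Interval(ir.left_arm.seq_id, ir.left_arm.start, ir.right_arm.end) for ir in irs
        ]
        expr = quantify(mapped, precursors, unique_only=cfg.unique_only)
        log.append(f"  filtered_reads={filtered.total_copies} placements={len(mapped)}")

        current = stage("screen_hairpins")
        log.append(f"  criteria={cfg.hairpin} min_expression={cfg.min_expression}")
        cands = screen_candidates(irs, cfg.hairpin, expr, min_expression=cfg.min_expression)
        expressed = [c for c in cands if c.expressed]
        retained = [c for c in expressed if c.passes]
        log.append(
            f"  expressed={len(expressed)} structure_pass={sum(c.passes for c in cands)} retained={len(retained)}"
        )

        current = stage("extract_expressed_srna")
        queries: dict[str, int] = {}
        for cand in retained:
            ir = cand.source
            span = Interval(ir.left_arm.seq_id, ir.left_arm.start, ir.right_arm.end)
            for m in mapped:
                if m.seq_id != span.seq_id or not (21 <= len(m.read) <= 24):
                    continue
                if m.position < span.end and m.end > span.start:
                    queries[m.read] = m.count
        queries = {r: c for r, c in queries.items() if c >= cfg.min_expression}
        log.append(f"  srna_queries={len(queries)}")

        current = stage("scan_targets")
        log.append(f"  scheme={cfg.scheme}")
        hits: list[TargetHit] = []
        for idx, (read, _count) in enumerate(sorted(queries.items())):
            for a_seq in a_seqs:
                hits.extend(scan_targets((f"sRNA_{idx:03d}", read), a_seq, cfg.scheme))
        regions = merge_hit_regions(hits)
        log.append(f"  target_hits={len(hits)} target_regions={len(regions)}")

        current = stage("optional_diversity")
        div: dict[str, dict[str, float]] = {}
        for label, path in sorted(dict(cfg.alignments).items()):
            est = diversity(CodingAlignment.from_fasta(path))
            div[label] = {
                "pi": round(est.pi, 4),
                "theta_w": round(est.theta_w, 4),
                "S": est.S,
                "n": est.n,
                "L_used": est.L_used,
            }
            log.append(f"  diversity[{label}]: {div[label]}")

        current = stage("optional_coverage")
        cov: dict[str, dict[str, Any]] = {}
        for label, path in sorted(dict(cfg.depth_tables).items()):
            for sid, depths in read_depth_table(path).items():
                call = classify_coverage(depths, cfg.min_depth, cfg.breadth_threshold, seq_id=sid)
                cov[f"{label}:{sid}"] = {
                    "breadth": round(call.breadth, 4),
                    "mean_depth": round(call.mean_depth, 2),
                    "evenness": round(call.evenness, 4),
                    "present": call.present,
                }
                log.append(f"  coverage[{label}:{sid}]: {cov[f'{label}:{sid}']}")

        current = stage("write_outputs")
        seq_lengths = {s.id: s.length for s in b_seqs}
        write_gff3(
            [
                (
                    Interval(ir.left_arm.seq_id, ir.left_arm.start, ir.right_arm.end),
                    "inverted_repeat",
                    ir.score,
                    {
                        "ID": f"IR{i:04d}",
                        "left_arm": f"{ir.left_arm.start}-{ir.left_arm.end}",
                        "right_arm": f"{ir.right_arm.start}-{ir.right_arm.end}",
                    },
                )
                for i, ir in enumerate(irs)
            ],
            outdir / "inverted_repeats.gff3",
            seq_lengths,
        )
        write_gff3(
            [
                (
                    Interval(c.source.left_arm.seq_id, c.source.left_arm.start, c.source.right_arm.end),
                    "sRNA_precursor",
                    c.source.score,
                    {
                        "ID": f"precursor{i:02d}",
                        "loop_len": str(c.loop_len),
                        "paired_len": str(c.paired_len),
                        "mismatches": str(c.mismatch_count),
                        "bulges": str(c.asym_bulge_count),
                    },
                )
                for i, c in enumerate(retained)
            ],
            outdir / "retained_precursors.gff3",
            seq_lengths,
        )
        region_rows = [
            {
                "seq_id": iv.seq_id,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "best_score": best.score,
                "best_srna": best.srna_id,
                "pairing": best.pairing_string,
            }
            for iv, best in regions
        ]
        with open(outdir / "target_regions.tsv", "w") as fh:
            cols = ["seq_id", "start", "end", "strand", "best_score", "best_srna", "pairing"]
            fh.write("\t".join(cols) + "\n")
            for row in region_rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage name
        raise PipelineStageError(current, exc) from exc

    counts = {
        "inverted_repeats": len(irs),
        "expressed": len(expressed),
        "structure_pass": sum(c.passes for c in cands),
        "retained": len(retained),
        "srna_queries": len(queries),
        "target_hits": len(hits),
        "target_regions": len(regions),
    }
    report = RunReport(counts, region_rows, div, cov, log)
    report.to_json(outdir / "report.json")
    with open(outdir / "log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report
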