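"""End-to-end workflow: filter variants, trim reads, assign, quantify.

A full run consumes a consensus FASTA, a VCF of called polymorphisms, a
barcode region definition and an amplicon FASTQ, and produces the
genotype abundance table plus a self-contained run manifest (tool
version, configuration snapshot, input digests and per-stage record
counts) so any result can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .haplotype_db import BarcodeRegion
from .quantify import AbundanceTable, assign_reads, quantify, write_abundance_tsv
from .read_processing import quality_filter, read_fastq, trim_to_amplicon
from .variants import PipelineConfig, filter_variants, read_consensus, read_vcf_records

__all__ = ["RunManifest", "run_pipeline", "load_run_config", "build_region"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline invocation."""

    version: str
    config: dict
    inputs: dict[str, str]  # path -> sha256
    stage_counts: dict[str, int] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    status: str = "running"
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_run_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` run-configuration file.

    Required keys: consensus, vcf, reads, region (contig:start-end),
    label, out_dir.  Threshold keys mirror PipelineConfig field names.
    """
    settings: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line is not 'key = value': {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        settings[key] = value
    missing = {"consensus", "vcf", "reads", "region", "label", "out_dir"} - set(settings)
    if missing:
        raise ValueError(f"run config missing keys: {sorted(missing)}")
    return settings


def parse_region_spec(spec: str) -> tuple[str, int, int]:
    """Parse ``contig:start-end`` (1-based inclusive)."""
    contig, _, span = spec.rpartition(":")
    start_s, _, end_s = span.partition("-")
    if not contig or not start_s or not end_s:
        raise ValueError(f"region must be contig:start-end, got {spec!r}")
    return contig, int(start_s), int(end_s)


def build_region(
    consensus: dict[str, str],
    polymorphisms,
    contig: str,
    start: int,
    end: int,
    label: str,
) -> BarcodeRegion:
    """Assemble a BarcodeRegion from a consensus and filtered polymorphisms.

    Only polymorphisms whose full reference span lies inside
    [start, end] on ``contig`` are attached.
    """
    if contig not in consensus:
        raise ValueError(f"contig {contig!r} not in consensus")
    seq = consensus[contig]
    if not 1 <= start <= end <= len(seq):
        raise ValueError(f"region {start}-{end} outside contig of length {len(seq)}")
    inside = tuple(
        p
        for p in polymorphisms
        if p.contig == contig and p.ref_span[0] >= start and p.ref_span[1] <= end
    )
    return BarcodeRegion(
        label=label,
        contig=contig,
        start=start,
        end=end,
        consensus_seq=seq[start - 1 : end],
        polymorphisms=inside,
    )


def run_pipeline(
    config_file: str | Path,
) -> tuple[AbundanceTable, RunManifest]:
    """Execute the four-stage workflow described by a run-config file.

    Stages: hard-filter the VCF; build the barcode region; quality-filter
    and (optionally) primer-trim the reads; assign each read to a
    genotype; quantify.  Writes ``abundance.tsv`` and ``manifest.json``
    into ``out_dir`` and returns both objects.
    """
    settings = load_run_config(config_file)
    for key in ("consensus", "vcf", "reads"):
        if not Path(settings[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {settings[key]}")

    config = PipelineConfig(
        **{
            name: int(settings[name])
            for name in (
                "min_genotype_quality",
                "min_site_depth",
                "min_read_quality",
                "min_genotype_coverage",
                "max_polymorphisms",
            )
            if name in settings
        }
    )
    out_dir = Path(settings["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config=dataclasses.asdict(config) | {k: v for k, v in settings.items()},
        inputs={
            settings[k]: _sha256(settings[k]) for k in ("consensus", "vcf", "reads")
        },
        started=datetime.now(timezone.utc).isoformat(),
    )
    stage = "filter_variants"
    try:
        consensus = read_consensus(settings["consensus"])
        raw_records = read_vcf_records(settings["vcf"])
        polymorphisms = filter_variants(raw_records, config, consensus)
        manifest.stage_counts["variants_in"] = len(raw_records)
        manifest.stage_counts["variants_out"] = len(polymorphisms)

        stage = "build_region"
        contig, start, end = parse_region_spec(settings["region"])
        region = build_region(
            consensus, polymorphisms, contig, start, end, settings["label"]
        )
        manifest.stage_counts["region_polymorphisms"] = region.y

        stage = "read_processing"
        reads = list(read_fastq(settings["reads"]))
        manifest.stage_counts["reads_in"] = len(reads)
        filtered = list(quality_filter(reads, config))
        manifest.stage_counts["reads_quality_pass"] = len(filtered)
        if "forward_primer" in settings and "reverse_primer" in settings:
            filtered = list(
                trim_to_amplicon(
                    filtered,
                    settings["forward_primer"],
                    settings["reverse_primer"],
                    int(settings.get("expected_length", region.length)),
                )
            )
        manifest.stage_counts["reads_trimmed"] = len(filtered)

        stage = "assign_and_quantify"
        table = quantify(assign_reads(filtered, region, config), region, config)
        manifest.stage_counts["reads_assigned"] = table.total_assigned
        manifest.stage_counts["reads_rejected"] = table.total_rejected
        manifest.stage_counts["genotypes_detected"] = table.n_genotypes_detected
        manifest.stage_counts["genotypes_retained"] = len(table.rows)

        write_abundance_tsv(table, out_dir / "abundance.tsv")
        manifest.status = (
            "success" if table.total_assigned > 0 else "success-with-warning"
        )
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.write(out_dir / "manifest.json")
        raise
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out_dir / "manifest.json")
    return table, manifest
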