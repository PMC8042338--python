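"""End-to-end orchestration: scan -> clusters -> offsets -> orthologs -> markers.

One deterministic run over validated inputs, producing a site TSV, a
cluster JSON, an offsets TSV, an optional conservation JSON, a markers TSV
and a machine-readable manifest.  Stages are the library calls the CLI
subcommands expose individually; running them through the pipeline is
equivalent to composing the subcommands by hand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster_analysis import build_clusters, compaction_stats, offset_patterns, summarize_by_region
from .duplex_core import EnergyModel
from .errors import MirsiteError
from .expression_context import build_associations, marker_candidates
from .io_formats import (
    AnalysisConfig,
    read_fasta,
    read_ortholog_fasta,
    read_transcript_table,
    write_site_table,
    MiRNA,
)
from .ortholog_conservation import conservation_report
from .site_scanner import Thresholds, scan_all


@dataclass
class PipelineInputs:
    mirnas: Path
    transcripts: Path
    annotations: Path
    ortholog_segments: Path | None = None
    ortholog_cluster: tuple[int, int] | None = None
    offset_pairs: list[tuple[str, str]] = field(default_factory=list)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator tagging stage errors with the failing stage's name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (MirsiteError, OSError) as exc:
                raise MirsiteError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(
    inputs: PipelineInputs,
    outdir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict[str, Path]:
    """Execute every stage in order and write the output bundle.

    Identical inputs and config yield byte-identical data outputs; the
    manifest additionally records a wall-clock timestamp.
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds(config.threshold_report, config.threshold_efficient)
    model = EnergyModel(config.e_hb_kj_per_bond)
    counts: dict[str, int] = {}

    mirna_records = _stage("io_formats")(read_fasta)(inputs.mirnas)
    mirnas = [MiRNA(rid, seq) for rid, seq in mirna_records]
    transcript_records = _stage("io_formats")(read_fasta)(inputs.transcripts)
    transcripts = _stage("io_formats")(read_transcript_table)(
        inputs.annotations, transcript_records
    )
    counts["mirnas"] = len(mirnas)
    counts["transcripts"] = len(transcripts)

    sites = _stage("site_scanner")(scan_all)(mirnas, transcripts, thresholds, model)
    sites_path = outdir / "sites.tsv"
    write_site_table(sites, sites_path)
    counts["sites"] = len(sites)

    clusters_by_transcript = {
        t.transcript_id: build_clusters([s for s in sites if s.transcript_id == t.transcript_id])
        for t in transcripts
    }
    all_clusters = [c for cl in clusters_by_transcript.values() for c in cl]
    cluster_payload = {
        "clusters": [
            {
                "transcript_id": c.transcript_id,
                "region": c.region,
                "span": [c.span_start, c.span_end],
                "members": [
                    {"mirna_id": m.mirna_id, "start": m.start, "length": m.length}
                    for m in c.members
                ],
                **compaction_stats(c),
            }
            for c in all_clusters
        ],
        "summary": summarize_by_region(all_clusters, sites, transcripts),
    }
    clusters_path = outdir / "clusters.json"
    clusters_path.write_text(json.dumps(cluster_payload, indent=1, sort_keys=True) + "\n")
    counts["clusters"] = len(all_clusters)

    patterns = offset_patterns(sites, inputs.offset_pairs)
    offsets_path = outdir / "offsets.tsv"
    pd.DataFrame(
        [
            {
                "mirna_a": p.mirna_a,
                "mirna_b": p.mirna_b,
                "gene": gene,
                "offset_nt": diff,
                "constant": int(p.constant),
            }
            for p in patterns
            for gene, diff in sorted(p.per_gene.items())
        ],
        columns=["mirna_a", "mirna_b", "gene", "offset_nt", "constant"],
    ).to_csv(offsets_path, sep="\t", index=False)
    counts["offset_patterns"] = len(patterns)

    conservation_path = None
    if inputs.ortholog_segments is not None:
        sets = _stage("ortholog_conservation")(read_ortholog_fasta)(inputs.ortholog_segments)
        reports = []
        for oset in sets:
            cluster = inputs.ortholog_cluster or (1, len(oset.reference))
            rep = conservation_report(oset, cluster, mirnas, model)
            reports.append(
                {
                    "locus": rep.locus,
                    "flank5": rep.flank5,
                    "flank3": rep.flank3,
                    "cluster_lengths": rep.cluster_lengths,
                    "ratio_matrix": rep.ratio_matrix,
                    "bands": rep.bands,
                    "substitutions": {
                        sp: dataclasses.asdict(sc) for sp, sc in rep.substitutions.items()
                    },
                }
            )
        conservation_path = outdir / "conservation.json"
        conservation_path.write_text(json.dumps(reports, indent=1, sort_keys=True) + "\n")
        counts["ortholog_sets"] = len(sets)

    associations = marker_candidates(
        build_associations(sites), config.marker_dg_cutoff, config.multisite_min
    )
    markers_path = outdir / "markers.tsv"
    pd.DataFrame(
        [
            {
                "mirna_id": a.mirna_id,
                "gene": a.gene,
                "region": a.region,
                "start": a.start,
                "delta_g_kj_mol": a.delta_g,
                "ratio_percent": a.ratio,
                "n_sites": a.n_sites,
                "rpkm": a.rpkm,
                "expression_class": a.expression_class,
                "marker": int(a.marker),
            }
            for a in associations
        ],
        columns=[
            "mirna_id", "gene", "region", "start", "delta_g_kj_mol",
            "ratio_percent", "n_sites", "rpkm", "expression_class", "marker",
        ],
    ).to_csv(markers_path, sep="\t", index=False)
    counts["associations"] = len(associations)
    counts["markers"] = sum(a.marker for a in associations)

    manifest = {
        "tool": "mirsite",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _digest(p)}
            for name, p in (
                ("mirnas", inputs.mirnas),
                ("transcripts", inputs.transcripts),
                ("annotations", inputs.annotations),
                ("ortholog_segments", inputs.ortholog_segments),
            )
            if p is not None
        },
        "record_counts": counts,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    outputs = {
        "sites": sites_path,
        "clusters": clusters_path,
        "offsets": offsets_path,
        "markers": markers_path,
        "manifest": manifest_path,
    }
    if conservation_path is not None:
        outputs["conservation"] = conservation_path
    return outputs
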