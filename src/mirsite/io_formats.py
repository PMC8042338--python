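"""Input/output layer: FASTA, annotation tables, site reports and configs.

All external representations are read into validated domain objects here so
the analysis modules never touch raw files.  Conventions used throughout the
package:

* sequences are stored in the RNA alphabet {A, C, G, U, N}, upper case;
  DNA input (T) is normalized to U on read;
* coordinates are 1-based and inclusive, counted from the first nucleotide
  of the transcript (i.e. the first nucleotide of the 5'UTR when present);
* the transcript annotation travels in a sidecar TSV rather than being
  parsed out of GenBank-style feature records.
"""

from __future__ import annotations

import dataclasses
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlphabetError,
    BoundaryError,
    FormatError,
    FrameError,
    ReferenceError_,
)

RNA_ALPHABET = frozenset("ACGUN")

#: Region labels used everywhere downstream.
REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGION_UNANNOTATED = "unannotated"
REGIONS = (REGION_5UTR, REGION_CDS, REGION_3UTR, REGION_UNANNOTATED)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


def normalize_rna(sequence: str, *, record_id: str = "?") -> str:
    """Fold to upper case, map T to U and validate the alphabet."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"record {record_id!r}: characters outside ACGUTN: {sorted(bad)}"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over the RNA alphabet (N -> N)."""
    return "".join(_COMPLEMENT[b] for b in reversed(sequence))


@dataclass(frozen=True)
class MiRNA:
    """An identified short RNA query.

    The canonical mature-miRNA length range 18-26 nt is enforced by default;
    pass ``strict_length=False`` for deliberately out-of-range toy queries.
    """

    id: str
    sequence: str
    strict_length: dataclasses.InitVar[bool] = True

    def __post_init__(self, strict_length: bool) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, record_id=self.id))
        if not self.sequence:
            raise FormatError(f"miRNA {self.id!r} has an empty sequence")
        if strict_length and not 18 <= len(self.sequence) <= 26:
            raise FormatError(
                f"miRNA {self.id!r} length {len(self.sequence)} outside [18, 26]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Transcript:
    """An mRNA with 1-based region boundaries and an expression value.

    ``utr5_end`` is the last nucleotide of the 5'UTR (0 when absent) and
    ``cds_end`` the last nucleotide of the CDS.  ``utr5_end == cds_end == 0``
    marks an unannotated transcript treated as a single region.
    """

    transcript_id: str
    gene: str
    sequence: str
    utr5_end: int = 0
    cds_end: int = 0
    rpkm: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", normalize_rna(self.sequence, record_id=self.transcript_id)
        )
        n = len(self.sequence)
        if not 0 <= self.utr5_end <= self.cds_end <= n:
            raise BoundaryError(
                f"{self.transcript_id}: boundaries utr5_end={self.utr5_end}, "
                f"cds_end={self.cds_end} inconsistent with length {n}"
            )
        cds_len = self.cds_end - self.utr5_end
        if cds_len and cds_len % 3:
            raise FrameError(
                f"{self.transcript_id}: CDS length {cds_len} is not a multiple of 3"
            )
        if not (isinstance(self.rpkm, (int, float)) and (math.isnan(self.rpkm) or self.rpkm >= 0)):
            raise BoundaryError(f"{self.transcript_id}: negative RPKM {self.rpkm}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def annotated(self) -> bool:
        return self.cds_end > 0

    def region_of(self, position: int) -> str:
        """Region label of a 1-based nucleotide position."""
        if not 1 <= position <= len(self):
            raise BoundaryError(
                f"{self.transcript_id}: position {position} outside 1..{len(self)}"
            )
        if not self.annotated:
            return REGION_UNANNOTATED
        if position <= self.utr5_end:
            return REGION_5UTR
        if position <= self.cds_end:
            return REGION_CDS
        return REGION_3UTR


@dataclass(frozen=True)
class OrthologSet:
    """Species-labelled homologous mRNA segments around one locus."""

    locus: str
    segments: Mapping[str, str]
    reference_species: str

    def __post_init__(self) -> None:
        segs = OrderedDict(
            (sp, normalize_rna(seq, record_id=f"{sp}|{self.locus}"))
            for sp, seq in self.segments.items()
        )
        object.__setattr__(self, "segments", segs)
        if len(segs) < 2:
            raise FormatError(f"ortholog set {self.locus!r} needs >= 2 species")
        if self.reference_species not in segs:
            raise FormatError(
                f"reference species {self.reference_species!r} missing from {self.locus!r}"
            )
        if any(not s for s in segs.values()):
            raise FormatError(f"ortholog set {self.locus!r} has an empty segment")

    @property
    def reference(self) -> str:
        return self.segments[self.reference_species]


def read_fasta(path: str | Path, alphabet_policy: str = "auto") -> list[tuple[str, str]]:
    """Read a multi-FASTA file into ``(id, RNA sequence)`` pairs, in order.

    ``alphabet_policy`` is one of ``rna``/``dna``/``auto``; T and U are
    interchangeable on input in every mode, so the policy only documents
    intent -- the result is always RNA.
    """
    if alphabet_policy not in ("rna", "dna", "auto"):
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    path = Path(path)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path.name}: empty record {rec.id!r}")
        records.append((rec.id, normalize_rna(seq, record_id=rec.id)))
    if not records:
        raise FormatError(f"{path.name}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_ANNOT_COLUMNS = ["transcript_id", "gene", "utr5_end", "cds_end", "rpkm"]


def read_transcript_table(path: str | Path, fasta: list[tuple[str, str]]) -> list[Transcript]:
    """Join the annotation TSV onto FASTA records, validating boundaries."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene": str})
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing columns: {missing}")
    seqs = dict(fasta)
    transcripts = []
    for row in df.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise ReferenceError_(
                f"annotation row {row.transcript_id!r} has no FASTA sequence"
            )
        transcripts.append(
            Transcript(
                transcript_id=row.transcript_id,
                gene=row.gene,
                sequence=seqs[row.transcript_id],
                utr5_end=int(row.utr5_end),
                cds_end=int(row.cds_end),
                rpkm=float(row.rpkm),
            )
        )
    return transcripts


def write_transcript_table(transcripts: Iterable[Transcript], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "gene": t.gene,
                "utr5_end": t.utr5_end,
                "cds_end": t.cds_end,
                "rpkm": t.rpkm,
            }
            for t in transcripts
        ],
        columns=_ANNOT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# --- site report dialect ----------------------------------------------------

#: Report columns; the table layout mirrors published site tables
#: (gene, expression, miRNA, start, region, length, free energy, ratio).
SITE_COLUMNS = [
    "gene",
    "rpkm",
    "mirna_id",
    "start",
    "region",
    "length",
    "delta_g_kj_mol",
    "ratio_percent",
    "efficient_flag",
    "transcript_id",
    "boundary_spanning",
]


def write_site_table(sites: Iterable, path: str | Path) -> None:
    """Write binding sites as a deterministic TSV sorted by (gene, start, miRNA)."""
    rows = [
        {
            "gene": s.gene,
            "rpkm": s.rpkm,
            "mirna_id": s.mirna_id,
            "start": s.start,
            "region": s.region,
            "length": s.length,
            "delta_g_kj_mol": repr(float(s.delta_g)),
            "ratio_percent": repr(float(s.ratio)),
            "efficient_flag": int(s.efficient),
            "transcript_id": s.transcript_id,
            "boundary_spanning": int(s.boundary_spanning),
        }
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if len(df):
        df = df.sort_values(["gene", "start", "mirna_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list:
    """Re-parse a site report TSV into BindingSite objects (round-trip)."""
    from .site_scanner import BindingSite  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "mirna_id": str, "transcript_id": str})
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            BindingSite(
                mirna_id=row.mirna_id,
                transcript_id=row.transcript_id,
                gene=row.gene,
                start=int(row.start),
                length=int(row.length),
                delta_g=float(row.delta_g_kj_mol),
                ratio=float(row.ratio_percent),
                region=row.region,
                efficient=bool(row.efficient_flag),
                boundary_spanning=bool(row.boundary_spanning),
                rpkm=float(row.rpkm),
            )
        )
    return sites


def read_ortholog_fasta(
    path: str | Path, reference_species: str = "hsa"
) -> list[OrthologSet]:
    """Read species-tagged multi-FASTA (ids ``species|locus``) into ortholog sets."""
    loci: OrderedDict[str, OrderedDict[str, str]] = OrderedDict()
    for rid, seq in read_fasta(path):
        if "|" not in rid:
            raise FormatError(f"ortholog record id {rid!r} is not 'species|locus'")
        species, locus = rid.split("|", 1)
        loci.setdefault(locus, OrderedDict())[species] = seq
    sets = []
    for locus, segs in loci.items():
        ref = reference_species if reference_species in segs else next(iter(segs))
        sets.append(OrthologSet(locus=locus, segments=segs, reference_species=ref))
    return sets


# --- analysis configuration -------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the whole analysis (plain key-value file)."""

    threshold_report: float = 85.0
    threshold_efficient: float = 90.0
    e_hb_kj_per_bond: float = 2.1
    polysite_max_gap: int = 3
    marker_dg_cutoff: float = 130.0
    multisite_min: int = 5
    seed: int = 0


def read_config(path: str | Path) -> AnalysisConfig:
    """Parse ``key = value`` lines (``#`` comments allowed) into a config."""
    cfg = AnalysisConfig()
    valid = {f.name: f.type for f in dataclasses.fields(AnalysisConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"config line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in valid:
                raise FormatError(f"config line {lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            setattr(cfg, key, type(current)(float(value)) if not isinstance(current, int) else int(float(value)))
    return cfg


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(cfg):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")
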