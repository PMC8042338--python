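"""Seeded generators with planted, recoverable ground truth.

The cohort generator emulates the regimes the analysis is built for:

* GC-enriched 5'UTRs carrying clusters of overlapping sites for several
  miRNAs (each member miRNA is derived as the reverse complement of its
  window, then degraded by transitions to a target ratio);
* polysites — runs of starts of one miRNA spaced 2-3 nt apart — realized
  as tandem repeats paired with a periodic miRNA, so every planted start
  scores 100%;
* constant start offsets between two miRNAs across genes, realized by
  planting one composite repeat block (both miRNAs derived from its two
  ends) into several genes;
* ortholog sets diverging by transition-biased substitutions around
  untouched flanking oligonucleotides;
* log-normal RPKM values spanning roughly 0.1-322.5 with a forced
  high-expression subset.

Everything is driven by a single integer seed through one NumPy generator,
so identical configs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cluster_analysis import build_clusters
from .duplex_core import max_bonds, reverse_complement, score_window
from .errors import GenerationError
from .io_formats import (
    MiRNA,
    Transcript,
    write_fasta,
    write_transcript_table,
)
from .site_scanner import BindingSite

BASES = np.array(list("ACGU"))

#: Three-letter species codes used for generated ortholog sets.
SPECIES_CODES = [
    "hsa", "ptr", "ppa", "ggo", "pab", "nle", "mml", "mfa", "mne", "sbo",
    "cja", "mmu", "fca", "ppr", "oor", "dle", "ord", "ssc", "bta", "bbu",
    "chi", "oar",
]

_TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}
_TRANSVERSIONS = {"A": "CU", "G": "CU", "C": "AG", "U": "AG"}

#: Windows scoring within this many ratio points of the planting target are
#: accepted (matches the scanner-recovery contract asserted in tests).
RATIO_TOLERANCE = 1.5


# --------------------------------------------------------------------------
# specs and config


@dataclass(frozen=True)
class PlantedSiteSpec:
    """A single miRNA planted ``count`` times; spacing >= 2 makes a polysite."""

    region: str = "3UTR"
    target_ratio: float = 100.0
    count: int = 1
    spacing: int = 0
    mirna_length: int = 22


@dataclass(frozen=True)
class ClusterSpec:
    """Several miRNAs with overlapping windows in one region of one gene."""

    n_mirnas: int = 5
    region: str = "5UTR"
    start_spread: int = 10  # starts fall in [anchor, anchor + spread]; < miRNA length
    ratio_range: tuple[float, float] = (88.0, 100.0)
    mirna_length: int = 22


@dataclass(frozen=True)
class OffsetPairSpec:
    """Two miRNAs whose site starts differ by a constant offset in n genes."""

    offset: int = 74
    n_genes: int = 3
    region: str = "3UTR"
    mirna_length: int = 22


@dataclass(frozen=True)
class OrthologSpec:
    n_species: int = 6
    sub_rate: float = 0.05
    transition_fraction: float = 0.8
    flank5: str = "UGCGGG"
    flank3: str = "CCGAG"
    segment_length: int = 120
    cluster_length: int = 33


def _default_planted() -> list[PlantedSiteSpec]:
    return [
        PlantedSiteSpec(region="3UTR", target_ratio=100.0),
        PlantedSiteSpec(region="CDS", target_ratio=93.0),
        PlantedSiteSpec(region="5UTR", target_ratio=90.0),
        PlantedSiteSpec(region="3UTR", target_ratio=87.0),
        PlantedSiteSpec(region="3UTR", count=13, spacing=2),
    ]


def _default_clusters() -> list[ClusterSpec]:
    return [ClusterSpec(n_mirnas=9, region="5UTR", start_spread=10)]


def _default_offsets() -> list[OffsetPairSpec]:
    return [
        OffsetPairSpec(offset=6, n_genes=3),
        OffsetPairSpec(offset=74, n_genes=3),
        OffsetPairSpec(offset=99, n_genes=2),
    ]


@dataclass
class SimConfig:
    """Study conditions of a synthetic cohort.

    Transcript architecture defaults: 100-300 nt 5'UTRs (GC-enriched, where
    clusters concentrate), 300-1500 nt triplet-rounded CDSs and 300-4000 nt
    3'UTRs.  RPKM is log-normal around a few RPKM, clipped to [0.1, 322.5],
    with 20% of genes forced into the 43.1-322.5 high-expression band.
    """

    seed: int = 0
    n_genes: int = 12
    utr5_len: tuple[int, int] = (100, 300)
    cds_len: tuple[int, int] = (300, 1500)
    utr3_len: tuple[int, int] = (300, 4000)
    gc_fraction: float = 0.45
    utr5_gc_fraction: float = 0.60
    planted_sites: list[PlantedSiteSpec] = field(default_factory=_default_planted)
    clusters: list[ClusterSpec] = field(default_factory=_default_clusters)
    offset_pairs: list[OffsetPairSpec] = field(default_factory=_default_offsets)
    ortholog: OrthologSpec | None = field(default_factory=OrthologSpec)
    rpkm_log_mean: float = 1.25  # ln RPKM; median ~3.5
    rpkm_log_sigma: float = 1.1
    rpkm_high_fraction: float = 0.2
    rpkm_range: tuple[float, float] = (0.1, 322.5)
    high_band: tuple[float, float] = (43.1, 322.5)


@dataclass
class Cohort:
    mirnas: list[MiRNA]
    transcripts: list[Transcript]
    ground_truth: dict


# --------------------------------------------------------------------------
# elementary generators


def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    """Random RNA with the expected GC fraction."""
    gc = rng.random(length) < gc_fraction
    strong = rng.integers(0, 2, length)  # G vs C, A vs U
    out = np.where(gc, np.where(strong == 0, "G", "C"), np.where(strong == 0, "A", "U"))
    return "".join(out)


def gen_mirna(
    length: int,
    gc_fraction: float,
    rng: np.random.Generator,
    mirna_id: str = "sim-miR",
) -> MiRNA:
    """A random miRNA of the given length and expected GC content."""
    if not 18 <= length <= 26:
        raise GenerationError(f"miRNA length {length} outside [18, 26]")
    if not 0.0 <= gc_fraction <= 1.0:
        raise GenerationError(f"GC fraction {gc_fraction} outside [0, 1]")
    return MiRNA(id=mirna_id, sequence=random_sequence(length, gc_fraction, rng))


def _ratio(mirna_seq: str, window: str) -> float:
    scheme = score_window(MiRNA("q", mirna_seq, strict_length=False), window)
    return scheme.ratio


def degrade_window(
    mirna: MiRNA, target_ratio: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Perfect-complement window degraded by transitions to a target ratio.

    Transitions in the window turn a canonical pair into a 1-bond
    non-canonical pair (G-C drops 2 bonds, A-U drops 1), so any integer
    bond total down from the maximum is reachable and the achieved ratio
    lands within RATIO_TOLERANCE of the target (granularity permitting).
    """
    window = list(reverse_complement(mirna.sequence))
    mb = max_bonds(mirna)
    target_bonds = round(target_ratio * mb / 100.0)
    deficit = mb - target_bonds
    drop2 = [k for k, b in enumerate(window) if b in "GC"]
    drop1 = [k for k, b in enumerate(window) if b in "AU"]
    rng.shuffle(drop2)
    rng.shuffle(drop1)
    degraded_gc: list[int] = []  # transitioned G/C positions still holding 1 bond
    while deficit > 0:
        if deficit == 1:
            if drop1:
                k = drop1.pop()
                window[k] = _TRANSITION[window[k]]
                deficit -= 1
            elif degraded_gc:
                # zero out the residual non-canonical bond of a previous edit
                k = degraded_gc.pop()
                window[k] = {"A": "U", "U": "A"}[window[k]]
                deficit -= 1
            elif drop2:
                k = drop2.pop()
                window[k] = _TRANSITION[window[k]]
                deficit -= 2  # unavoidable 1-bond overshoot; tolerance-checked below
            else:
                raise GenerationError("no positions left to degrade")
        else:
            use2 = bool(rng.integers(0, 2)) if (drop1 and drop2) else bool(drop2)
            if use2:
                k = drop2.pop()
                degraded_gc.append(k)
                drop = 2
            else:
                k = drop1.pop()
                drop = 1
            window[k] = _TRANSITION[window[k]]
            deficit -= drop
    achieved = _ratio(mirna.sequence, "".join(window))
    if abs(achieved - target_ratio) > RATIO_TOLERANCE:
        raise GenerationError(
            f"planting target {target_ratio}% unreachable: achieved {achieved:.2f}%"
        )
    return "".join(window), achieved


def derive_mirna(
    window: str,
    target_ratio: float,
    rng: np.random.Generator,
    mirna_id: str,
    max_attempts: int = 500,
) -> tuple[MiRNA, float]:
    """A miRNA matching a fixed mRNA window at a target ratio.

    Starts from the exact reverse complement of the window and applies
    transitions to the miRNA (re-scoring after each edit, reverting
    overshoots) until the ratio is within RATIO_TOLERANCE of the target.
    Used for cluster members, whose windows overlap and cannot be edited.
    """
    seq = list(reverse_complement(window))
    current = _ratio("".join(seq), window)
    untouched = list(range(len(seq)))
    rng.shuffle(untouched)
    attempts = 0
    while current > target_ratio + RATIO_TOLERANCE:
        attempts += 1
        if attempts > max_attempts or not untouched:
            raise GenerationError(
                f"could not reach ratio {target_ratio}% for {mirna_id} (at {current:.2f}%)"
            )
        k = untouched.pop()
        old = seq[k]
        seq[k] = _TRANSITION[old]
        candidate = _ratio("".join(seq), window)
        if candidate < target_ratio - RATIO_TOLERANCE:
            seq[k] = old  # overshoot: revert, try another position
            continue
        current = candidate
    if abs(current - target_ratio) > RATIO_TOLERANCE:
        raise GenerationError(
            f"ratio {current:.2f}% outside target {target_ratio}+-{RATIO_TOLERANCE}"
        )
    return MiRNA(id=mirna_id, sequence="".join(seq)), current


def gen_ortholog_set(
    reference: str,
    n_species: int,
    sub_rate: float,
    transition_fraction: float,
    preserved_flanks: tuple[str, str] = ("", ""),
    rng: np.random.Generator | None = None,
    locus: str = "locus",
):
    """Ortholog set from a reference segment by i.i.d. per-site substitution.

    Positions inside the first occurrence of either preserved flank are
    never mutated; elsewhere each non-reference species substitutes each
    position with probability ``sub_rate``, drawing a transition with
    probability ``transition_fraction`` and a random transversion otherwise.
    """
    from .io_formats import OrthologSet  # deferred: keeps module import light

    rng = rng if rng is not None else np.random.default_rng(0)
    if n_species < 2 or n_species > len(SPECIES_CODES):
        raise GenerationError(f"n_species {n_species} outside [2, {len(SPECIES_CODES)}]")
    masked = np.zeros(len(reference), dtype=bool)
    for flank in preserved_flanks:
        if not flank:
            continue
        pos = reference.find(flank)
        if pos < 0:
            raise GenerationError(f"flank {flank!r} absent from the reference segment")
        masked[pos : pos + len(flank)] = True
    segments = {SPECIES_CODES[0]: reference}
    for species in SPECIES_CODES[1:n_species]:
        seq = list(reference)
        hit = (rng.random(len(reference)) < sub_rate) & ~masked
        for k in np.nonzero(hit)[0]:
            base = seq[k]
            if rng.random() < transition_fraction:
                seq[k] = _TRANSITION[base]
            else:
                seq[k] = _TRANSVERSIONS[base][int(rng.integers(0, 2))]
        segments[species] = "".join(seq)
    return OrthologSet(locus=locus, segments=segments, reference_species=SPECIES_CODES[0])


# --------------------------------------------------------------------------
# cohort assembly


def _draw_len(bounds: tuple[int, int], rng: np.random.Generator) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _region_bounds(utr5: int, cds_end: int, total: int, region: str) -> tuple[int, int]:
    return {
        "5UTR": (1, utr5),
        "CDS": (utr5 + 1, cds_end),
        "3UTR": (cds_end + 1, total),
    }[region]


class _TranscriptDraft:
    """Mutable transcript under construction, with occupancy bookkeeping."""

    def __init__(self, gene: str, transcript_id: str, utr5: int, cds: int, utr3: int,
                 gc: float, utr5_gc: float, rng: np.random.Generator):
        self.gene = gene
        self.transcript_id = transcript_id
        self.utr5_end = utr5
        self.cds_end = utr5 + cds
        body = random_sequence(cds + utr3, gc, rng)
        head = random_sequence(utr5, utr5_gc, rng)
        self.seq = list(head + body)
        self.occupied: list[tuple[int, int]] = []

    def __len__(self) -> int:
        return len(self.seq)

    def free_start(
        self, region: str, block_len: int, rng: np.random.Generator, margin: int = 26,
        attempts: int = 300,
    ) -> int:
        """A 1-based start for a block avoiding previously planted intervals."""
        lo, hi = _region_bounds(self.utr5_end, self.cds_end, len(self), region)
        hi = hi - block_len + 1
        if hi < lo:
            raise GenerationError(
                f"{self.transcript_id}: region {region} too short for a {block_len}-nt block"
            )
        for _ in range(attempts):
            start = int(rng.integers(lo, hi + 1))
            end = start + block_len - 1
            if all(end + margin < a or start - margin > b for a, b in self.occupied):
                self.occupied.append((start, end))
                return start
        raise GenerationError(f"{self.transcript_id}: no free {block_len}-nt slot in {region}")

    def write_block(self, start: int, block: str) -> None:
        self.seq[start - 1 : start - 1 + len(block)] = list(block)

    def freeze(self, rpkm: float) -> Transcript:
        return Transcript(
            transcript_id=self.transcript_id,
            gene=self.gene,
            sequence="".join(self.seq),
            utr5_end=self.utr5_end,
            cds_end=self.cds_end,
            rpkm=rpkm,
        )


def _periodic_mirna(length: int, spacing: int, rng: np.random.Generator, mirna_id: str) -> MiRNA:
    """A miRNA with period ``spacing``, so its complement tandem-repeats."""
    for _ in range(50):
        unit = random_sequence(spacing, 0.5, rng)
        seq = (unit * (length // spacing + 1))[:length]
        # reject units whose shifted phases still pair (degenerate repeats)
        if len(set(unit)) > 1:
            return MiRNA(id=mirna_id, sequence=seq)
    raise GenerationError("could not draw a non-degenerate repeat unit")


def gen_cohort(config: SimConfig) -> Cohort:
    """Generate miRNAs, transcripts and the ground truth of every planting."""
    rng = np.random.default_rng(config.seed)
    drafts: list[_TranscriptDraft] = []
    for g in range(config.n_genes):
        utr5 = _draw_len(config.utr5_len, rng)
        cds = _draw_len(config.cds_len, rng) // 3 * 3
        utr3 = _draw_len(config.utr3_len, rng)
        drafts.append(
            _TranscriptDraft(
                gene=f"G{g + 1:03d}",
                transcript_id=f"T{g + 1:03d}",
                utr5=utr5,
                cds=cds,
                utr3=utr3,
                gc=config.gc_fraction,
                utr5_gc=config.utr5_gc_fraction,
                rng=rng,
            )
        )

    mirnas: list[MiRNA] = []
    truth: dict = {
        "planted_sites": [],
        "polysites": [],
        "clusters": [],
        "offset_pairs": [],
        "ortholog": None,
        "rpkm": {},
    }
    gene_cycle = 0

    def next_draft() -> _TranscriptDraft:
        nonlocal gene_cycle
        if not drafts:
            raise GenerationError("planting requested but n_genes is 0")
        draft = drafts[gene_cycle % len(drafts)]
        gene_cycle += 1
        return draft

    def record_site(mirna: MiRNA, draft: _TranscriptDraft, start: int, ratio: float) -> None:
        truth["planted_sites"].append(
            {
                "mirna_id": mirna.id,
                "gene": draft.gene,
                "transcript_id": draft.transcript_id,
                "start": start,
                "length": len(mirna),
                "region": "",  # filled after freezing
                "achieved_ratio": ratio,
            }
        )

    # single sites and polysites -------------------------------------------
    for i, spec in enumerate(config.planted_sites):
        draft = next_draft()
        if spec.count > 1 and spec.spacing >= 2:
            mirna = _periodic_mirna(
                spec.mirna_length, spec.spacing, rng, f"sim-poly-{i + 1:02d}"
            )
            unit_rc = reverse_complement(mirna.sequence)[: spec.spacing]
            block_len = spec.mirna_length + (spec.count - 1) * spec.spacing
            block = (unit_rc * (block_len // spec.spacing + 1))[:block_len]
            start = draft.free_start(spec.region, block_len + 2, rng) + 1
            draft.write_block(start, block)
            # break the repeat phase just outside the block
            for edge, phase in ((start - 1, -1), (start + block_len, block_len)):
                forbidden = unit_rc[phase % spec.spacing]
                choices = [b for b in "ACGU" if b != forbidden]
                draft.write_block(edge, choices[int(rng.integers(0, 3))])
            starts = [start + k * spec.spacing for k in range(spec.count)]
            for s in starts:
                record_site(mirna, draft, s, 100.0)
            truth["polysites"].append(
                {
                    "mirna_id": mirna.id,
                    "gene": draft.gene,
                    "transcript_id": draft.transcript_id,
                    "starts": starts,
                    "spacing": spec.spacing,
                }
            )
        else:
            mirna = gen_mirna(spec.mirna_length, 0.5, rng, f"sim-miR-{i + 1:02d}")
            window, achieved = degrade_window(mirna, spec.target_ratio, rng)
            start = draft.free_start(spec.region, len(window), rng)
            draft.write_block(start, window)
            record_site(mirna, draft, start, achieved)
        mirnas.append(mirna)

    # clusters of overlapping sites ----------------------------------------
    for ci, spec in enumerate(config.clusters):
        draft = next_draft()
        region_len = spec.start_spread + spec.mirna_length
        anchor = draft.free_start(spec.region, region_len, rng)
        offsets = sorted(
            int(o) for o in rng.choice(spec.start_spread + 1, spec.n_mirnas, replace=True)
        )
        offsets[0] = 0  # pin the cluster to its anchor
        cluster_sites = []
        for mi, off in enumerate(offsets):
            start = anchor + off
            window = "".join(draft.seq[start - 1 : start - 1 + spec.mirna_length])
            target = float(rng.uniform(*spec.ratio_range))
            mirna, achieved = derive_mirna(
                window, target, rng, f"sim-clu{ci + 1}-{mi + 1:02d}"
            )
            mirnas.append(mirna)
            record_site(mirna, draft, start, achieved)
            cluster_sites.append((mirna.id, start, spec.mirna_length))
        truth["clusters"].append(
            {
                "transcript_id": draft.transcript_id,
                "gene": draft.gene,
                "members": [
                    {"mirna_id": m, "start": s, "length": L} for m, s, L in cluster_sites
                ],
                "span": [
                    min(s for _, s, _ in cluster_sites),
                    max(s + L - 1 for _, s, L in cluster_sites),
                ],
            }
        )

    # constant-offset pairs -------------------------------------------------
    for pi, spec in enumerate(config.offset_pairs):
        L = spec.mirna_length
        block = random_sequence(spec.offset + L, 0.55, rng)
        mirna_a = MiRNA(id=f"sim-off{pi + 1}-a", sequence=reverse_complement(block[:L]))
        mirna_b = MiRNA(id=f"sim-off{pi + 1}-b", sequence=reverse_complement(block[spec.offset :]))
        mirnas.extend([mirna_a, mirna_b])
        genes = []
        for _ in range(spec.n_genes):
            draft = next_draft()
            start = draft.free_start(spec.region, len(block), rng)
            draft.write_block(start, block)
            record_site(mirna_a, draft, start, 100.0)
            record_site(mirna_b, draft, start + spec.offset, 100.0)
            genes.append(draft.gene)
        truth["offset_pairs"].append(
            {
                "mirna_a": mirna_a.id,
                "mirna_b": mirna_b.id,
                "offset": spec.offset,
                "genes": genes,
            }
        )

    # expression values ------------------------------------------------------
    lo, hi = config.rpkm_range
    rpkms = np.exp(rng.normal(config.rpkm_log_mean, config.rpkm_log_sigma, config.n_genes))
    rpkms = np.clip(rpkms, lo, hi)
    n_high = int(round(config.rpkm_high_fraction * config.n_genes))
    if n_high:
        idx = rng.choice(config.n_genes, n_high, replace=False)
        rpkms[idx] = rng.uniform(*config.high_band, n_high)
    rpkms = np.round(rpkms, 1)

    transcripts = [d.freeze(float(r)) for d, r in zip(drafts, rpkms)]
    by_id = {t.transcript_id: t for t in transcripts}
    for rec in truth["planted_sites"]:
        rec["region"] = by_id[rec["transcript_id"]].region_of(rec["start"])
    truth["rpkm"] = {t.gene: t.rpkm for t in transcripts}

    # ortholog set around the first planted cluster (or a fresh segment) -----
    if config.ortholog is not None:
        spec = config.ortholog
        core = random_sequence(
            spec.cluster_length, 0.6, rng
        )
        pad = spec.segment_length - spec.cluster_length - len(spec.flank5) - len(spec.flank3)
        left = random_sequence(max(pad // 2, 0), 0.5, rng)
        right = random_sequence(max(pad - pad // 2, 0), 0.5, rng)
        reference = left + spec.flank5 + core + spec.flank3 + right
        oset = gen_ortholog_set(
            reference,
            spec.n_species,
            spec.sub_rate,
            spec.transition_fraction,
            (spec.flank5, spec.flank3),
            rng,
            locus="simlocus",
        )
        cluster_start = len(left) + len(spec.flank5) + 1
        truth["ortholog"] = {
            "locus": oset.locus,
            "segments": dict(oset.segments),
            "reference_species": oset.reference_species,
            "flank5": spec.flank5,
            "flank3": spec.flank3,
            "cluster": [cluster_start, cluster_start + spec.cluster_length - 1],
            "transition_fraction": spec.transition_fraction,
        }

    # unique miRNA ids sanity
    ids = [m.id for m in mirnas]
    if len(ids) != len(set(ids)):
        raise GenerationError("duplicate generated miRNA ids")
    return Cohort(mirnas=mirnas, transcripts=transcripts, ground_truth=truth)


def truth_sites(cohort: Cohort) -> list[BindingSite]:
    """Ground-truth plantings as BindingSite objects (for cluster checks)."""
    by_id = {t.transcript_id: t for t in cohort.transcripts}
    sites = []
    for rec in cohort.ground_truth["planted_sites"]:
        t = by_id[rec["transcript_id"]]
        sites.append(
            BindingSite(
                mirna_id=rec["mirna_id"],
                transcript_id=rec["transcript_id"],
                gene=rec["gene"],
                start=rec["start"],
                length=rec["length"],
                delta_g=0.0,
                ratio=rec["achieved_ratio"],
                region=rec["region"],
                rpkm=t.rpkm,
            )
        )
    return sites


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the four cohort artifacts; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirnas": outdir / "mirnas.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "annotations": outdir / "annotations.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_fasta([(m.id, m.sequence) for m in cohort.mirnas], paths["mirnas"])
    write_fasta(
        [(t.transcript_id, t.sequence) for t in cohort.transcripts], paths["transcripts"]
    )
    write_transcript_table(cohort.transcripts, paths["annotations"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
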