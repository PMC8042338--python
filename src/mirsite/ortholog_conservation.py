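"""Conservation of binding-site clusters across orthologous mRNAs.

Orthologous segments tend to diverge inside a cluster by transitions —
purine for purine (A↔G) or pyrimidine for pyrimidine (C↔U) — which swap
canonical pairs for the 1-bond non-canonical G-U / A-C pairs instead of
abolishing pairing, so the duplex survives with a modest ratio loss.  The
oligonucleotides flanking a cluster stay close to invariant.  This module
measures both effects: exact conserved flanks around a cluster interval,
substitution classification on a pairwise global alignment, per-species
re-scoring of a miRNA within homologous segments, inter-flank cluster
shrinkage, and peptide translation for CDS clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .duplex_core import DEFAULT_ENERGY_MODEL, EnergyModel
from .errors import ContractError, CoordinateError
from .io_formats import MiRNA, OrthologSet, Transcript
from .site_scanner import DEFAULT_THRESHOLDS, Thresholds, find_sites

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

#: Ratio bands used when reporting cross-species site strength.
RATIO_BANDS = ((90.0, ">=90"), (85.0, "85-90"), (80.0, "80-85"), (float("-inf"), "<80"))


@dataclass(frozen=True)
class AlignmentParams:
    """Fixed small-integer global-alignment scores (linear gaps).

    The default gap penalty is deliberately stiff relative to the mismatch
    cost: a compensating gap pair must rescue at least three substitutions
    before it outscores the ungapped diagonal, so ortholog segments that
    diverged by substitution alone align gapless in practice and their
    substitution classes are read off faithfully.
    """

    match: int = 2
    mismatch: int = -1
    gap: int = -4

    def __post_init__(self) -> None:
        if not (self.gap <= self.mismatch <= 0 < self.match):
            raise ContractError(f"invalid alignment params {self}")


DEFAULT_ALIGNMENT = AlignmentParams()


@dataclass(frozen=True)
class SubstitutionCounts:
    purine_transition: int = 0
    pyrimidine_transition: int = 0
    transversion: int = 0
    indel: int = 0

    @property
    def total(self) -> int:
        return self.purine_transition + self.pyrimidine_transition + self.transversion + self.indel


@dataclass(frozen=True)
class ConservationReport:
    """Cross-species summary of one cluster interval."""

    locus: str
    flank5: str
    flank3: str
    cluster_lengths: dict[str, int | None]  # species -> inter-flank length
    ratio_matrix: dict[str, dict[str, float | None]]  # mirna -> species -> best ratio
    bands: dict[str, dict[str, str]]
    substitutions: dict[str, SubstitutionCounts]  # species -> counts vs reference


def _aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap
    aligner.extend_gap_score = params.gap
    return aligner


def align_global(
    reference: str, other: str, params: AlignmentParams = DEFAULT_ALIGNMENT
) -> tuple[str, str, float]:
    """Optimal global alignment as two gapped strings plus its score."""
    alignment = _aligner(params).align(reference, other)[0]
    return str(alignment[0]), str(alignment[1]), alignment.score


def classify_substitutions(
    reference: str, other: str, params: AlignmentParams = DEFAULT_ALIGNMENT
) -> SubstitutionCounts:
    """Align two segments and classify aligned differences.

    Mismatched columns are purine transitions (A↔G), pyrimidine transitions
    (C↔U) or transversions (cross-class); gap columns count as indels.
    """
    if not reference or not other:
        raise ContractError("both segments must be non-empty")
    ref_aln, other_aln, _ = align_global(reference, other, params)
    pur = pyr = tv = indel = 0
    for a, b in zip(ref_aln, other_aln):
        if a == "-" or b == "-":
            indel += 1
        elif a != b:
            if a in PURINES and b in PURINES:
                pur += 1
            elif a in PYRIMIDINES and b in PYRIMIDINES:
                pyr += 1
            else:
                tv += 1
    return SubstitutionCounts(
        purine_transition=pur, pyrimidine_transition=pyr, transversion=tv, indel=indel
    )


def conserved_flanks(
    ortholog_set: OrthologSet, cluster: tuple[int, int], max_len: int = 10
) -> tuple[str, str]:
    """Longest oligonucleotides adjacent to the cluster shared by all species.

    ``cluster`` is a 1-based inclusive interval on the reference segment.
    The 5' flank is the longest suffix (≤ ``max_len``) of the sequence
    upstream of the cluster present in every species' segment; the 3' flank
    the longest prefix of the downstream sequence.  Either may be empty.
    """
    start, end = cluster
    reference = ortholog_set.reference
    if not (1 <= start <= end <= len(reference)):
        raise CoordinateError(
            f"cluster {cluster} outside reference segment 1..{len(reference)}"
        )
    upstream = reference[: start - 1]
    downstream = reference[end:]
    others = [seq for sp, seq in ortholog_set.segments.items()]

    def longest(candidates) -> str:
        for cand in candidates:  # longest first
            if cand and all(cand in seq for seq in others):
                return cand
        return ""

    flank5 = longest(upstream[-k:] for k in range(min(max_len, len(upstream)), 0, -1))
    flank3 = longest(downstream[:k] for k in range(min(max_len, len(downstream)), 0, -1))
    return flank5, flank3


def cluster_shrinkage(
    ortholog_set: OrthologSet,
    reference_cluster: tuple[int, int],
    max_flank: int = 10,
) -> dict[str, int | None]:
    """Per-species length of the homologous region between the matched flanks.

    Species in which either flank cannot be located are reported as None.
    """
    flank5, flank3 = conserved_flanks(ortholog_set, reference_cluster, max_flank)
    lengths: dict[str, int | None] = {}
    for species, segment in ortholog_set.segments.items():
        if flank5:
            i5 = segment.find(flank5)
            inner_start = i5 + len(flank5) if i5 >= 0 else -1
        else:
            inner_start = 0
        i3 = segment.find(flank3, max(inner_start, 0)) if flank3 else len(segment)
        if inner_start < 0 or i3 < 0:
            lengths[species] = None
        else:
            lengths[species] = i3 - inner_start
    return lengths


def rescore_across_species(
    mirna: MiRNA,
    ortholog_set: OrthologSet,
    model: EnergyModel = DEFAULT_ENERGY_MODEL,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> dict[str, dict]:
    """Best window ratio of one miRNA within each species' segment.

    Segments shorter than the miRNA are marked not evaluable.  The band
    labels (>=90 / 85-90 / 80-85 / <80) grade interaction strength.
    """
    result: dict[str, dict] = {}
    for species, segment in ortholog_set.segments.items():
        if len(segment) < len(mirna):
            result[species] = {"ratio": None, "start": None, "band": "not_evaluable"}
            continue
        transcript = Transcript(
            transcript_id=f"{species}|{ortholog_set.locus}",
            gene=ortholog_set.locus,
            sequence=segment,
        )
        # report threshold 0: we want the best window even when weak
        sites = find_sites(mirna, transcript, Thresholds(report=0.0, efficient=thresholds.efficient), model)
        best = max(sites, key=lambda s: (s.ratio, -s.start))
        result[species] = {
            "ratio": best.ratio,
            "start": best.start,
            "band": ratio_band(best.ratio),
        }
    return result


def ratio_band(ratio: float) -> str:
    for cutoff, label in RATIO_BANDS:
        if ratio >= cutoff:
            return label
    raise AssertionError("unreachable")


def translate_segment(segment: str, frame_offset: int = 0) -> str:
    """Translate complete codons after the frame offset; stops rendered '*'."""
    if frame_offset not in (0, 1, 2):
        raise ContractError(f"frame offset must be 0, 1 or 2, got {frame_offset}")
    effective = segment[frame_offset:]
    if len(effective) < 3:
        raise ContractError("effective sequence shorter than one codon")
    trimmed = effective[: len(effective) - len(effective) % 3]
    return str(Seq(trimmed).translate())


def conservation_report(
    ortholog_set: OrthologSet,
    cluster: tuple[int, int],
    mirnas: list[MiRNA] | None = None,
    model: EnergyModel = DEFAULT_ENERGY_MODEL,
    max_flank: int = 10,
    params: AlignmentParams = DEFAULT_ALIGNMENT,
) -> ConservationReport:
    """Assemble flanks, shrinkage, substitution counts and a ratio matrix."""
    flank5, flank3 = conserved_flanks(ortholog_set, cluster, max_flank)
    lengths = cluster_shrinkage(ortholog_set, cluster, max_flank)
    reference = ortholog_set.reference
    substitutions = {
        species: classify_substitutions(reference, segment, params)
        for species, segment in ortholog_set.segments.items()
        if species != ortholog_set.reference_species
    }
    ratio_matrix: dict[str, dict[str, float | None]] = {}
    bands: dict[str, dict[str, str]] = {}
    for mirna in mirnas or []:
        per_species = rescore_across_species(mirna, ortholog_set, model)
        ratio_matrix[mirna.id] = {sp: rec["ratio"] for sp, rec in per_species.items()}
        bands[mirna.id] = {sp: rec["band"] for sp, rec in per_species.items()}
    return ConservationReport(
        locus=ortholog_set.locus,
        flank5=flank5,
        flank3=flank3,
        cluster_lengths=lengths,
        ratio_matrix=ratio_matrix,
        bands=bands,
        substitutions=substitutions,
    )
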