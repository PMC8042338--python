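"""Expression context and marker ranking of miRNA-gene associations.

Whether a predicted interaction matters in vivo depends on the target's
expression: weakly expressed genes (RPKM < 10) are easily silenced by a
strong site, while highly expressed genes need comparably high miRNA
concentrations.  An association is flagged as a candidate diagnostic
marker when its strongest site binds with |ΔG| above a cutoff (default
130 kJ/mol) or when the miRNA holds multiple sites on the gene (default
≥ 5), since repeated sites buffer the interaction against point mutations.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace

from scipy import stats

from .errors import ContractError, UndefinedCorrelationError
from .site_scanner import BindingSite

EXPRESSION_BREAKPOINT_RPKM = 10.0


@dataclass(frozen=True)
class Association:
    """One miRNA-gene association summarized over its sites."""

    mirna_id: str
    gene: str
    region: str
    start: int
    delta_g: float
    ratio: float
    n_sites: int
    rpkm: float
    expression_class: str = "low"
    marker: bool = False


def classify_expression(rpkm: float) -> str:
    """Two-class expression label: low below 10 RPKM, high at or above."""
    if not rpkm >= 0:
        raise ContractError(f"RPKM must be non-negative, got {rpkm}")
    return "high" if rpkm >= EXPRESSION_BREAKPOINT_RPKM else "low"


def build_associations(sites: list[BindingSite]) -> list[Association]:
    """Aggregate sites into per-(miRNA, gene) associations.

    The representative site is the one with the largest |ΔG| (ties broken
    by higher ratio, then earlier start).
    """
    grouped: dict[tuple[str, str], list[BindingSite]] = defaultdict(list)
    for s in sites:
        grouped[(s.mirna_id, s.gene)].append(s)
    associations = []
    for (mirna_id, gene), members in sorted(grouped.items()):
        best = min(members, key=lambda s: (s.delta_g, -s.ratio, s.start))
        rpkm = best.rpkm
        associations.append(
            Association(
                mirna_id=mirna_id,
                gene=gene,
                region=best.region,
                start=best.start,
                delta_g=best.delta_g,
                ratio=best.ratio,
                n_sites=len(members),
                rpkm=rpkm,
                expression_class=(
                    classify_expression(rpkm) if not math.isnan(rpkm) else "low"
                ),
            )
        )
    return associations


def marker_candidates(
    associations: list[Association],
    dg_cutoff: float = 130.0,
    multisite_min: int = 5,
) -> list[Association]:
    """Set the marker flag: strict |ΔG| > cutoff OR ≥ multisite_min sites."""
    return [
        replace(
            a,
            marker=(abs(a.delta_g) > dg_cutoff) or (a.n_sites >= multisite_min),
        )
        for a in associations
    ]


def pearson_r(x: list[float], y: list[float]) -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    if len(x) != len(y) or len(x) < 3:
        raise ContractError("pearson_r needs two equal-length vectors of length >= 3")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise UndefinedCorrelationError("zero variance in an input vector")
    return float(stats.pearsonr(x, y).statistic)
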