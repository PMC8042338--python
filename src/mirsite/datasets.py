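"""Curated worked-example site tables for human PD candidate genes.

Published characteristics of miRNA binding sites on the mRNAs of several
Parkinson's-disease candidate genes (GSK3B, CCNY, FOXO1, SETD1A, VSNL1,
LRP10, PDP2, RBBP5, SLC14A1): per-site start position, site length and,
where available, free energy and ratio.  Start-range notations like
"1,021÷1,045 (13)" are stored expanded, one start per entry.  These rows
are inputs to the cluster/compaction, offset and polysite worked examples
and regression tests; the sequences themselves are not part of the tables.

Row format: (gene, rpkm, mirna_id, start, length, delta_g, ratio).
``delta_g``/``ratio`` are None where a row lists a value range rather than
per-start values; the cluster arithmetic only needs starts and lengths.
"""

from __future__ import annotations

from .site_scanner import BindingSite

# --- 5'UTR sites -----------------------------------------------------------

GSK3B_5UTR_ROWS = [
    ("GSK3B", 8.3, "ID02187.5p-miR", 3, 23, -123.0, 89.0),
    ("GSK3B", 8.3, "ID03229.5p-miR", 4, 22, -123.0, 92.0),
    ("GSK3B", 8.3, "ID01804.3p-miR", 5, 23, -134.0, 91.0),
    ("GSK3B", 8.3, "ID01804.3p-miR", 12, 23, -134.0, 91.0),
    ("GSK3B", 8.3, "ID00756.3p-miR", 8, 23, -123.0, 89.0),
    ("GSK3B", 8.3, "ID01041.5p-miR", 8, 24, -132.0, 90.0),
    ("GSK3B", 8.3, "ID02294.5p-miR", 8, 24, -127.0, 87.0),
    ("GSK3B", 8.3, "ID00457.3p-miR", 8, 22, -123.0, 91.0),
    ("GSK3B", 8.3, "ID00457.3p-miR", 11, 22, -129.0, 95.0),
    ("GSK3B", 8.3, "ID03367.5p-miR", 11, 20, -119.0, 95.0),
    ("GSK3B", 8.3, "ID00061.3p-miR", 8, 22, -125.0, 91.0),
    ("GSK3B", 8.3, "ID00061.3p-miR", 11, 22, -136.0, 98.0),
    ("GSK3B", 8.3, "ID00296.3p-miR", 9, 25, -138.0, 88.0),
    ("GSK3B", 8.3, "ID01641.3p-miR", 9, 24, -127.0, 86.0),
    ("GSK3B", 8.3, "ID03151.3p-miR", 9, 20, -115.0, 93.0),
    ("GSK3B", 8.3, "ID03151.3p-miR", 12, 20, -115.0, 93.0),
    ("GSK3B", 8.3, "ID03229.5p-miR", 10, 22, -123.0, 92.0),
    ("GSK3B", 8.3, "ID01702.3p-miR", 13, 24, -140.0, 93.0),
    ("GSK3B", 8.3, "ID02064.5p-miR", 10, 23, -129.0, 90.0),
    ("GSK3B", 8.3, "ID02064.5p-miR", 13, 23, -136.0, 94.0),
    ("GSK3B", 8.3, "ID01873.3p-miR", 11, 21, -123.0, 94.0),
    ("GSK3B", 8.3, "miR-3960", 11, 20, -115.0, 92.0),
    ("GSK3B", 8.3, "miR-3960", 14, 20, -115.0, 92.0),
    ("GSK3B", 8.3, "ID02522.3p-miR", 12, 23, -127.0, 91.0),
    ("GSK3B", 8.3, "ID02499.3p-miR", 13, 21, -119.0, 92.0),
    ("GSK3B", 8.3, "ID02429.3p-miR", 14, 23, -125.0, 92.0),
    ("GSK3B", 8.3, "ID01652.3p-miR", 15, 23, -125.0, 89.0),
    ("GSK3B", 8.3, "ID02538.3p-miR", 15, 22, -121.0, 90.0),
]

CCNY_5UTR_ROWS = [
    ("CCNY", 19.7, "ID01041.5p-miR", 1, 24, -136.0, 93.0),
    ("CCNY", 19.7, "ID01873.3p-miR", 1, 21, -123.0, 94.0),
    ("CCNY", 19.7, "ID00296.3p-miR", 4, 25, -140.0, 89.0),
    ("CCNY", 19.7, "ID01702.3p-miR", 4, 24, -134.0, 89.0),
    ("CCNY", 19.7, "ID01641.3p-miR", 4, 24, -132.0, 89.0),
    ("CCNY", 19.7, "ID01106.5p-miR", 7, 24, -132.0, 89.0),
    ("CCNY", 19.7, "ID01879.5p-miR", 8, 22, -129.0, 95.0),
    ("CCNY", 19.7, "ID02229.3p-miR", 9, 21, -121.0, 92.0),
    ("CCNY", 19.7, "ID02499.3p-miR", 9, 21, -123.0, 95.0),
    ("CCNY", 19.7, "ID03027.3p-miR", 11, 24, -121.0, 85.0),
]

#: Published bounds of the first CCNY 5'UTR cluster (nine member sites).
CCNY_CLUSTER1_INTERVAL = (1, 30)

#: 5'UTR length of the CCNY transcript.
CCNY_UTR5_LEN = 180

# --- CDS sites -------------------------------------------------------------

FOXO1_CDS_ROWS = [
    ("FOXO1", 2.5, "ID03332.3p-miR", 655, 24, -136.0, 91.0),
    ("FOXO1", 2.5, "ID03332.3p-miR", 658, 24, -140.0, 94.0),
    ("FOXO1", 2.5, "ID02761.3p-miR", 661, 24, -132.0, 89.0),
    ("FOXO1", 2.5, "ID02611.3p-miR", 660, 22, -125.0, 91.0),
    ("FOXO1", 2.5, "ID00171.3p-miR", 666, 20, -117.0, 93.0),
    ("FOXO1", 2.5, "ID01804.3p-miR", 672, 23, -136.0, 93.0),
]

#: Published bounds of the FOXO1 CDS cluster.
FOXO1_CLUSTER_INTERVAL = (655, 695)

SETD1A_CDS_CLUSTER_ROWS = [
    ("SETD1A", 4.5, "ID02538.3p-miR", 4877, 22, -121.0, 90.0),
    ("SETD1A", 4.5, "ID01641.3p-miR", 4894, 24, -132.0, 89.0),
    ("SETD1A", 4.5, "ID01641.3p-miR", 4900, 24, -140.0, 94.0),
    ("SETD1A", 4.5, "ID01323.3p-miR", 4898, 22, -123.0, 91.0),
    ("SETD1A", 4.5, "miR-3960", 4899, 20, -115.0, 92.0),
    ("SETD1A", 4.5, "ID00296.3p-miR", 4900, 25, -140.0, 89.0),
    ("SETD1A", 4.5, "ID01702.3p-miR", 4900, 24, -134.0, 89.0),
    ("SETD1A", 4.5, "ID01959.3p-miR", 4905, 21, -117.0, 92.0),
    ("SETD1A", 4.5, "ID00962.3p-miR", 4905, 23, -117.0, 89.0),
]

#: Published bounds of the SETD1A CDS cluster.
SETD1A_CLUSTER_INTERVAL = (4877, 4928)

# --- 3'UTR sites (offset and polysite examples) ----------------------------

LRP10_3UTR_ROWS = [
    ("LRP10", 7.8, "miR-5096", 3237, 21, -104.0, 92.0),
    ("LRP10", 7.8, "ID02175.3p-miR", 3353, 22, -110.0, 91.0),
    ("LRP10", 7.8, "miR-5585-3p", 3305, 22, -115.0, 98.0),
    ("LRP10", 7.8, "miR-1285-5p", 3404, 21, -102.0, 91.0),
    ("LRP10", 7.8, "miR-619-5p", 3497, 22, -110.0, 91.0),
    ("LRP10", 7.8, "miR-4452", 3544, 23, -108.0, 94.0),
    ("LRP10", 7.8, "miR-5095", 3788, 21, -106.0, 91.0),
    ("LRP10", 7.8, "miR-619-5p", 3794, 22, -115.0, 95.0),
    ("LRP10", 7.8, "ID00913.5p-miR", 3814, 23, -117.0, 92.0),
]

PDP2_3UTR_ROWS = [
    ("PDP2", 1.2, "ID00047.3p-miR", 3220, 21, -110.0, 93.0),
    ("PDP2", 1.2, "miR-5096", 3920, 21, -108.0, 96.0),
    ("PDP2", 1.2, "miR-619-5p", 3980, 22, -113.0, 93.0),
    ("PDP2", 1.2, "miR-5585-3p", 3987, 22, -106.0, 91.0),
    ("PDP2", 1.2, "miR-1285-5p", 4086, 21, -102.0, 91.0),
    ("PDP2", 1.2, "ID01200.3p-miR", 4511, 21, -102.0, 91.0),
    ("PDP2", 1.2, "miR-1273a", 4639, 25, -119.0, 90.0),
    ("PDP2", 1.2, "miR-1273c", 4641, 22, -110.0, 91.0),
    ("PDP2", 1.2, "miR-1273g-3p", 4661, 21, -106.0, 91.0),
    ("PDP2", 1.2, "ID01360.3p-miR", 5493, 21, -104.0, 91.0),
    ("PDP2", 1.2, "miR-3159", 5861, 22, -106.0, 91.0),
    ("PDP2", 1.2, "miR-619-5p", 5863, 22, -113.0, 93.0),
    ("PDP2", 1.2, "miR-619-5p", 5988, 22, -110.0, 91.0),
    ("PDP2", 1.2, "miR-619-5p", 6173, 22, -119.0, 98.0),
    ("PDP2", 1.2, "miR-5096", 6247, 21, -108.0, 96.0),
    ("PDP2", 1.2, "miR-619-5p", 6308, 22, -117.0, 96.0),
    ("PDP2", 1.2, "ID01836.5p-miR", 6398, 23, -113.0, 90.0),
    ("PDP2", 1.2, "miR-5096", 6413, 21, -102.0, 91.0),
]

RBBP5_3UTR_ROWS = [
    ("RBBP5", 3.9, "miR-5095", 3065, 21, -108.0, 93.0),
    ("RBBP5", 3.9, "miR-619-5p", 3071, 22, -113.0, 93.0),
    ("RBBP5", 3.9, "miR-5096", 3145, 21, -106.0, 94.0),
    ("RBBP5", 3.9, "ID03006.5p-miR", 4015, 24, -121.0, 89.0),
    ("RBBP5", 3.9, "miR-619-5p", 4030, 22, -115.0, 95.0),
    ("RBBP5", 3.9, "miR-5096", 4104, 21, -106.0, 94.0),
    ("RBBP5", 3.9, "miR-3159", 4163, 22, -106.0, 91.0),
    ("RBBP5", 3.9, "ID02175.3p-miR", 4220, 22, -113.0, 93.0),
    ("RBBP5", 3.9, "ID01237.3p-miR", 4271, 24, -117.0, 92.0),
]

SLC14A1_3UTR_ROWS = [
    ("SLC14A1", 8.5, "miR-5095", 2771, 21, -110.0, 95.0),
    ("SLC14A1", 8.5, "miR-619-5p", 2777, 22, -119.0, 98.0),
    ("SLC14A1", 8.5, "miR-5096", 2851, 21, -102.0, 91.0),
    ("SLC14A1", 8.5, "miR-619-5p", 3215, 22, -115.0, 95.0),
    ("SLC14A1", 8.5, "ID01836.5p-miR", 3003, 23, -113.0, 90.0),
]

#: VSNL1 polysites: miR-574-5p 13 starts and ID00470.5p-miR 12 starts, 2-nt
#: spacing over the 1,021-1,045 tandem-repeat region.
VSNL1_3UTR_ROWS = [
    ("VSNL1", 206.5, "miR-574-5p", start, 23, -110.0, 91.0)
    for start in range(1021, 1046, 2)
] + [
    ("VSNL1", 206.5, "ID00470.5p-miR", start, 23, -108.0, 89.0)
    for start in range(1023, 1046, 2)
]


def rows_to_sites(rows, region: str, transcript_id: str | None = None) -> list[BindingSite]:
    """Materialize curated rows as BindingSite objects for the analyses."""
    sites = []
    for gene, rpkm, mirna_id, start, length, delta_g, ratio in rows:
        sites.append(
            BindingSite(
                mirna_id=mirna_id,
                transcript_id=transcript_id or gene,
                gene=gene,
                start=start,
                length=length,
                delta_g=delta_g if delta_g is not None else 0.0,
                ratio=ratio if ratio is not None else 0.0,
                region=region,
                efficient=bool(ratio is not None and ratio >= 90.0),
                rpkm=rpkm,
            )
        )
    return sites


def sites_within(sites: list[BindingSite], interval: tuple[int, int]) -> list[BindingSite]:
    """Sites whose whole interval lies inside a stated cluster interval."""
    lo, hi = interval
    return [s for s in sites if lo <= s.start and s.end <= hi]


#: All 3'UTR offset-example rows in one list.
OFFSET_EXAMPLE_ROWS = LRP10_3UTR_ROWS + PDP2_3UTR_ROWS + RBBP5_3UTR_ROWS + SLC14A1_3UTR_ROWS
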