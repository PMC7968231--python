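"""Published bitter gourd InDel map and marker-development reference numbers.

Per-linkage-group summary of the published 164-marker InDel F2 genetic map
of bitter gourd ('47-2-1-1-3' x '04-17'), and the marker-development funnel
counts from the same study (389,487 InDels among 61 accessions on the
~300 Mb 'Dali-11' genome; 3,511 PIC >= 0.6 candidates; 3,140 designed,
2,502 unique, 2,466 amplified, 212 polymorphic primer pairs).  These
printed values serve as fixed inputs for arithmetic consistency checks of
the summary and report layers; the underlying genotype data are not
redistributed here.
"""

from __future__ import annotations

import pandas as pd

# (lg_id, pseudochromosome, marker_no, genetic_cM, printed density cM/marker,
#  physical_Mb, printed recombination rate cM/Mb)
MAP_SUMMARY_PUBLISHED = [
    ("LG1", "MC01", 7, 55.64, 7.94, 6.30, 8.83),
    ("LG2", "MC01", 6, 27.84, 4.64, 2.49, 11.18),
    ("LG3", "MC02", 14, 86.72, 6.19, 7.82, 11.09),
    ("LG4", "MC03", 16, 112.04, 7.00, 16.14, 6.94),
    ("LG5", "MC04", 10, 86.93, 8.69, 15.11, 5.75),
    ("LG6", "MC05", 8, 55.19, 6.90, 4.02, 13.73),
    ("LG7", "MC05", 12, 97.78, 8.15, 12.19, 8.02),
    ("LG8", "MC06", 26, 210.70, 8.10, 26.34, 8.00),
    ("LG9", "MC07", 6, 17.07, 2.85, 1.46, 11.69),
    ("LG10", "MC08", 17, 117.06, 6.89, 10.72, 10.92),
    ("LG11", "MC08", 9, 89.78, 9.98, 6.77, 13.26),
    ("LG12", "MC09", 9, 104.74, 11.64, 14.50, 7.22),
    ("LG13", "MC10", 12, 106.04, 8.84, 10.22, 10.38),
    ("LG14", "MC11", 6, 60.38, 10.06, 5.72, 10.56),
    ("LG15", "MC11", 6, 51.77, 8.63, 8.26, 6.27),
]

# published totals row: markers, cM, cM/marker, Mb, cM/Mb
MAP_TOTALS_PUBLISHED = (164, 1279.68, 7.80, 148.06, 8.64)

FUNNEL_PUBLISHED = {
    "indels_total": 389_487,
    "genome_mb": 300.0,
    "accessions": 61,
    "selected_pic06": 3_511,
    "primer_pairs_designed": 3_140,
    "primer_pairs_unique": 2_502,
    "markers_amplified": 2_466,
    "markers_polymorphic": 212,
    "f2_individuals": 113,
    "map_markers_loaded": 189,
    "map_markers_placed": 164,
    "linkage_groups": 15,
}


def map_summary_rows() -> pd.DataFrame:
    """Published per-LG (marker_no, genetic, physical) triples in the layout
    consumed by :func:`indelkit.linkage.summary_from_rows`."""
    return pd.DataFrame(
        [(lg, chrom, n, cm, mb) for lg, chrom, n, cm, _, mb, _ in MAP_SUMMARY_PUBLISHED],
        columns=["lg_id", "chrom", "marker_no", "genetic_cM", "physical_Mb"],
    )
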