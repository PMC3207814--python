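"""Published example inputs used by the validation tests and reports.

``TOP20_COUNTS`` holds the printed per-gene tag counts (76 bp and 39 bp
runs, focal species first) for the twenty highest-fold genes of the
cross-species liver comparison this package re-implements, together with
the fold difference printed alongside them.  ``SOLEXA_QPCR_COUNTS`` holds
the printed tag counts for the transcripts carried into the qPCR
cross-validation.
"""

from __future__ import annotations

from .dex import GeneCountRecord

# gene, focal_76, focal_39, ref_76, ref_39, printed corrected fold
TOP20_COUNTS: list[tuple[str, int, int, int, int, float]] = [
    ("Epcam", 37073, 596, 27, 4, 290.4),
    ("Suclg2", 31261, 1075, 23, 14, 252.9),
    ("Gulp1", 25654, 926, 23, 1, 207.7),
    ("Acmsd", 31590, 1166, 66, 3, 189.8),
    ("Eif4g1", 19309, 339, 5, 8, 183.1),
    ("Tyro3", 18421, 4336, 8, 0, 169.9),
    ("Upb1", 19335, 2868, 25, 21, 154.2),
    ("Tspan1", 14695, 903, 0, 0, 146.5),
    ("A2m", 202485, 14461, 1307, 0, 143.9),
    ("Ugt1a10", 21227, 981, 56, 168, 135.8),
    ("Scd3", 14613, 2961, 11, 7, 131.4),
    ("Rpl39l", 12512, 4230, 1, 0, 123.6),
    ("Rpl26", 74402, 3182, 507, 144, 122.5),
    ("Fau", 21058, 7205, 87, 358, 112.5),
    ("Amacr", 11959, 721, 11, 7, 107.7),
    ("Crym", 19454, 5099, 86, 4, 104.6),
    ("Upp2", 11671, 1140, 22, 6, 95.7),
    ("Moxd1", 9523, 1438, 5, 0, 90.8),
    ("Mt2", 16106, 3522, 78, 12, 90.5),
    ("Sdc2", 13769, 1218, 56, 56, 88.3),
]

# transcript -> mapped tag count for the qPCR comparison's housekeeping genes
SOLEXA_QPCR_COUNTS: dict[str, int] = {"Hprt1": 249, "Tbp": 57}


def top20_records() -> list[GeneCountRecord]:
    """The printed counts as GeneCountRecord objects (76 bp + 39 bp replicate)."""
    return [
        GeneCountRecord(gene, float(f76), float(r76), float(f39), float(r39))
        for gene, f76, f39, r76, r39, _fold in TOP20_COUNTS
    ]


def top20_printed_folds() -> dict[str, float]:
    return {gene: fold for gene, _f76, _f39, _r76, _r39, fold in TOP20_COUNTS}
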