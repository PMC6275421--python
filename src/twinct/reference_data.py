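"""Published values from the cord-blood twin miRNA qRT-PCR study reanalyzed here.

The study profiled 44 miRNAs in CD133+ hematopoietic stem cells from cord
blood of identical and fraternal newborn twins and printed three result
tables: the most highly expressed assays per twin with their ΔCT values, the
within-pair discordance folds split into high (> 10-fold) and low (< 2-fold)
lists, and the genetics-vs-environment group (A–D) of each highly discordant
miRNA.  Those printed numbers are transcribed here verbatim; they are the
desk-scale inputs every regression in this package recomputes from.

Notes on the printed material:

* Only the high and low discordance lists are printed; the moderate folds
  (2–10) are not.  The two group-D members absent from the fraternal lists
  (miR-24, miR-19b) are therefore necessarily fraternal-moderate; they are
  represented by :data:`FRATERNAL_MODERATE_ONLY` with a nominal mid-range
  fold — the grouping rule needs only their not-high bin.
* ``miR-129-3P`` (fraternal list) and ``miR-129-3p`` (identical list) are the
  same assay; names here keep the capitalized spelling.
* The published correlations between co-twin expression profiles were
  r = 0.61 (identical) and r = 0.15 (fraternal); the full 44-row ΔCT matrix
  behind them is not printed, so they enter only the heritability
  arithmetic, not a recomputation.
"""

from __future__ import annotations

__all__ = [
    "FRATERNAL_DCT_PAIRS",
    "IDENTICAL_DCT_PAIRS",
    "FRATERNAL_FOLDS",
    "IDENTICAL_FOLDS",
    "FRATERNAL_MODERATE_ONLY",
    "GROUP_MEMBERSHIP",
    "PUBLISHED_R_MZ",
    "PUBLISHED_R_DZ",
    "NOT_EXPRESSED_ASSAY",
]

#: Per-twin ΔCT for assays printed in BOTH columns of the fraternal
#: highest-expression list (twin A, twin B).
FRATERNAL_DCT_PAIRS: dict[str, tuple[float, float]] = {
    "miR-10a": (10.07, 13.03),
    "miR-20a": (9.77, 14.05),
    "miR-125d": (9.07, 14.06),
    "miR-181d": (9.07, 16.08),
    "miR-29a": (9.07, 14.88),
    "miR-34b": (8.12, 14.11),
}

#: Same for the identical-twin highest-expression list.
IDENTICAL_DCT_PAIRS: dict[str, tuple[float, float]] = {
    "miR-181d": (10.82, 10.40),
    "miR-20a": (10.82, 10.34),
    "miR-29a": (10.82, 10.05),
    "miR-10a": (8.82, 10.29),
    "miR-19a": (5.82, 9.80),
}

#: Printed fraternal within-pair discordance folds (20 high + 10 low = 30).
FRATERNAL_FOLDS: dict[str, float] = {
    "miR-129-3P": 8248.98,
    "miR-106b": 7858.29,
    "miR-34c-3p": 2105.57,
    "miR-34a": 261.37,
    "miR-125a-3p": 131.59,
    "miR-181d": 128.89,
    "miR-17": 123.63,
    "miR-519d": 66.25,
    "miR-34b": 63.55,
    "miR-181b": 61.81,
    "miR-181a": 56.10,
    "miR-29a": 56.10,
    "miR-125b": 31.77,
    "miR-181c": 31.12,
    "miR-19a": 30.69,
    "miR-144": 28.24,
    "miR-20a": 19.42,
    "miR-520h": 17.38,
    "miR-130a": 15.45,
    "miR-34c-5p": 13.64,
    "miR-223": 1.97,
    "miR-155": 1.94,
    "miR-107": 1.93,
    "miR-142-5p": 1.91,
    "miR-411": 1.35,
    "miR-221": 1.00,
    "miR-92a": 1.00,
    "miR-10b": 1.00,
    "miR-20b": 1.00,
    "miR-93": 1.00,
}

#: Printed identical within-pair discordance folds (13 high + 19 low = 32).
IDENTICAL_FOLDS: dict[str, float] = {
    "miR-181b": 837.53,
    "miR-181c": 689.78,
    "miR-144": 352.13,
    "miR-130a": 158.68,
    "miR-125a-3p": 93.05,
    "miR-519d": 47.17,
    "miR-520h": 47.17,
    "miR-181a": 24.08,
    "miR-19b": 23.75,
    "miR-17": 22.16,
    "miR-19a": 15.77,
    "miR-92a": 10.92,
    "miR-24": 10.63,
    "miR-29a": 1.70,
    "miR-221": 1.47,
    "miR-20a": 1.39,
    "miR-155": 1.38,
    "miR-22": 1.38,
    "miR-411": 1.37,
    "miR-181d": 1.33,
    "miR-16": 1.31,
    "miR-34c-3p": 1.31,
    "miR-106b": 1.21,
    "miR-34a": 1.20,
    "miR-34b": 1.20,
    "miR-34c-5p": 1.16,
    "miR-9": 1.01,
    "miR-129-3P": 1.00,
    "miR-125b": 1.00,
    "miR-10b": 1.00,
    "miR-125a-5p": 1.00,
    "miR-128": 1.00,
}

#: Group-D members whose fraternal fold is unprinted (hence 2–10, moderate);
#: the nominal value 5.0 stands in only so a bin can be computed.
FRATERNAL_MODERATE_ONLY: dict[str, float] = {
    "miR-24": 5.0,
    "miR-19b": 5.0,
}

#: Published genetics-vs-environment group of each highly discordant miRNA.
GROUP_MEMBERSHIP: dict[str, str] = {
    "miR-129-3P": "A",
    "miR-106b": "A",
    "miR-34c-3p": "A",
    "miR-34a": "A",
    "miR-34b": "A",
    "miR-29a": "A",
    "miR-125b": "A",
    "miR-34c-5p": "A",
    "miR-20a": "A",
    "miR-181b": "B",
    "miR-181c": "B",
    "miR-144": "B",
    "miR-520h": "B",
    "miR-130a": "B",
    "miR-181d": "C",
    "miR-17": "C",
    "miR-519d": "C",
    "miR-181a": "C",
    "miR-19a": "C",
    "miR-125a-3p": "C",
    "miR-24": "D",
    "miR-19b": "D",
    "miR-92a": "D",
}

#: Co-twin profile correlations as published (full matrix not printed).
PUBLISHED_R_MZ = 0.61
PUBLISHED_R_DZ = 0.15

#: The one assay undetected in every sample of the study.
NOT_EXPRESSED_ASSAY = "miR-10b"
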