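"""Within-pair expression discordance: fold changes, bins and A–D groups.

The discordance of a miRNA within a twin pair is the fold difference between
the co-twins' relative expression, ``2^|ΔCT_A − ΔCT_B|`` — always ≥ 1 and
symmetric in the two twins.  Folds are binned as

* low       — fold < 2
* moderate  — 2 ≤ fold ≤ 10
* high      — fold > 10

(the boundary values 2 and 10 fall in the moderate bin: the bin definitions
use strictly "more than 10-fold" and "less than 2-fold").

Comparing a miRNA's fraternal-twin discordance with its identical-twin
discordance classifies how much of its expression variability is genetic
versus environmental:

* **A** — high in fraternal, low in identical: genetic differences dominate.
* **B** — high in both, identical ≥ fraternal: environment dominates.
* **C** — high in both, fraternal > identical: both contribute.
* **D** — high in identical only: environment acts despite shared genomes.

Any other combination (e.g. moderate bins) is left unclassified (``none``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .ct_io import DZ, MZ, DesignError, TwinDesign
from .normalization import ExpressionMatrix

__all__ = [
    "BinThresholds",
    "DiscordanceRecord",
    "GroupAssignment",
    "discordance_fold",
    "classify_discordance",
    "pair_discordance",
    "bin_counts",
    "zygosity_composite_folds",
    "assign_group",
    "assign_groups",
    "LOW",
    "MODERATE",
    "HIGH",
    "NOT_EXPRESSED",
]

LOW = "low"
MODERATE = "moderate"
HIGH = "high"
NOT_EXPRESSED = "not_expressed"


@dataclass(frozen=True)
class BinThresholds:
    """Fold cut-points: low strictly below ``low_below``, high strictly above
    ``high_above``."""

    low_below: float = 2.0
    high_above: float = 10.0

    def __post_init__(self) -> None:
        if not (1.0 <= self.low_below < self.high_above):
            raise ValueError("thresholds must satisfy 1 <= low_below < high_above")


@dataclass(frozen=True)
class DiscordanceRecord:
    """One miRNA's discordance within one twin pair."""

    mirna: str
    pair_id: str
    zygosity: str
    dct_a: float | None
    dct_b: float | None
    fold: float | None
    bin: str


@dataclass(frozen=True)
class GroupAssignment:
    """Genetics-vs-environment group of one miRNA across the two zygosities."""

    mirna: str
    group: str  # "A" | "B" | "C" | "D" | "none"
    fraternal_fold: float | None
    identical_fold: float | None
    not_expressed: bool = False


def discordance_fold(dct_a: float, dct_b: float) -> float:
    """``2^|dct_a − dct_b|``: the within-pair expression fold difference."""
    return 2.0 ** abs(dct_a - dct_b)


def classify_discordance(fold: float, thresholds: BinThresholds = BinThresholds()) -> str:
    if fold < 1.0:
        raise ValueError(f"a discordance fold is >= 1 by construction, got {fold}")
    if fold < thresholds.low_below:
        return LOW
    if fold > thresholds.high_above:
        return HIGH
    return MODERATE


def pair_discordance(
    expr: ExpressionMatrix,
    design: TwinDesign,
    thresholds: BinThresholds = BinThresholds(),
) -> list[DiscordanceRecord]:
    """One record per (miRNA, pair); flagged cells yield a not_expressed bin.

    A pair whose member sample is absent from the expression matrix is a
    design error.
    """
    absent = [s for s in design.sample_ids if s not in expr.values.columns]
    if absent:
        raise DesignError(f"pair member sample(s) missing from expression matrix: {', '.join(absent)}")
    records: list[DiscordanceRecord] = []
    for pair_id, zygosity, sample_a, sample_b in design.pairs():
        col_a = expr.values[sample_a]
        col_b = expr.values[sample_b]
        for mirna in expr.mirnas:
            a, b = col_a[mirna], col_b[mirna]
            if pd.isna(a) or pd.isna(b):
                records.append(
                    DiscordanceRecord(mirna, pair_id, zygosity,
                                      None if pd.isna(a) else float(a),
                                      None if pd.isna(b) else float(b),
                                      None, NOT_EXPRESSED)
                )
                continue
            fold = discordance_fold(float(a), float(b))
            records.append(
                DiscordanceRecord(mirna, pair_id, zygosity, float(a), float(b),
                                  fold, classify_discordance(fold, thresholds))
            )
    return records


def bin_counts(records: list[DiscordanceRecord]) -> pd.DataFrame:
    """Counts per (zygosity, bin) over detected records only.

    Not-expressed records are excluded so the counts describe the assays that
    actually carried signal.
    """
    rows = [(r.zygosity, r.bin) for r in records if r.bin != NOT_EXPRESSED]
    if not rows:
        return pd.DataFrame(0, index=pd.Index([], name="zygosity"), columns=[LOW, MODERATE, HIGH])
    df = pd.DataFrame(rows, columns=["zygosity", "bin"])
    counts = df.value_counts(["zygosity", "bin"]).unstack(fill_value=0)
    for b in (LOW, MODERATE, HIGH):
        if b not in counts.columns:
            counts[b] = 0
    return counts[[LOW, MODERATE, HIGH]]


def zygosity_composite_folds(
    records: list[DiscordanceRecord],
    zygosity: str,
    thresholds: BinThresholds = BinThresholds(),
) -> dict[str, DiscordanceRecord]:
    """Collapse a zygosity's pairs to one composite record per miRNA.

    Folds are multiplicative, so the per-pair folds are pooled by their
    geometric mean (equivalently the mean |ΔΔCt|).  A miRNA flagged in every
    pair stays not_expressed; flagged pairs otherwise drop out of the mean.
    With a single pair this is the identity.
    """
    by_mirna: dict[str, list[DiscordanceRecord]] = {}
    for r in records:
        if r.zygosity == zygosity:
            by_mirna.setdefault(r.mirna, []).append(r)
    out: dict[str, DiscordanceRecord] = {}
    for mirna, recs in by_mirna.items():
        folds = [r.fold for r in recs if r.fold is not None]
        if not folds:
            out[mirna] = DiscordanceRecord(mirna, "pooled", zygosity, None, None, None, NOT_EXPRESSED)
            continue
        log_mean = sum(math.log2(f) for f in folds) / len(folds)
        fold = 2.0 ** log_mean
        out[mirna] = DiscordanceRecord(
            mirna, "pooled", zygosity, None, None, fold, classify_discordance(fold, thresholds)
        )
    return out


def assign_group(frat: DiscordanceRecord, ident: DiscordanceRecord) -> GroupAssignment:
    """Classify one miRNA from its fraternal and identical discordance.

    Ties between two high folds go to B (the "high in both" default); C is
    the refinement for strictly larger fraternal discordance.
    """
    if frat.mirna != ident.mirna:
        raise ValueError(f"records refer to different miRNAs: {frat.mirna!r} vs {ident.mirna!r}")
    if frat.bin == NOT_EXPRESSED or ident.bin == NOT_EXPRESSED:
        return GroupAssignment(frat.mirna, "none", frat.fold, ident.fold, not_expressed=True)
    group = "none"
    if frat.bin == HIGH and ident.bin == LOW:
        group = "A"
    elif frat.bin == HIGH and ident.bin == HIGH:
        group = "C" if frat.fold > ident.fold else "B"
    elif ident.bin == HIGH and frat.bin != HIGH:
        group = "D"
    return GroupAssignment(frat.mirna, group, frat.fold, ident.fold)


def assign_groups(
    records: list[DiscordanceRecord],
    thresholds: BinThresholds = BinThresholds(),
) -> list[GroupAssignment]:
    """Composite per-zygosity folds, then the A–D rule for every miRNA."""
    frat = zygosity_composite_folds(records, DZ, thresholds)
    ident = zygosity_composite_folds(records, MZ, thresholds)
    out = []
    for mirna in frat:
        if mirna in ident:
            out.append(assign_group(frat[mirna], ident[mirna]))
    return out


def records_frame(records: list[DiscordanceRecord]) -> pd.DataFrame:
    """Tabular view of discordance records (folds rounded to 2 decimals)."""
    return pd.DataFrame(
        {
            "miRNA": [r.mirna for r in records],
            "zygosity": [r.zygosity for r in records],
            "pair": [r.pair_id for r in records],
            "dct_a": [r.dct_a for r in records],
            "dct_b": [r.dct_b for r in records],
            "fold": [None if r.fold is None else round(r.fold, 2) for r in records],
            "bin": [r.bin for r in records],
        }
    )
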