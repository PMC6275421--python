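"""Reference-gene normalization of Ct values to relative expression (ΔCT).

Each sample's endogenous-control Cts (here typically U6-2 and SNORD48) are
summarized by their arithmetic mean on the Ct scale — Ct is already a log2
quantity, so this equals a geometric mean of the linear abundances.  Relative
expression is then

    ΔCT(miRNA, sample) = mean reference Ct(sample) − Ct(miRNA, sample)

so a larger ΔCT means higher expression (a target crossing threshold earlier
than the reference is more abundant).  No amplification-efficiency correction
is applied: the comparative-Ct convention of exact base-2 doubling per cycle
is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .ct_io import CtTable, DetectionPolicy, detect_not_expressed

__all__ = [
    "ReferenceBaseline",
    "ExpressionMatrix",
    "NormalizationError",
    "reference_baseline",
    "relative_expression",
    "write_expression_matrix",
    "read_expression_matrix",
    "DEFAULT_CONTROLS",
]

log = logging.getLogger(__name__)

DEFAULT_CONTROLS = ("U6-2", "SNORD48")

#: Serialization token for a flagged (not-expressed) cell.
NOT_EXPRESSED_MARKER = "NE"


class NormalizationError(ValueError):
    pass


@dataclass
class ReferenceBaseline:
    """Per-sample mean reference Ct and the controls that contributed."""

    mean_ct: pd.Series
    controls_used: dict[str, list[str]] = field(repr=False)


@dataclass
class ExpressionMatrix:
    """ΔCT relative expression, miRNAs in rows, samples in columns.

    Control assays are excluded from the rows.  Cells flagged not-detected
    hold NaN; ``not_expressed_assays`` lists assays flagged study-wide.
    """

    values: pd.DataFrame
    not_expressed_assays: list[str] = field(default_factory=list)

    @property
    def mirnas(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def reference_baseline(table: CtTable, control_names=DEFAULT_CONTROLS) -> ReferenceBaseline:
    """Mean of the non-missing control Cts per sample.

    A control missing in one sample simply drops out of that sample's mean
    (logged); a sample with no usable control at all is an error.
    """
    control_names = list(control_names)
    absent = [c for c in control_names if c not in table.values.index]
    if absent:
        raise NormalizationError(f"control assay(s) not in Ct table: {', '.join(absent)}")
    controls = table.values.loc[control_names]
    mean_ct = controls.mean(axis=0, skipna=True)
    used: dict[str, list[str]] = {}
    for sample in table.samples:
        usable = [c for c in control_names if pd.notna(controls.at[c, sample])]
        if not usable:
            raise NormalizationError(f"sample {sample!r} has no usable control Ct")
        if len(usable) < len(control_names):
            log.warning(
                "sample %s: baseline from %d of %d controls (%s)",
                sample, len(usable), len(control_names), ", ".join(usable),
            )
        used[sample] = usable
    return ReferenceBaseline(mean_ct=mean_ct, controls_used=used)


def relative_expression(
    table: CtTable,
    baseline: ReferenceBaseline,
    control_names=DEFAULT_CONTROLS,
    policy: DetectionPolicy = DetectionPolicy(),
) -> ExpressionMatrix:
    """ΔCT = baseline − Ct for every target assay, with detection flags.

    Cells undetermined or beyond the detection limit propagate as NaN;
    assays non-detected in every sample are additionally listed study-wide.
    """
    not_covered = [s for s in table.samples if s not in baseline.mean_ct.index]
    if not_covered:
        raise NormalizationError(f"baseline does not cover sample(s): {', '.join(not_covered)}")
    assay_flags, cell_flags = detect_not_expressed(table, policy)
    targets = [a for a in table.assays if a not in set(control_names)]
    dct = baseline.mean_ct - table.values.loc[targets]
    dct = dct.where(~cell_flags.loc[targets])
    flagged = [a for a in targets if assay_flags[a]]
    return ExpressionMatrix(values=dct, not_expressed_assays=flagged)


def write_expression_matrix(expr: ExpressionMatrix, path, dialect: str = "comma") -> None:
    sep = "," if dialect in ("comma", ",") else "\t"
    out = expr.values.map(lambda v: NOT_EXPRESSED_MARKER if pd.isna(v) else repr(float(v)))
    out.index.name = "miRNA"
    out.to_csv(path, sep=sep)


def read_expression_matrix(path, dialect: str = "comma") -> ExpressionMatrix:
    sep = "," if dialect in ("comma", ",") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    values = raw.map(lambda t: float("nan") if t.strip() == NOT_EXPRESSED_MARKER else float(t))
    flagged = [a for a in values.index if values.loc[a].isna().all()]
    return ExpressionMatrix(values=values, not_expressed_assays=flagged)
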