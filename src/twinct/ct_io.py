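"""Reading, writing and validation of raw Ct tables and twin sample sheets.

A Ct table is a delimited text file whose first column holds assay names
(target miRNAs plus endogenous controls) and whose header row holds sample
IDs; each cell is a raw cycle-threshold value or an "undetermined" marker.
A sample sheet maps each sample to a twin pair, a member slot (A/B) and a
zygosity.  Detection flagging operationalizes "not expressed": an assay whose
Ct never rises above the instrument's detection limit in any sample carries
no usable signal and is excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "TwinDesign",
    "DetectionPolicy",
    "CtValidationError",
    "CtParseError",
    "DesignError",
    "read_ct_table",
    "write_ct_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "detect_not_expressed",
    "MZ",
    "DZ",
]

MZ = "monozygotic"
DZ = "dizygotic"

#: Accepted spellings per canonical zygosity.
_ZYGOSITY_TOKENS = {
    "monozygotic": MZ,
    "identical": MZ,
    "mz": MZ,
    "dizygotic": DZ,
    "fraternal": DZ,
    "dz": DZ,
}

DEFAULT_MISSING_MARKERS = frozenset({"Undetermined", "NA", ""})


class CtValidationError(ValueError):
    """A Ct table violates a structural invariant (duplicate names, bad value)."""


class CtParseError(ValueError):
    """A cell could not be parsed as a cycle value or known missing marker."""


class DesignError(ValueError):
    """A twin sample sheet violates the paired design."""


@dataclass(frozen=True)
class DetectionPolicy:
    """Detection limit and the cell tokens treated as undetermined.

    ``max_ct`` is the last cycle at which amplification counts as detection;
    40 cycles is the run length on the common real-time platforms, so a Ct
    that never crosses threshold within the run is reported undetermined.
    """

    max_ct: float = 40.0
    missing_markers: frozenset[str] = DEFAULT_MISSING_MARKERS

    def __post_init__(self) -> None:
        if not (0.0 < self.max_ct <= 60.0):
            raise ValueError(f"max_ct must lie in (0, 60], got {self.max_ct}")


@dataclass
class CtTable:
    """Raw Ct cycle values, assays in rows and samples in columns.

    ``values`` is a float DataFrame; undetermined cells are NaN.  Assay and
    sample names must be unique and every finite Ct positive.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        dup_assays = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_assays):
            raise CtValidationError(f"duplicate assay name(s): {', '.join(map(str, dup_assays))}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise CtValidationError(f"duplicate sample ID(s): {', '.join(map(str, dup_samples))}")
        finite = self.values.to_numpy()[~np.isnan(self.values.to_numpy())]
        if np.any(~np.isfinite(finite)) or np.any(finite <= 0):
            raise CtValidationError("every non-missing Ct must be finite and > 0")

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where the cell was undetermined."""
        return self.values.isna()


@dataclass
class TwinDesign:
    """Pair membership and zygosity per sample.

    ``entries`` has columns sample_id, pair_id, member, zygosity with
    zygosity already canonical (monozygotic / dizygotic).  Each pair holds
    exactly two samples, one member A and one member B.
    """

    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["sample_id", "pair_id", "member", "zygosity"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise DesignError(f"sample sheet lacks column(s): {', '.join(missing)}")
        self.entries = self.entries[required].astype(str).reset_index(drop=True)
        if self.entries["sample_id"].duplicated().any():
            dup = self.entries.loc[self.entries["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DesignError(f"duplicate sample ID {dup!r} in sample sheet")
        bad_zyg = set(self.entries["zygosity"]) - {MZ, DZ}
        if bad_zyg:
            raise DesignError(f"unknown zygosity value(s): {', '.join(sorted(bad_zyg))}")
        for pair_id, grp in self.entries.groupby("pair_id"):
            if len(grp) != 2 or set(grp["member"]) != {"A", "B"}:
                raise DesignError(
                    f"pair {pair_id!r} must have exactly two samples with members A and B"
                )
            if grp["zygosity"].nunique() != 1:
                raise DesignError(f"pair {pair_id!r} has inconsistent zygosity")

    @property
    def pair_ids(self) -> list[str]:
        return list(dict.fromkeys(self.entries["pair_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries["sample_id"])

    def pairs(self, zygosity: str | None = None) -> list[tuple[str, str, str, str]]:
        """(pair_id, zygosity, sample_A, sample_B) tuples, optionally filtered."""
        out = []
        for pair_id, grp in self.entries.groupby("pair_id", sort=False):
            zyg = grp["zygosity"].iloc[0]
            if zygosity is not None and zyg != zygosity:
                continue
            by_member = grp.set_index("member")["sample_id"]
            out.append((pair_id, zyg, by_member["A"], by_member["B"]))
        return out

    def zygosity_of(self, pair_id: str) -> str:
        grp = self.entries[self.entries["pair_id"] == pair_id]
        if grp.empty:
            raise DesignError(f"unknown pair {pair_id!r}")
        return grp["zygosity"].iloc[0]

    def validate_against(self, table: CtTable) -> None:
        """Every designed sample must exist as a Ct table column."""
        absent = [s for s in self.sample_ids if s not in table.values.columns]
        if absent:
            raise DesignError(f"sample(s) not found in Ct table: {', '.join(absent)}")


def _sep(dialect: str) -> str:
    if dialect in ("comma", ","):
        return ","
    if dialect in ("tab", "\t"):
        return "\t"
    raise ValueError(f"dialect must be 'comma' or 'tab', got {dialect!r}")


def read_ct_table(
    path,
    dialect: str = "comma",
    missing_markers: frozenset[str] = DEFAULT_MISSING_MARKERS,
) -> CtTable:
    """Parse a delimited Ct table; markers become NaN, everything else cycles.

    Raises :class:`CtParseError` with the offending assay/sample coordinates
    for a cell that is neither numeric nor a known marker, and
    :class:`CtValidationError` for duplicated assay or sample names.
    """
    raw = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str, keep_default_na=False)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for assay, row in raw.iterrows():
        for sample, cell in row.items():
            token = cell.strip()
            if token in missing_markers:
                values.loc[assay, sample] = np.nan
                continue
            try:
                values.loc[assay, sample] = float(token)
            except ValueError:
                raise CtParseError(
                    f"cell ({assay!r}, {sample!r}) is neither a Ct value "
                    f"nor a missing marker: {cell!r}"
                ) from None
    return CtTable(values)


def write_ct_table(table: CtTable, path, dialect: str = "comma", marker: str = "Undetermined") -> None:
    """Write a Ct table; NaN cells serialize as ``marker``.

    Finite values round-trip exactly through ``repr``-precision formatting.
    """
    out = table.values.map(lambda v: marker if pd.isna(v) else repr(float(v)))
    out.index.name = "assay"
    out.to_csv(path, sep=_sep(dialect))


def read_sample_sheet(path, dialect: str = "comma") -> TwinDesign:
    """Parse a sample sheet, normalizing zygosity spellings.

    Accepts monozygotic/identical/MZ and dizygotic/fraternal/DZ (any case).
    """
    raw = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    if "zygosity" in raw.columns:
        canonical = []
        for tok in raw["zygosity"]:
            key = tok.strip().lower()
            if key not in _ZYGOSITY_TOKENS:
                raise DesignError(f"unknown zygosity token {tok!r}")
            canonical.append(_ZYGOSITY_TOKENS[key])
        raw = raw.assign(zygosity=canonical)
    return TwinDesign(raw)


def write_sample_sheet(design: TwinDesign, path, dialect: str = "comma") -> None:
    design.entries.to_csv(path, sep=_sep(dialect), index=False)


def detect_not_expressed(
    table: CtTable, policy: DetectionPolicy = DetectionPolicy()
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag non-detected cells and assays.

    A cell is flagged when its Ct is missing or above ``policy.max_ct``; an
    assay is flagged study-wide (not expressed) when every one of its cells
    is flagged.  Returns ``(assay_flags, cell_flags)``.
    """
    cell_flags = table.values.isna() | (table.values > policy.max_ct)
    assay_flags = cell_flags.all(axis=1)
    return assay_flags, cell_flags
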