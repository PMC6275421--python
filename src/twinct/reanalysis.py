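"""Desk-scale reanalysis of the published twin panel through the pipeline.

The study's printed per-twin ΔCT values are inverted to raw Ct tables
(controls at the reference level, target Ct = reference − ΔCT), pushed
through normalization and discordance exactly as any user data would be, and
the resulting folds, bins and groups are compared against the published
numbers.  A parameter-recovery routine runs the simulator → pipeline →
Falconer chain repeatedly to measure estimator bias against the known truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import reference_data as ref
from .ct_io import DZ, MZ, CtTable, TwinDesign
from .discordance import (BinThresholds, DiscordanceRecord, assign_group,
                          classify_discordance, pair_discordance)
from .normalization import reference_baseline, relative_expression
from .synthetic_data import SimulationConfig, simulate_twin_ct
from .twin_stats import HeritabilityEstimate, falconer_h2, zygosity_correlation

__all__ = [
    "reconstruct_study",
    "recomputed_pair_folds",
    "published_bin_classification",
    "group_regression",
    "published_heritability",
    "recover_h2",
    "REFERENCE_CT",
]

#: Reference (control) Ct level used when inverting printed ΔCT to raw Ct.
#: Any value works — ΔCT is shift-invariant — this one keeps Cts in the
#: instrument's usual range.
REFERENCE_CT = 32.0

_DCT = {DZ: ref.FRATERNAL_DCT_PAIRS, MZ: ref.IDENTICAL_DCT_PAIRS}
_PAIR_ID = {DZ: "F1", MZ: "I1"}


def reconstruct_study(zygosity: str) -> tuple[CtTable, TwinDesign]:
    """Raw Ct table + design for one zygosity's printed co-twin ΔCT values."""
    dct = _DCT[zygosity]
    pair = _PAIR_ID[zygosity]
    samples = [f"{pair}A", f"{pair}B"]
    rows = {"U6-2": [REFERENCE_CT, REFERENCE_CT], "SNORD48": [REFERENCE_CT, REFERENCE_CT]}
    for mirna, (a, b) in dct.items():
        rows[mirna] = [REFERENCE_CT - a, REFERENCE_CT - b]
    table = CtTable(pd.DataFrame(rows, index=samples).T)
    design = TwinDesign(pd.DataFrame(
        {"sample_id": samples, "pair_id": [pair, pair], "member": ["A", "B"],
         "zygosity": [zygosity, zygosity]}
    ))
    return table, design


def recomputed_pair_folds(zygosity: str) -> dict[str, DiscordanceRecord]:
    """Printed ΔCT pairs → Ct → ΔCT → fold, via the full pipeline."""
    table, design = reconstruct_study(zygosity)
    baseline = reference_baseline(table)
    expr = relative_expression(table, baseline)
    return {r.mirna: r for r in pair_discordance(expr, design)}


def published_bin_classification(thresholds: BinThresholds = BinThresholds()) -> pd.DataFrame:
    """Classify every printed discordance fold; one row per (zygosity, miRNA)."""
    rows = []
    for zygosity, folds in ((DZ, ref.FRATERNAL_FOLDS), (MZ, ref.IDENTICAL_FOLDS)):
        for mirna, fold in folds.items():
            rows.append((zygosity, mirna, fold, classify_discordance(fold, thresholds)))
    return pd.DataFrame(rows, columns=["zygosity", "miRNA", "fold", "bin"])


def _record(mirna: str, zygosity: str, fold: float,
            thresholds: BinThresholds) -> DiscordanceRecord:
    return DiscordanceRecord(mirna, _PAIR_ID[zygosity], zygosity, None, None,
                             fold, classify_discordance(fold, thresholds))


def group_regression(thresholds: BinThresholds = BinThresholds()) -> pd.DataFrame:
    """A–D rule on the printed folds vs the published group of each miRNA.

    The published discordance tables print only the high and low lists, so
    the two group-D members absent from the fraternal lists enter with the
    nominal moderate fold from :data:`reference_data.FRATERNAL_MODERATE_ONLY`
    (the rule only needs their not-high bin).
    """
    frat_folds = {**ref.FRATERNAL_FOLDS, **ref.FRATERNAL_MODERATE_ONLY}
    rows = []
    for mirna, published_group in ref.GROUP_MEMBERSHIP.items():
        frat = _record(mirna, DZ, frat_folds[mirna], thresholds)
        ident = _record(mirna, MZ, ref.IDENTICAL_FOLDS[mirna], thresholds)
        assigned = assign_group(frat, ident).group
        rows.append((mirna, frat.fold, ident.fold, assigned, published_group,
                     assigned == published_group))
    return pd.DataFrame(rows, columns=[
        "miRNA", "fraternal_fold", "identical_fold", "assigned", "published", "agree",
    ])


def published_heritability() -> HeritabilityEstimate:
    """Falconer partition from the published co-twin correlations."""
    return falconer_h2(ref.PUBLISHED_R_MZ, ref.PUBLISHED_R_DZ)


#: Variance components of the recovery benchmark: σ_b²=1, σ_g²=2, σ_c²=0.5,
#: σ_e²=1.5, hence h² = 2/5 = 0.4.
RECOVERY_CONFIG = SimulationConfig(
    n_mirnas=5000, n_pairs_mz=1, n_pairs_dz=1,
    sigma_b=1.0, sigma_g=float(np.sqrt(2.0)),
    sigma_c=float(np.sqrt(0.5)), sigma_e=float(np.sqrt(1.5)),
    n_not_expressed=0, seed=0,
)


def recover_h2(config: SimulationConfig, seeds) -> pd.DataFrame:
    """Simulate → normalize → correlate → Falconer, once per seed.

    Returns per-seed r_mz, r_dz and h2_raw; the mean of h2_raw against
    ``config.h2_expected`` measures estimator bias.
    """
    rows = []
    for seed in seeds:
        study = simulate_twin_ct(dataclasses.replace(config, seed=int(seed)))
        baseline = reference_baseline(study.table, config.control_names)
        expr = relative_expression(study.table, baseline, config.control_names)
        r_mz = zygosity_correlation(expr, study.design, MZ).r
        r_dz = zygosity_correlation(expr, study.design, DZ).r
        rows.append((int(seed), r_mz, r_dz, falconer_h2(r_mz, r_dz).h2_raw))
    return pd.DataFrame(rows, columns=["seed", "r_mz", "r_dz", "h2_raw"])
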