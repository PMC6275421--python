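"""End-to-end orchestration: Ct table → ΔCT → discordance → heritability.

`run_pipeline` composes the library stages on either a real Ct table plus
sample sheet or a freshly simulated study, and writes a report bundle:

* ``expression_matrix.csv`` — ΔCT per (miRNA, sample), flags as "NE"
* ``discordance_dizygotic.csv`` / ``discordance_monozygotic.csv`` — per-pair
  folds sorted descending
* ``bin_counts.csv`` — low/moderate/high counts per zygosity
* ``groups.csv`` — A–D assignment per miRNA
* ``heritability.json`` — co-twin correlations and the Falconer partition
* ``run_log.txt`` — config echo and seed

`summarize` renders a bundle for the terminal without recomputing anything.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import discordance as disc
from .ct_io import (DZ, MZ, CtTable, DetectionPolicy, TwinDesign,
                    read_ct_table, read_sample_sheet, write_ct_table,
                    write_sample_sheet)
from .discordance import BinThresholds
from .normalization import (DEFAULT_CONTROLS, reference_baseline,
                            relative_expression, write_expression_matrix)
from .synthetic_data import SimulationConfig, simulate_twin_ct
from .twin_stats import CorrelationError, falconer_h2, zygosity_correlation

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize"]

log = logging.getLogger(__name__)

_ZYG_FILE = {DZ: "discordance_dizygotic.csv", MZ: "discordance_monozygotic.csv"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Exactly one of (``ct_path`` + ``samples_path``) or ``simulation`` must be
    given.
    """

    out_dir: str | Path
    ct_path: str | Path | None = None
    samples_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    control_names: tuple[str, ...] = DEFAULT_CONTROLS
    thresholds: BinThresholds = dataclasses.field(default_factory=BinThresholds)
    policy: DetectionPolicy = dataclasses.field(default_factory=DetectionPolicy)
    dialect: str = "comma"
    seed: int | None = None

    def __post_init__(self) -> None:
        real = self.ct_path is not None and self.samples_path is not None
        if real == (self.simulation is not None):
            raise ValueError("select exactly one input: ct+samples paths, or a simulation config")


def _load_inputs(cfg: RunConfig) -> tuple[CtTable, TwinDesign]:
    if cfg.simulation is not None:
        sim_cfg = cfg.simulation
        if cfg.seed is not None:
            sim_cfg = dataclasses.replace(sim_cfg, seed=cfg.seed)
        study = simulate_twin_ct(sim_cfg)
        return study.table, study.design
    ct_path = Path(cfg.ct_path)
    samples_path = Path(cfg.samples_path)
    for p in (ct_path, samples_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    table = read_ct_table(ct_path, dialect=cfg.dialect, missing_markers=cfg.policy.missing_markers)
    design = read_sample_sheet(samples_path, dialect=cfg.dialect)
    design.validate_against(table)
    return table, design


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and write the report bundle; returns the bundle dir.

    Any stage failure is re-raised as :class:`PipelineError` naming the
    stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        table, design = _load_inputs(cfg)

        stage = "normalization"
        baseline = reference_baseline(table, cfg.control_names)
        expr = relative_expression(table, baseline, cfg.control_names, cfg.policy)
        write_expression_matrix(expr, out / "expression_matrix.csv", dialect=cfg.dialect)

        stage = "discordance"
        records = disc.pair_discordance(expr, design, cfg.thresholds)
        frame = disc.records_frame(records)
        for zyg, fname in _ZYG_FILE.items():
            sub = frame[frame["zygosity"] == zyg].sort_values(
                "fold", ascending=False, na_position="last"
            )
            sub.to_csv(out / fname, index=False)
        disc.bin_counts(records).to_csv(out / "bin_counts.csv")
        groups = disc.assign_groups(records, cfg.thresholds)
        pd.DataFrame(
            {
                "miRNA": [g.mirna for g in groups],
                "fraternal_fold": [None if g.fraternal_fold is None else round(g.fraternal_fold, 2)
                                   for g in groups],
                "identical_fold": [None if g.identical_fold is None else round(g.identical_fold, 2)
                                   for g in groups],
                "group": [g.group for g in groups],
            }
        ).to_csv(out / "groups.csv", index=False)

        stage = "heritability"
        heritability: dict[str, object]
        try:
            corr_mz = zygosity_correlation(expr, design, MZ)
            corr_dz = zygosity_correlation(expr, design, DZ)
            est = falconer_h2(corr_mz.r, corr_dz.r)
            heritability = {
                "r_mz": corr_mz.r, "r_dz": corr_dz.r,
                "n_mz": corr_mz.n, "n_dz": corr_dz.n,
                "p_mz": corr_mz.p, "p_dz": corr_dz.p,
                "h2_raw": est.h2_raw, "h2_clamped": est.h2_clamped,
                "environment_share": est.environment_share,
            }
        except CorrelationError as exc:
            # One-zygosity designs still get the discordance report.
            heritability = {"error": str(exc)}
        with open(out / "heritability.json", "w") as fh:
            json.dump(heritability, fh, indent=2)

        stage = "log"
        with open(out / "run_log.txt", "w") as fh:
            fh.write("twinct pipeline run\n")
            fh.write(f"seed: {cfg.seed}\n")
            fh.write(f"controls: {', '.join(cfg.control_names)}\n")
            fh.write(f"thresholds: low<{cfg.thresholds.low_below} high>{cfg.thresholds.high_above}\n")
            fh.write(f"detection max_ct: {cfg.policy.max_ct}\n")
            if cfg.simulation is not None:
                fh.write(f"simulation: {cfg.simulation}\n")
            else:
                fh.write(f"ct table: {cfg.ct_path}\nsample sheet: {cfg.samples_path}\n")
        if cfg.simulation is not None:
            # Persist the generated inputs so the run is self-contained.
            write_ct_table(table, out / "simulated_ct.csv", dialect=cfg.dialect)
            write_sample_sheet(design, out / "simulated_samples.csv", dialect=cfg.dialect)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return out


def summarize(bundle_dir: str | Path) -> str:
    """Human-readable summary of a report bundle; no recomputation."""
    bundle = Path(bundle_dir)
    required = ["bin_counts.csv", "groups.csv", "heritability.json"]
    missing = [f for f in required if not (bundle / f).exists()]
    if missing:
        raise PipelineError(f"malformed bundle, missing: {', '.join(missing)}")
    lines = [f"Report bundle: {bundle}"]

    counts = pd.read_csv(bundle / "bin_counts.csv", index_col=0)
    lines.append("Discordance bin counts (detected miRNAs):")
    for zyg, row in counts.iterrows():
        parts = ", ".join(f"{b}={int(row[b])}" for b in counts.columns)
        lines.append(f"  {zyg}: {parts}")

    groups = pd.read_csv(bundle / "groups.csv")
    classified = groups[groups["group"].isin(list("ABCD"))]
    if classified.empty:
        lines.append("no miRNAs classified")
    else:
        lines.append("Genetics-vs-environment groups:")
        for grp, sub in classified.groupby("group"):
            lines.append(f"  {grp}: {', '.join(sub['miRNA'])}")

    with open(bundle / "heritability.json") as fh:
        h = json.load(fh)
    if "error" in h:
        lines.append(f"heritability unavailable: {h['error']}")
    else:
        lines.append(
            f"co-twin correlation: r_mz={h['r_mz']:.2f} (n={h['n_mz']}, p={h['p_mz']:.4g}), "
            f"r_dz={h['r_dz']:.2f} (n={h['n_dz']}, p={h['p_dz']:.4g})"
        )
        pct_h2 = round(100 * h["h2_clamped"])
        pct_env = round(100 * h["environment_share"])
        lines.append(f"H² = {pct_h2}%")
        lines.append(f"genetics {pct_h2}% / environment {pct_env}%")
    return "\n".join(lines)
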