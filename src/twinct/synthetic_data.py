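"""Variance-component simulator for twin qRT-PCR panels with known truth.

Each miRNA's true relative expression in a twin decomposes as

    ΔCT = μ + b_m + G + C + E

with ``b_m`` a per-miRNA baseline shared by everyone (between-assay spread of
the panel), ``G`` an additive-genetic deviation correlated ρ = 1 within
monozygotic and ρ = 0.5 within dizygotic pairs, ``C`` a shared-environment
deviation common to both co-twins, and ``E`` a unique-environment deviation
per twin.  Emitted Cts invert the normalization (target Ct = reference Ct −
ΔCT, controls emitted exactly at the reference level) and censor at the
detection limit, so the simulator is a drop-in data source for the reader.

Closed forms used as oracles downstream:

    h²            = σ_g² / (σ_b² + σ_g² + σ_c² + σ_e²)
    r(zygosity)   = (σ_b² + ρ·σ_g² + σ_c²) / (σ_b² + σ_g² + σ_c² + σ_e²)

so 2(r_MZ − r_DZ) recovers h² exactly in expectation.  Note the co-twin
correlation is taken *across the miRNA panel* (one expression vector per
twin), mirroring how small twin panels are analyzed, and therefore the
between-assay variance σ_b² inflates both correlations equally — Falconer's
difference cancels it, which is itself a tested property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .ct_io import DZ, MZ, CtTable, TwinDesign

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_twin_ct", "expected_correlation"]

#: Additive-genetic within-pair correlation by zygosity.
KINSHIP = {MZ: 1.0, DZ: 0.5}


@dataclass(frozen=True)
class SimulationConfig:
    """Panel geometry, variance components and emission parameters.

    Defaults emulate a small cord-blood twin panel: 44 assays of which one
    falls below the detection limit, two pairs per zygosity, a grand-mean
    ΔCT of 10 with a between-assay SD of 2 log2 units (spanning roughly
    ΔCT 6–14, the range such panels print), genetic/shared/unique SDs of
    1.5/0.5/1.0, controls at Ct 32 and a 40-cycle detection limit.
    """

    n_mirnas: int = 44
    n_pairs_mz: int = 2
    n_pairs_dz: int = 2
    mu: float = 10.0
    sigma_b: float = 2.0
    sigma_g: float = 1.5
    sigma_c: float = 0.5
    sigma_e: float = 1.0
    n_not_expressed: int = 1
    ref_ct: float = 32.0
    detection_max_ct: float = 40.0
    seed: int = 0
    control_names: tuple[str, ...] = ("U6-2", "SNORD48")

    def __post_init__(self) -> None:
        if self.n_mirnas < 4:
            raise ValueError("n_mirnas must be >= 4")
        for name in ("sigma_b", "sigma_g", "sigma_c", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.n_not_expressed <= self.n_mirnas:
            raise ValueError("n_not_expressed must lie in [0, n_mirnas]")

    @property
    def total_variance(self) -> float:
        return self.sigma_b**2 + self.sigma_g**2 + self.sigma_c**2 + self.sigma_e**2

    @property
    def h2_expected(self) -> float:
        if self.total_variance == 0:
            return 0.0  # degenerate: no variance to partition
        return self.sigma_g**2 / self.total_variance

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a JSON superset
        if "control_names" in data:
            data["control_names"] = tuple(data["control_names"])
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        data["control_names"] = list(data["control_names"])
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


@dataclass
class SimulatedStudy:
    table: CtTable
    design: TwinDesign
    true_dct: pd.DataFrame = field(repr=False)
    h2_expected: float = 0.0
    config: SimulationConfig | None = None


def expected_correlation(config: SimulationConfig, zygosity: str) -> float:
    """Closed-form co-twin correlation across the panel for one zygosity."""
    total = config.total_variance
    if total <= 0:
        raise ValueError("total variance is zero; correlation undefined")
    rho = KINSHIP[zygosity]
    return (config.sigma_b**2 + rho * config.sigma_g**2 + config.sigma_c**2) / total


def simulate_twin_ct(config: SimulationConfig) -> SimulatedStudy:
    """Draw a full twin study: Ct table, sample sheet and true ΔCT matrix.

    Twin A's genetic score is G; twin B's is ρG + √(1−ρ²)·G′ with G′ an
    independent draw, giving marginal SD σ_g and within-pair correlation ρ.
    The first ``n_not_expressed`` assays are emitted beyond the detection
    limit in every sample (their Ct exceeds ``detection_max_ct``), emulating
    an assay absent from the tissue.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = [f"miR-sim-{i + 1:03d}" for i in range(config.n_mirnas)]
    expressed = np.ones(config.n_mirnas, dtype=bool)
    expressed[: config.n_not_expressed] = False

    entries = []
    zygosities: list[tuple[str, str]] = []
    for i in range(config.n_pairs_mz):
        zygosities.append((f"MZ{i + 1}", MZ))
    for i in range(config.n_pairs_dz):
        zygosities.append((f"DZ{i + 1}", DZ))
    for pair_id, zyg in zygosities:
        for member in ("A", "B"):
            entries.append((f"{pair_id}{member}", pair_id, member, zyg))
    design = TwinDesign(pd.DataFrame(entries, columns=["sample_id", "pair_id", "member", "zygosity"]))

    baseline = rng.normal(0.0, config.sigma_b, size=config.n_mirnas)
    samples = [e[0] for e in entries]
    true_dct = pd.DataFrame(index=mirnas, columns=samples, dtype=float)

    for pair_id, zyg in zygosities:
        rho = KINSHIP[zyg]
        g = rng.normal(0.0, 1.0, size=config.n_mirnas)
        g_prime = rng.normal(0.0, 1.0, size=config.n_mirnas)
        g_a = config.sigma_g * g
        g_b = config.sigma_g * (rho * g + np.sqrt(1.0 - rho**2) * g_prime)
        c = rng.normal(0.0, config.sigma_c, size=config.n_mirnas)
        e_a = rng.normal(0.0, config.sigma_e, size=config.n_mirnas)
        e_b = rng.normal(0.0, config.sigma_e, size=config.n_mirnas)
        true_dct[f"{pair_id}A"] = config.mu + baseline + g_a + c + e_a
        true_dct[f"{pair_id}B"] = config.mu + baseline + g_b + c + e_b

    # Undetected assays sit past the run length regardless of their draw.
    ct = config.ref_ct - true_dct
    censor_floor = config.detection_max_ct + 1.0
    ct.loc[~expressed] = np.maximum(ct.loc[~expressed], censor_floor)
    ct = ct.where(ct <= config.detection_max_ct)

    controls = pd.DataFrame(config.ref_ct, index=list(config.control_names), columns=samples)
    table = CtTable(pd.concat([controls, ct]))
    return SimulatedStudy(
        table=table,
        design=design,
        true_dct=true_dct,
        h2_expected=config.h2_expected,
        config=config,
    )
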