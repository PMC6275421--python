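"""Co-twin correlation and the Falconer heritability partition.

The classical twin design compares the resemblance of monozygotic co-twins
(who share all segregating genetic variation) with that of dizygotic co-twins
(who share half of it on average).  Here resemblance is the Pearson
correlation of the two co-twins' ΔCT profiles across the miRNA panel, and the
broad-sense heritability is Falconer's estimate

    H² = 2 (r_MZ − r_DZ)

with the complementary share 1 − H² attributed to the environment.  When a
zygosity contributes several pairs, per-pair correlations are pooled on the
Fisher z scale weighted by n − 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ct_io import TwinDesign
from .normalization import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "HeritabilityEstimate",
    "CorrelationError",
    "pearson_r",
    "correlation_pvalue",
    "zygosity_correlation",
    "falconer_h2",
]


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    zygosity: str
    r: float
    n: int
    p: float
    per_pair: dict[str, tuple[float, int]] = field(default_factory=dict)


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Falconer partition of phenotypic variance.

    ``h2_raw`` is exactly 2(r_mz − r_dz) and may leave [0, 1] by sampling
    noise; shares use the clamped value so genetics + environment = 1.
    """

    r_mz: float
    r_dz: float
    h2_raw: float
    h2_clamped: float
    environment_share: float
    formula: str = "H2 = 2 * (r_mz - r_dz)"


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n ≥ 3).

    Entries where either side is NaN are dropped pairwise first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CorrelationError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise CorrelationError(f"need >= 3 complete observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        side = "first" if np.ptp(x) == 0 else "second"
        raise CorrelationError(f"{side} vector is constant; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for H0: ρ = 0 via t = r·√(n−2)/√(1−r²) on n−2 df."""
    if n < 3:
        raise CorrelationError("p-value needs n >= 3")
    if abs(r) >= 1.0:
        return 0.0  # exact fit: the t statistic diverges
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def zygosity_correlation(
    expr: ExpressionMatrix, design: TwinDesign, zygosity: str
) -> CorrelationResult:
    """Co-twin correlation over miRNAs for one zygosity.

    Per pair, r between member A's and member B's ΔCT vectors with
    pairwise-complete deletion of flagged miRNAs.  Several pairs pool by
    Fisher z weighted by n − 3; the pooled p then refers z̄·√Σ(n−3) to a
    standard normal, a single pair keeps the exact t-test.
    """
    pairs = design.pairs(zygosity)
    if not pairs:
        raise CorrelationError(f"no pairs of zygosity {zygosity!r}")
    per_pair: dict[str, tuple[float, int]] = {}
    for pair_id, _, sample_a, sample_b in pairs:
        a = expr.values[sample_a].to_numpy(dtype=float)
        b = expr.values[sample_b].to_numpy(dtype=float)
        keep = ~(np.isnan(a) | np.isnan(b))
        if keep.sum() < 3:
            raise CorrelationError(f"pair {pair_id!r} has < 3 detected miRNAs")
        per_pair[pair_id] = (pearson_r(a[keep], b[keep]), int(keep.sum()))
    n_total = sum(n for _, n in per_pair.values())
    if len(per_pair) == 1:
        ((r, n),) = per_pair.values()
        return CorrelationResult(zygosity, r, n, correlation_pvalue(r, n), per_pair)
    weights = np.array([n - 3 for _, n in per_pair.values()], dtype=float)
    zs = np.array([math.atanh(min(max(r, -1 + 1e-15), 1 - 1e-15)) for r, _ in per_pair.values()])
    z_bar = float(np.average(zs, weights=weights))
    r_pooled = math.tanh(z_bar)
    z_stat = z_bar * math.sqrt(weights.sum())
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return CorrelationResult(zygosity, r_pooled, n_total, p, per_pair)


def falconer_h2(r_mz: float, r_dz: float) -> HeritabilityEstimate:
    """Falconer's H² = 2(r_mz − r_dz), clamped to [0, 1] for the shares."""
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1], got {r}")
    h2_raw = 2.0 * (r_mz - r_dz)
    h2 = min(1.0, max(0.0, h2_raw))
    return HeritabilityEstimate(r_mz, r_dz, h2_raw, h2, 1.0 - h2)
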