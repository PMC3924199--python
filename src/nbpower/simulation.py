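"""Monte-Carlo validation of the FDR-controlled design.

Each replicate draws an m x 2n count matrix of independent NB genes —
the first m1 genes truly differentially expressed (treatment mean
w * rho * mu0, so w emulates a depth imbalance; w = 1 recovers the
standard setting), the rest null — then analyses it the way a real
experiment would: estimate normalization factors and a pooled common
dispersion from the simulated data, compute the exact-test p-value of
every gene from its group pseudo-sums, control FDR with Storey q-values
at level f, and count true and false rejections.  The mean true-rejection
count over replicates, r1_hat, is the achieved analogue of the design
target r1.

Replicates are seeded independently through numpy's SeedSequence keyed by
(seed, replicate_index), so results are bitwise reproducible and each
replicate can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exact_test import conditional_pvalue_table
from .pilot_estimation import (
    CONTROL,
    TREATMENT,
    CountMatrix,
    estimate_common_dispersion,
    norm_factors,
    ratio_w,
)

__all__ = [
    "SimulationDesign",
    "SimulationResult",
    "simulate_counts",
    "qvalues",
    "run_validation",
]


@dataclass(frozen=True)
class SimulationDesign:
    m: int
    m1: int
    n: int
    mu0: float
    rho: float
    phi: float
    w: float = 1.0
    f: float = 0.05
    reps: int = 1
    seed: int = 0
    norm_method: str = "libsize"  # "tmm", "libsize" or "none"

    def __post_init__(self) -> None:
        if not (0 <= self.m1 <= self.m):
            raise ValueError("need 0 <= m1 <= m")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0.0 < self.f < 1.0):
            raise ValueError("FDR level f must be in (0,1)")


@dataclass
class SimulationResult:
    r1_hat: float
    mc_se: float
    empirical_fdr: float  # NaN when no replicate rejected anything
    true_rejections: np.ndarray  # R1 per replicate
    false_rejections: np.ndarray  # R0 per replicate
    total_rejections: np.ndarray  # R per replicate
    design: SimulationDesign = field(repr=False, default=None)

    def per_replicate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.total_rejections)),
                "R": self.total_rejections,
                "R0": self.false_rejections,
                "R1": self.true_rejections,
            }
        )

    def summary(self) -> dict:
        return {
            "r1_hat": self.r1_hat,
            "mc_se": self.mc_se,
            "empirical_fdr": self.empirical_fdr,
            "reps": len(self.total_rejections),
        }


def _rng_for(seed: int, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, replicate_index]))


def _draw_nb(rng, mean: np.ndarray, phi: float, size) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mean, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean), size=size)


def simulate_counts(design: SimulationDesign, replicate_index: int = 0) -> CountMatrix:
    """One replicate matrix: m genes x 2n samples with truth in the gene ids.

    Prognostic genes (ids ``de*``, the first m1 rows) have control mean mu0
    and treatment mean w*rho*mu0; null genes (``null*``) have mean mu0 in
    both groups.  All counts independent NB with dispersion phi.
    """
    rng = _rng_for(design.seed, replicate_index)
    n, m, m1 = design.n, design.m, design.m1
    mean_ctrl = np.full((m, n), float(design.mu0))
    mean_trt = np.full((m, n), float(design.mu0))
    mean_trt[:m1] = design.w * design.rho * design.mu0
    ctrl = _draw_nb(rng, mean_ctrl, design.phi, (m, n))
    trt = _draw_nb(rng, mean_trt, design.phi, (m, n))
    genes = [f"de{i}" if i < m1 else f"null{i}" for i in range(m)]
    cols = [f"c{j}" for j in range(n)] + [f"t{j}" for j in range(n)]
    counts = pd.DataFrame(np.hstack([ctrl, trt]), index=genes, columns=cols)
    groups = pd.Series([CONTROL] * n + [TREATMENT] * n, index=cols)
    return CountMatrix(counts, groups)


def qvalues(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with fixed lambda.

    pi0_hat = #{p > lam} / (m*(1-lam)), capped at 1 and floored at 1/m (a
    zero estimate would force zero rejections by fiat);
    q_i = min over p_j >= p_i of pi0_hat * m * p_j / rank(p_j).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if not (0.0 <= lam < 1.0):
        raise ValueError("lambda must be in [0,1)")
    m = p.size
    pi0 = np.count_nonzero(p > lam) / (m * (1.0 - lam))
    pi0 = min(pi0, 1.0)
    pi0 = max(pi0, 1.0 / m)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _replicate_rejections(
    design: SimulationDesign, replicate_index: int, lam: float
) -> tuple[int, int]:
    cm = simulate_counts(design, replicate_index)
    if design.norm_method == "none":
        factors = pd.Series(1.0, index=cm.counts.columns)
        w_hat = 1.0
    else:
        factors = norm_factors(cm, method=design.norm_method)
        w_hat = ratio_w(factors, cm.groups)
    phi_hat = estimate_common_dispersion(cm, factors)

    mask0 = (cm.groups == CONTROL).to_numpy()
    y = cm.counts.to_numpy()
    s0 = y[:, mask0].sum(axis=1)
    s1 = y[:, ~mask0].sum(axis=1)
    totals = s0 + s1
    n = design.n
    pvals = np.ones(design.m)
    cache: dict[int, np.ndarray] = {}
    for i in range(design.m):
        s = int(totals[i])
        if s == 0:
            continue  # untestable gene, p = 1
        if s not in cache:
            cache[s] = conditional_pvalue_table(s, n, n, w=w_hat, phi=phi_hat)
        pvals[i] = cache[s][int(s1[i])]

    q = qvalues(pvals, lam=lam)
    rej = q <= design.f
    r1 = int(np.count_nonzero(rej[: design.m1]))
    r0 = int(np.count_nonzero(rej[design.m1:]))
    return r1, r0


def run_validation(design: SimulationDesign, lam: float = 0.5) -> SimulationResult:
    """Run the full Monte-Carlo experiment and aggregate rejection counts."""
    r1s = np.empty(design.reps, dtype=int)
    r0s = np.empty(design.reps, dtype=int)
    for rep in range(design.reps):
        r1s[rep], r0s[rep] = _replicate_rejections(design, rep, lam)
    tot = r1s + r0s
    r1_hat = float(np.mean(r1s))
    se = float(np.std(r1s, ddof=1) / np.sqrt(design.reps)) if design.reps > 1 else float("nan")
    with np.errstate(invalid="ignore"):
        fdp = np.where(tot > 0, r0s / np.maximum(tot, 1), np.nan)
    emp_fdr = float(np.nanmean(fdp)) if np.any(tot > 0) else float("nan")
    return SimulationResult(
        r1_hat=r1_hat,
        mc_se=se,
        empirical_fdr=emp_fdr,
        true_rejections=r1s,
        false_rejections=r0s,
        total_rejections=tot,
        design=design,
    )
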