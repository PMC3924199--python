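"""Design-parameter estimation from a pilot RNA-seq count matrix.

Turns a genes x samples table of raw read counts with a two-group sample
annotation into the inputs of the FDR-controlled design: per-sample
normalization factors d_ij (TMM), their geometric-mean ratio w, per-gene
control means mu0_g, fold changes rho_g, dispersions phi_g and exact-test
p-values, and a "prognostic" gene set selected by p-value.

Dispersions are per-gene maximum likelihood under NB(d_ij * gamma_i, phi)
with group means profiled out; a pooled common dispersion (maximizing the
summed per-gene log-likelihoods) is also provided, since a conservative
design only needs an upper envelope and a single-gene ML estimate is noisy
at pilot-scale replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import rankdata

from .exact_test import conditional_pvalue_table

__all__ = [
    "CountMatrix",
    "PilotEstimates",
    "read_counts",
    "read_groups",
    "filter_low_count_genes",
    "norm_factors",
    "ratio_w",
    "estimate_gene_params",
    "estimate_common_dispersion",
    "select_prognostic",
    "estimate_pilot",
]

CONTROL = "control"
TREATMENT = "treatment"

_PHI_LO, _PHI_HI = 1e-8, 100.0


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) plus a control/treatment label per sample."""

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        vals = c.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        self.groups = self.groups.reindex(c.columns)
        if self.groups.isna().any():
            missing = c.columns[self.groups.isna()].tolist()
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = set(self.groups.unique()) - {CONTROL, TREATMENT}
        if bad:
            raise ValueError(f"group labels must be control/treatment, got {bad}")
        for g in (CONTROL, TREATMENT):
            if (self.groups == g).sum() < 1:
                raise ValueError(f"no samples in group {g!r}")

    @property
    def control_samples(self) -> pd.Index:
        return self.counts.columns[self.groups == CONTROL]

    @property
    def treatment_samples(self) -> pd.Index:
        return self.counts.columns[self.groups == TREATMENT]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class PilotEstimates:
    norm_factors: pd.Series  # effective per-sample factors d_ij, geo-mean 1
    w: float
    per_gene: pd.DataFrame  # columns mu0, rho, phi, pvalue, prognostic
    common_dispersion: float

    def to_tsv(self, path) -> None:
        out = self.per_gene.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    """Gene-by-sample count table: header of sample names, first column gene ids.

    Tab-separated by default; comma-separated files are detected from the
    header line.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "," if ("," in header and "\t" not in header) else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_groups(path) -> pd.Series:
    """Two-column sample annotation (sample, group), tab- or comma-separated."""
    with open(path) as fh:
        header = fh.readline()
    sep = "," if ("," in header and "\t" not in header) else "\t"
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.iloc[0, 1].strip().lower() not in (CONTROL, TREATMENT):
        df = df.iloc[1:]  # tolerate a header row
    return pd.Series(
        df.iloc[:, 1].str.strip().str.lower().to_numpy(),
        index=df.iloc[:, 0].str.strip().to_numpy(),
    )


def filter_low_count_genes(cm: CountMatrix, min_total: int = 5) -> CountMatrix:
    """Keep genes whose total count exceeds ``min_total`` in BOTH groups."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    tot0 = cm.counts[cm.control_samples].sum(axis=1)
    tot1 = cm.counts[cm.treatment_samples].sum(axis=1)
    keep = (tot0 > min_total) & (tot1 > min_total)
    if not keep.any():
        raise ValueError("no genes left after low-count filtering")
    return CountMatrix(cm.counts.loc[keep], cm.groups)


# --- TMM normalization (trimmed mean of M-values) -------------------------

def _tmm_pair(obs, ref, lib_obs, lib_ref, logratio_trim=0.3, sum_trim=0.05,
              do_weighting=True, a_cutoff=-1e10) -> float:
    """TMM factor of one sample against the reference sample (log2 scale -> 2^f)."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))  # M values
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0  # A values
        v = (lib_obs - obs) / lib_obs / obs + (lib_ref - ref) / lib_ref / ref
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    if do_weighting:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def norm_factors(cm: CountMatrix, method: str = "tmm") -> pd.Series:
    """Effective per-sample normalization factors d_ij with geometric mean 1.

    ``method="tmm"``: TMM scaling factors (30% M-trim, 5% A-trim, precision
    weighting, reference = sample whose upper-quartile/library-size ratio is
    closest to the mean) applied to library sizes.  ``method="libsize"``:
    plain library-size factors, mostly useful for testing.
    """
    x = cm.counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        empty = cm.counts.columns[lib == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {empty}")
    if method == "libsize":
        eff = lib
    elif method == "tmm":
        f75 = np.quantile(x, 0.75, axis=0) / lib
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        tmm = np.array(
            [
                1.0 if j == ref else _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref])
                for j in range(x.shape[1])
            ]
        )
        tmm = tmm / np.exp(np.mean(np.log(tmm)))
        eff = lib * tmm
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    d = eff / np.exp(np.mean(np.log(eff)))
    return pd.Series(d, index=cm.counts.columns, name="norm_factor")


def ratio_w(factors: pd.Series, groups: pd.Series) -> float:
    """w = geometric mean of treatment factors / geometric mean of control factors."""
    groups = groups.reindex(factors.index)
    d1 = factors[groups == TREATMENT]
    d0 = factors[groups == CONTROL]
    if len(d0) == 0 or len(d1) == 0:
        raise ValueError("both groups must be nonempty")
    return float(np.exp(np.mean(np.log(d1))) / np.exp(np.mean(np.log(d0))))


# --- dispersion and per-gene parameters -----------------------------------

def _logpmf_mu(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB log pmf with elementwise means (same dispersion); Poisson at phi=0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if phi == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(mu), 0.0)
        return t - mu - gammaln(y + 1.0)
    r = 1.0 / phi
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _fitted_means(y: np.ndarray, d: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """Per-sample fitted means d_j * gamma_i with gamma_i = sum(y)/sum(d) per group."""
    y = np.asarray(y, dtype=float)
    mu = np.empty_like(y)
    for mask in (group_mask, ~group_mask):
        gamma = y[..., mask].sum(axis=-1) / d[mask].sum()
        mu[..., mask] = np.multiply.outer(gamma, d[mask])
    return mu


def _ml_phi(y: np.ndarray, mu: np.ndarray) -> float:
    """Maximize the NB log-likelihood over phi (profile means plugged in)."""
    ok = mu > 0
    y, mu = y[ok], mu[ok]
    if y.size == 0:
        return 0.0

    def negll(logphi: float) -> float:
        return -float(np.sum(_logpmf_mu(y, mu, float(np.exp(logphi)))))

    res = minimize_scalar(
        negll,
        bounds=(np.log(_PHI_LO), np.log(_PHI_HI)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    phi = float(np.exp(res.x))
    # floor at the Poisson boundary
    if phi < 10 * _PHI_LO or -float(np.sum(_logpmf_mu(y, mu, 0.0))) <= res.fun:
        return 0.0
    return phi


def estimate_common_dispersion(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    method: str = "conditional",
) -> float:
    """Pooled common dispersion phi shared by all genes.

    ``method="conditional"`` (default) maximizes the summed per-gene
    conditional log-likelihoods given each group's total count, which is
    free of the unknown group means when samples within a group share a
    distribution (the construction behind edgeR's common dispersion); the
    normalization factors are not used.  ``method="profile"`` maximizes
    the unconditional likelihood with group means profiled out by the
    moment plug-in gamma_i = sum(y)/sum(d); it honours unequal ``factors``
    but is biased low for small group sizes.
    """
    y = cm.counts.to_numpy(dtype=float)
    mask = (cm.groups == CONTROL).to_numpy()

    if method == "conditional":
        groups = [y[:, mask], y[:, ~mask]]

        def negll(logphi: float) -> float:
            r = 1.0 / float(np.exp(logphi))
            total = 0.0
            for yg in groups:
                n = yg.shape[1]
                t = yg.sum(axis=1)
                total += float(
                    np.sum(gammaln(yg + r))
                    + np.sum(gammaln(n * r) - gammaln(t + n * r))
                    - yg.size * gammaln(r)
                )
            return -total

        res = minimize_scalar(
            negll,
            bounds=(np.log(_PHI_LO), np.log(_PHI_HI)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        phi = float(np.exp(res.x))
        # boundary: conditional likelihood flat/increasing toward Poisson
        return 0.0 if phi < 10 * _PHI_LO else phi

    if method != "profile":
        raise ValueError(f"unknown dispersion method {method!r}")
    if factors is None:
        factors = norm_factors(cm, method="libsize")
    d = factors.reindex(cm.counts.columns).to_numpy(dtype=float)
    mu = _fitted_means(y, d, mask)
    yf, muf = y.ravel(), mu.ravel()
    ok = muf > 0
    yf, muf = yf[ok], muf[ok]

    def negll_prof(logphi: float) -> float:
        return -float(np.sum(_logpmf_mu(yf, muf, float(np.exp(logphi)))))

    res = minimize_scalar(
        negll_prof,
        bounds=(np.log(_PHI_LO), np.log(_PHI_HI)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    phi = float(np.exp(res.x))
    if phi < 10 * _PHI_LO or -float(np.sum(_logpmf_mu(yf, muf, 0.0))) <= res.fun:
        return 0.0
    return phi


def estimate_gene_params(
    cm: CountMatrix,
    factors: pd.Series,
    common_dispersion: float | None = None,
    method: str = "small-p",
) -> pd.DataFrame:
    """Per-gene (mu0, rho, phi, pvalue) estimates.

    mu0_g is the mean of normalized control counts; rho_g the ratio of
    normalized group means (+0.5 continuity offset to both means when
    either is zero); phi_g the per-gene ML dispersion; pvalue_g the exact
    test on the group sums using the pooled common dispersion and w.
    """
    for g, samples in ((CONTROL, cm.control_samples), (TREATMENT, cm.treatment_samples)):
        if len(samples) < 2:
            raise ValueError(f"need >= 2 samples in group {g!r} for dispersion estimation")
    d = factors.reindex(cm.counts.columns).to_numpy(dtype=float)
    y = cm.counts.to_numpy(dtype=float)
    mask0 = (cm.groups == CONTROL).to_numpy()
    norm = y / d
    mean0 = norm[:, mask0].mean(axis=1)
    mean1 = norm[:, ~mask0].mean(axis=1)
    zero = (mean0 == 0) | (mean1 == 0)
    rho = np.where(zero, (mean1 + 0.5) / (mean0 + 0.5), mean1 / np.where(mean0 == 0, 1.0, mean0))

    phis = np.empty(cm.n_genes)
    for i in range(cm.n_genes):
        mu = _fitted_means(y[i], d, mask0)
        phis[i] = _ml_phi(y[i], mu)

    if common_dispersion is None:
        common_dispersion = estimate_common_dispersion(cm, factors)
    w = ratio_w(factors, cm.groups)
    n0, n1 = int(mask0.sum()), int((~mask0).sum())
    s0 = y[:, mask0].sum(axis=1).astype(int)
    s1 = y[:, ~mask0].sum(axis=1).astype(int)
    pvals = np.empty(cm.n_genes)
    table_cache: dict[int, np.ndarray] = {}
    for i in range(cm.n_genes):
        s = int(s0[i] + s1[i])
        if s not in table_cache:
            table_cache[s] = conditional_pvalue_table(
                s, n0, n1, w=w, phi=common_dispersion, method=method
            )
        pvals[i] = table_cache[s][s1[i]]

    return pd.DataFrame(
        {"mu0": mean0, "rho": rho, "phi": phis, "pvalue": pvals},
        index=cm.counts.index,
    )


def select_prognostic(per_gene: pd.DataFrame, proportion: float) -> pd.Index:
    """The ceil(proportion*m) genes with smallest exact-test p-values.

    Ties on the p-value are broken toward larger |log2 rho|, then by gene
    identifier, so the selection is deterministic.
    """
    if not (0.0 < proportion < 1.0):
        raise ValueError("proportion must be in (0,1)")
    m = len(per_gene)
    k = int(np.ceil(proportion * m))
    # sort by id first so stable sorting leaves full ties in lexicographic order
    order = (
        per_gene.sort_index()
        .assign(_mag=lambda df: -np.abs(np.log2(df["rho"])))
        .sort_values(["pvalue", "_mag"], kind="stable")
    )
    return order.index[:k]


def estimate_pilot(
    cm: CountMatrix,
    min_total: int = 5,
    proportion: float = 0.01,
    norm_method: str = "tmm",
) -> PilotEstimates:
    """Full pilot workflow: filter, normalize, estimate, select prognostic set."""
    filtered = filter_low_count_genes(cm, min_total=min_total)
    factors = norm_factors(filtered, method=norm_method)
    common = estimate_common_dispersion(filtered, factors)
    per_gene = estimate_gene_params(filtered, factors, common_dispersion=common)
    prog = select_prognostic(per_gene, proportion)
    per_gene["prognostic"] = per_gene.index.isin(prog)
    return PilotEstimates(
        norm_factors=factors,
        w=ratio_w(factors, filtered.groups),
        per_gene=per_gene,
        common_dispersion=common,
    )
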