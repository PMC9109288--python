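"""Selection-coefficient estimation and the cost-of-pleiotropy statistic.

The per-locus selection coefficient is inferred from the change in log-odds
of the beneficial allele frequency,

    s_i = (2 / dt) * ln( q_f (1 - q_b) / (q_b (1 - q_f)) ),

the diploid codominant scaling: under genic selection with fitnesses
(1, 1 + s/2, 1 + s) the logit of the allele frequency advances by ~s/2 per
generation, so the factor 2 recovers s.

The cost of pleiotropy is the mean selective advantage that beneficial
alleles gain in a freshly mixed population where their recessive pleiotropic
side effects are masked in heterozygotes; it is reported with a positive
sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

IMMIGRANT = "immigrant"
RECIPIENT = "recipient"


@dataclass
class SelectionEstimate:
    chrom: str
    pos: int
    q_b: float
    q_f: float
    delta_t: int
    s: float
    origin_class: str = ""
    analysis_window: str = ""
    clamped: bool = False


@dataclass
class FrequencyBinSummary:
    bin_edges: np.ndarray
    bin_mean_afc: np.ndarray
    bin_counts: np.ndarray
    bin_se: np.ndarray
    correlation: float          # Spearman rho, NaN when undefined
    p_value: float              # permutation p (two-sided), NaN when undefined
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1],
            "bin_high": self.bin_edges[1:],
            "mean_afc": self.bin_mean_afc,
            "count": self.bin_counts,
            "se": self.bin_se,
        })


def estimate_s(q_b, q_f, delta_t: int, boundary_eps: float = 0.01, return_flags: bool = False):
    """Log-odds selection coefficient per generation.

    Frequencies are clamped into [boundary_eps, 1 - boundary_eps] first: the
    estimator diverges at 0/1, and Pool-Seq frequencies of 0 or 1 usually
    reflect finite depth rather than true fixation.  Works elementwise on
    arrays.  With return_flags=True also returns a boolean mask of clamped
    inputs.
    """
    if delta_t is None or delta_t < 1:
        raise ValueError("delta_t must be >= 1")
    if not 0 < boundary_eps < 0.5:
        raise ValueError("boundary_eps must lie in (0, 0.5)")
    qb = np.asarray(q_b, dtype=float)
    qf = np.asarray(q_f, dtype=float)
    clamped = (qb < boundary_eps) | (qb > 1 - boundary_eps) | \
              (qf < boundary_eps) | (qf > 1 - boundary_eps)
    qb = np.clip(qb, boundary_eps, 1 - boundary_eps)
    qf = np.clip(qf, boundary_eps, 1 - boundary_eps)
    s = (2.0 / delta_t) * (special.logit(qf) - special.logit(qb))
    if np.ndim(q_b) == 0:
        s = float(s)
        clamped = bool(clamped)
    if return_flags:
        return s, clamped
    return s


def estimate_table(
    snps: pd.DataFrame,
    q_b: np.ndarray,
    q_f: np.ndarray,
    delta_t: int,
    window: str,
    boundary_eps: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP SelectionEstimate table for one analysis window."""
    s, clamped = estimate_s(q_b, q_f, delta_t, boundary_eps, return_flags=True)
    out = snps[["chrom", "pos"]].copy()
    if "origin_class" in snps:
        out["origin_class"] = snps["origin_class"].values
    out["q_b"] = np.asarray(q_b, dtype=float)
    out["q_f"] = np.asarray(q_f, dtype=float)
    out["delta_t"] = delta_t
    out["s"] = s
    out["analysis_window"] = window
    out["clamped"] = clamped
    return out


def _bootstrap_ci(values: np.ndarray, n_boot: int, seed, alpha: float = 0.05):
    rng = np.random.default_rng(seed)
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    return float(np.quantile(means, alpha / 2)), float(np.quantile(means, 1 - alpha / 2))


def mean_afc(freq_start, freq_end, n_boot: int = 1000, seed: int = 0) -> dict:
    """Mean polarized allele-frequency change with a percentile bootstrap CI
    over SNPs.  NaN pairs are dropped."""
    start = np.asarray(freq_start, dtype=float)
    end = np.asarray(freq_end, dtype=float)
    if start.shape != end.shape:
        raise ValueError("start and end vectors must match")
    ok = ~(np.isnan(start) | np.isnan(end))
    diffs = (end - start)[ok]
    if diffs.size == 0:
        raise ValueError("empty SNP subset")
    lo, hi = _bootstrap_ci(diffs, n_boot, seed)
    return {"mean": float(diffs.mean()), "ci_low": lo, "ci_high": hi, "n": int(diffs.size)}


def control_afc(freq_110, freq_130, n_boot: int = 1000, seed: int = 0) -> dict:
    """Negative control: the same mean frequency change computed on the
    unmixed parental population over a matching wall-clock window."""
    return mean_afc(freq_110, freq_130, n_boot=n_boot, seed=seed)


def bin_by_start_frequency(
    freq_start,
    afc,
    bins=5,
    n_perm: int = 1000,
    seed: int = 0,
) -> FrequencyBinSummary:
    """Frequency-dependence of the selection response.

    Bins the per-SNP frequency change by starting frequency and reports a
    Spearman rank correlation between the two with a seeded permutation
    p-value (two-sided).  `bins` is an integer count (edges equally spaced on
    [0, 1]) or explicit edges.
    """
    start = np.asarray(freq_start, dtype=float)
    change = np.asarray(afc, dtype=float)
    ok = ~(np.isnan(start) | np.isnan(change))
    start, change = start[ok], change[ok]
    if start.size == 0:
        raise ValueError("empty SNP subset")
    edges = np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins) else np.asarray(bins, dtype=float)
    which = np.clip(np.digitize(start, edges) - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    means = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    ses = np.full(nb, np.nan)
    for b in range(nb):
        vals = change[which == b]
        counts[b] = vals.size
        if vals.size:
            means[b] = vals.mean()
            if vals.size > 1:
                ses[b] = vals.std(ddof=1) / np.sqrt(vals.size)
    rho, p = np.nan, np.nan
    if np.unique(start).size > 1 and np.unique(change).size > 1:
        rho = float(stats.spearmanr(start, change).statistic)
        rng = np.random.default_rng(seed)
        rank_s = stats.rankdata(start)
        rank_c = stats.rankdata(change)
        rank_s = (rank_s - rank_s.mean()) / rank_s.std()
        rank_c = (rank_c - rank_c.mean()) / rank_c.std()
        obs = np.abs(np.mean(rank_s * rank_c))
        hits = 0
        for _ in range(n_perm):
            hits += np.abs(np.mean(rank_s * rng.permutation(rank_c))) >= obs
        p = (1 + hits) / (n_perm + 1)
    return FrequencyBinSummary(edges, means, counts, ses, rho, float(p), int(start.size))


def cost_of_pleiotropy(
    estimates: pd.DataFrame,
    focal_origin: str = RECIPIENT,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Cost of pleiotropy as the mean selective advantage of the focal
    origin's beneficial alleles in the mixed population.

    focal_origin='recipient' (default): the cost is the negated mean s of
    the recipient population's beneficial alleles in the mixture — their
    disadvantage against the masked immigrant alleles.
    focal_origin='immigrant': the masked low-frequency class; the cost is
    its mean s directly.  Both variants use the positive-sign convention.
    """
    if focal_origin not in (IMMIGRANT, RECIPIENT):
        raise ValueError("focal_origin must be 'immigrant' or 'recipient'")
    cls = f"{focal_origin}-beneficial"
    s = estimates.loc[estimates["origin_class"] == cls, "s"].to_numpy(dtype=float)
    s = s[~np.isnan(s)]
    if s.size == 0:
        raise ValueError(f"no estimates with origin_class {cls!r}")
    sign = 1.0 if focal_origin == IMMIGRANT else -1.0
    lo, hi = _bootstrap_ci(sign * s, n_boot, seed)
    return {
        "cost": float(sign * s.mean()),
        "mean_s": float(s.mean()),
        "ci_low": lo,
        "ci_high": hi,
        "n": int(s.size),
        "focal_origin": focal_origin,
    }


def realized_vs_cost(parental_estimates: dict, mixed_costs: dict) -> pd.DataFrame:
    """Compare the realized parental selection coefficient with the estimated
    cost of pleiotropy, per mixture pair.

    parental_estimates: pair label -> mean realized s over adaptation
    (scalar or dict with key 'mean').  mixed_costs: pair label -> output of
    cost_of_pleiotropy.  Returns rows (pair, realized_s, cost, ratio).
    """
    if set(parental_estimates) != set(mixed_costs):
        raise ValueError("mismatched pair labels between parental and mixed estimates")
    rows = []
    for pair in parental_estimates:
        realized = parental_estimates[pair]
        if isinstance(realized, dict):
            realized = realized["mean"]
        cost = mixed_costs[pair]["cost"]
        ratio = cost / realized if realized != 0 else np.inf
        rows.append((pair, float(realized), float(cost), float(ratio)))
    return pd.DataFrame(rows, columns=["pair", "realized_s", "cost", "ratio"])
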