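"""Statistical core: sampling theory, enrichment ratios, parasite
population definitions and replicate-based count statistics.

Parasite populations
--------------------
P_10   naive copy number n > 10 (strict).
P_1R   P_10 and normalized amplified/naive ratio > 3 (strict): parasites
       callable from a single replicate, using the 99th-percentile ratio
       variance of replicate experiments as the implicit null band.
P_BR   one-sided Welch t across biological replicates, p < alpha and fold
       f_i > 1 (no multiple-testing correction, deliberately).
P_ER   negative-binomial exact test with TMM-normalized library sizes and
       Benjamini-Hochberg correction, q < alpha and enrichment direction.

Overdispersion diagnostics follow the exposure-scaled Pearson
goodness-of-fit statistic: with scale factors s_k = total_k / mean(totals)
and per-sequence rate lambda_i = sum_k N_ik / sum_k s_k, the statistic
X_i = sum_k (N_ik - s_k lambda_i)^2 / (s_k lambda_i) is approximately
chi-square with k-1 degrees of freedom under Poisson sampling; plotting its
order statistics against chi-square quantiles gives a QQ slope equal to the
variance inflation factor (1.25 for technical, 1.5 for biological
replicates in the runs this package models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import PeptideMultiset, ReplicateMatrix, align_matrices

__all__ = [
    "SamplingTheory",
    "normalize_abundance",
    "sampling_theory",
    "ratio_table",
    "classify_p10_p1r",
    "volcano",
    "pearson_gof",
    "qq_slope",
    "tmm_factors",
    "nb_exact_test",
    "bh_adjust",
    "build_parasite_table",
]


# --------------------------------------------------------------- sampling
@dataclass
class SamplingTheory:
    """Poisson sampling theory for reads drawn from a uniform library."""

    n_reads: int
    diversity: float
    lambda_: float

    def copy_number_probability(self, c: int) -> float:
        """P(X = c) for the per-sequence copy number X ~ Poisson(lambda)."""
        return float(sps.poisson.pmf(c, self.lambda_))

    def conditional_copy_probability(self, c: int) -> float:
        """P(X = c | X >= 1): copy-number distribution among observed
        sequences."""
        return float(
            sps.poisson.pmf(c, self.lambda_) / sps.poisson.sf(0, self.lambda_)
        )

    def expected_sequences_above(self, c: int) -> float:
        """Expected number of library sequences with copy number > c."""
        return float(self.diversity * sps.poisson.sf(c, self.lambda_))


def sampling_theory(n_reads: int, diversity: float) -> SamplingTheory:
    """Expected copy-number statistics for n_reads drawn from a uniform
    library of the given diversity (lambda = n_reads / diversity)."""
    if diversity <= 0:
        raise ValueError("diversity must be positive")
    lam = n_reads / diversity
    if not math.isfinite(lam) or lam <= 0:
        raise ValueError("lambda must be positive and finite")
    return SamplingTheory(n_reads, diversity, lam)


def normalize_abundance(ms: PeptideMultiset) -> dict[str, float]:
    """Per-peptide abundance count_i / sum(counts); sums to 1."""
    return ms.abundances()


# ------------------------------------------------------------------ ratios
def ratio_table(
    naive: PeptideMultiset, amplified: PeptideMultiset, pseudo: float = 0.5
) -> pd.DataFrame:
    """Per-sequence normalized amplified/naive abundance ratio.

    ``normalized_ratio = (amp/total_amp) / (naive/total_naive)``; the
    pseudo-count is added to both raw counts only when either is zero, so
    exact ratios are untouched and division by zero cannot occur.  Rows
    cover the union of the two multisets.
    """
    if len(naive) == 0 or len(amplified) == 0:
        raise ValueError("both multisets must be nonempty")
    tn, ta = float(naive.total_reads), float(amplified.total_reads)
    rows = []
    for pep in sorted(set(naive.counts) | set(amplified.counts)):
        n_c = naive.counts.get(pep, 0)
        a_c = amplified.counts.get(pep, 0)
        n_eff, a_eff = (n_c + pseudo, a_c + pseudo) if (n_c == 0 or a_c == 0) else (n_c, a_c)
        rows.append(
            {
                "peptide": pep,
                "naive_count": n_c,
                "amp_count": a_c,
                "naive_abundance": n_c / tn,
                "amp_abundance": a_c / ta,
                "normalized_ratio": (a_eff / ta) / (n_eff / tn),
            }
        )
    return pd.DataFrame(rows).set_index("peptide")


def classify_p10_p1r(
    table: pd.DataFrame, min_copy: int = 10, min_fold: float = 3.0
) -> pd.DataFrame:
    """Add strict-threshold membership flags to a ratio table.

    P10: naive copy number > min_copy; P1R: P10 and normalized ratio >
    min_fold (both strict inequalities).
    """
    out = table.copy()
    out["P10"] = out["naive_count"] > min_copy
    out["P1R"] = out["P10"] & (out["normalized_ratio"] > min_fold)
    return out


# ----------------------------------------------------------------- volcano
def volcano(
    naive_reps: ReplicateMatrix,
    amp_reps: ReplicateMatrix,
    alpha: float = 0.05,
    pseudo: float = 0.5,
    var_floor: float = 1e-12,
) -> pd.DataFrame:
    """Replicate-based enrichment test (fold f_i vs one-sided Welch t).

    Counts are scaled by each replicate's total reads; sequences missing
    from a replicate count as 0.  ``f_i = mean(amp) / mean(naive)`` with a
    pseudo-scale of ``pseudo`` reads (relative to the mean naive library
    size) substituted only when the naive mean is exactly 0.  Significance
    is a one-sided Welch t (amplified > naive) with a per-group variance
    floor; P_BR requires p < alpha and f_i > 1.  No multiple-testing
    correction is applied.
    """
    if naive_reps.n_replicates < 2 or amp_reps.n_replicates < 2:
        raise ValueError("need >= 2 replicates in each group")
    seqs, n_counts, a_counts = align_matrices(naive_reps, amp_reps)
    n_scaled = n_counts / naive_reps.library_sizes[None, :]
    a_scaled = a_counts / amp_reps.library_sizes[None, :]

    n_mean = n_scaled.mean(axis=1)
    a_mean = a_scaled.mean(axis=1)
    pseudo_scale = pseudo / naive_reps.library_sizes.mean()
    denom = np.where(n_mean > 0, n_mean, pseudo_scale)
    fold = a_mean / denom

    t, p = _welch_one_sided(a_scaled, n_scaled, var_floor)
    out = pd.DataFrame(
        {
            "naive_mean": n_mean,
            "amp_mean": a_mean,
            "f": fold,
            "t": t,
            "p": p,
        },
        index=pd.Index(seqs, name="peptide"),
    )
    out["PBR"] = (out["p"] < alpha) & (out["f"] > 1.0)
    return out


def _welch_one_sided(a: np.ndarray, b: np.ndarray, var_floor: float):
    """Welch t for H1: mean(a) > mean(b), with a variance floor per group."""
    na, nb = a.shape[1], b.shape[1]
    va = np.maximum(a.var(axis=1, ddof=1), var_floor)
    vb = np.maximum(b.var(axis=1, ddof=1), var_floor)
    se2 = va / na + vb / nb
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = sps.t.sf(t, df)
    return t, p


# ---------------------------------------------------- overdispersion (GOF)
def pearson_gof(matrix: ReplicateMatrix):
    """Exposure-scaled Pearson goodness-of-fit statistic per sequence.

    Returns ``(X, s)``: the per-sequence statistics (approximately
    chi-square with k-1 df under Poisson sampling) and the per-replicate
    scale factors s_k = total_k / mean(totals).  All-zero sequences are
    excluded.
    """
    if matrix.n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    totals = matrix.library_sizes
    if totals.sum() == 0:
        raise ValueError("all-zero matrix")
    s = totals / totals.mean()
    counts = matrix.counts.astype(float)
    lam = counts.sum(axis=1) / s.sum()
    keep = lam > 0
    expected = s[None, :] * lam[keep, None]
    x = ((counts[keep] - expected) ** 2 / expected).sum(axis=1)
    return pd.Series(x, index=np.asarray(matrix.sequences)[keep]), s


def qq_slope(
    gof_stats, df: int = 4, window: tuple[float, float] = (0.10, 0.90)
) -> float:
    """Slope of the QQ plot of GOF statistics against chi-square quantiles.

    Order statistics are paired with chi-square(df) quantiles at
    probabilities (i - 0.5)/n and a least-squares line through the origin
    is fitted over the central quantile ``window`` (the tails deviate
    because dispersion is not constant across counts).  A Poisson-sampled
    matrix gives slope ~1; variance inflation by a factor phi gives ~phi.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    x = np.sort(np.asarray(gof_stats, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need >= 100 statistics for a stable slope")
    probs = (np.arange(1, n + 1) - 0.5) / n
    keep = (probs >= window[0]) & (probs <= window[1])
    q = sps.chi2.ppf(probs[keep], df)
    y = x[keep]
    return float((q * y).sum() / (q * q).sum())


# -------------------------------------------------------------------- TMM
def tmm_factors(
    matrix: ReplicateMatrix,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    ref: int | None = None,
) -> np.ndarray:
    """Trimmed Mean of M-values normalization factors.

    Per-sequence log2 ratios (M) and mean log2 abundances (A) against a
    reference replicate are doubly trimmed (``trim_M`` of M, ``trim_A`` of
    A, both tails) and combined in a precision-weighted mean; factors are
    rescaled to multiply to 1.  The reference defaults to the replicate
    whose upper-quartile abundance is closest to the mean upper quartile.
    """
    y = matrix.counts.astype(float)
    n_lib = matrix.library_sizes.astype(float)
    k = matrix.n_replicates
    if ref is None:
        f75 = np.array([np.quantile(y[:, j] / n_lib[j], 0.75) for j in range(k)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(k)
    for j in range(k):
        if j == ref:
            continue
        ok = (y[:, j] > 0) & (y[:, ref] > 0)
        if not ok.any():
            raise ValueError(f"replicate {j} shares no nonzero sequences with reference")
        yk, yr = y[ok, j], y[ok, ref]
        pk, pr = yk / n_lib[j], yr / n_lib[ref]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (n_lib[j] - yk) / (n_lib[j] * yk) + (n_lib[ref] - yr) / (n_lib[ref] * yr)

        n = m.size
        keep = _double_trim_mask(m, trim_M) & _double_trim_mask(a, trim_A)
        if not keep.any():
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        log_factors[j] = f

    factors = 2.0 ** log_factors
    return factors / np.exp(np.mean(np.log(factors)))


def _double_trim_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Keep the central (1 - 2*trim) of values by rank (both tails cut)."""
    n = values.size
    lo = math.floor(n * trim) + 1
    hi = n + 1 - lo
    ranks = sps.rankdata(values, method="average")  # ties share their mean rank
    return (ranks >= lo) & (ranks <= hi)


# -------------------------------------------------------- NB exact testing
def nb_exact_test(
    naive_reps: ReplicateMatrix,
    amp_reps: ReplicateMatrix,
    dispersion: str = "common",
    shrink_weight: float = 0.7,
    min_total: int = 1,
) -> pd.DataFrame:
    """Negative-binomial exact test for per-sequence enrichment.

    Counts are rescaled to a common TMM-adjusted effective library size
    (the geometric mean of size * factor).  The common dispersion maximizes
    the exact conditional likelihood of replicate counts given their group
    sums (which is free of the mean parameter); tagwise dispersions are
    per-sequence moment estimates shrunk toward the common value with
    weight ``shrink_weight``.  For each sequence the one-sided exact test
    conditions on the total of the two group sums: under the null the
    amplified group sum is NB-distributed with the group's share of the
    total mean, and the p-value is the inclusive upper conditional tail
    (1 when the amplified sum is at or below its conditional expectation,
    so p measures enrichment only).

    Returns a DataFrame with group sums, dispersion, p and BH-adjusted q.
    """
    if dispersion not in ("common", "tagwise"):
        raise ValueError(f"unknown dispersion mode {dispersion!r}")
    seqs, n_counts, a_counts = align_matrices(naive_reps, amp_reps)
    counts = np.hstack([n_counts, a_counts]).astype(float)
    sizes = np.concatenate([naive_reps.library_sizes, amp_reps.library_sizes])
    if np.any(sizes <= 0):
        raise ValueError("nonpositive library sizes")
    all_reps = ReplicateMatrix(
        seqs, np.hstack([n_counts, a_counts]), sizes,
        ["naive"] * naive_reps.n_replicates + ["amplified"] * amp_reps.n_replicates,
    )
    eff = sizes * tmm_factors(all_reps)
    common_size = float(np.exp(np.mean(np.log(eff))))
    adj = counts * (common_size / eff)[None, :]

    n1 = naive_reps.n_replicates
    keep = adj.sum(axis=1) >= min_total
    adj_kept = np.rint(adj[keep]).astype(np.int64)
    groups = (adj_kept[:, :n1], adj_kept[:, n1:])

    alpha_common = _ml_common_dispersion(groups)
    if dispersion == "common":
        alphas = np.full(adj_kept.shape[0], alpha_common)
    else:
        alphas = _tagwise_dispersion(groups, alpha_common, shrink_weight)

    s1 = groups[0].sum(axis=1)
    s2 = groups[1].sum(axis=1)
    n2 = groups[1].shape[1]
    p = np.array(
        [
            _exact_tail(int(a), int(b), n1, n2, alphas[i])
            for i, (a, b) in enumerate(zip(s1, s2))
        ]
    )
    out = pd.DataFrame(
        {
            "naive_sum": s1,
            "amp_sum": s2,
            "dispersion": alphas,
            "p": p,
        },
        index=pd.Index(np.asarray(seqs)[keep], name="peptide"),
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["common_dispersion"] = alpha_common
    out.attrs["effective_sizes"] = eff
    return out


def _cond_loglik(group: np.ndarray, r: float) -> float:
    """Exact log conditional likelihood of NB replicate counts given their
    sum (independent of the mean/probability parameter)."""
    n = group.shape[1]
    z = group.sum(axis=1)
    ll = (
        special.gammaln(group + r).sum(axis=1)
        - n * special.gammaln(r)
        - special.gammaln(group + 1).sum(axis=1)
        + special.gammaln(n * r)
        + special.gammaln(z + 1)
        - special.gammaln(z + n * r)
    )
    return float(ll.sum())


def _ml_common_dispersion(groups) -> float:
    def neg(log_r: float) -> float:
        r = math.exp(log_r)
        return -sum(_cond_loglik(g, r) for g in groups)

    res = optimize.minimize_scalar(neg, bounds=(-6.0, 20.0), method="bounded")
    return float(1.0 / math.exp(res.x))  # alpha = 1/r


def _tagwise_dispersion(groups, alpha_common: float, weight: float) -> np.ndarray:
    """Per-sequence moment estimator of alpha (var = mu + alpha mu^2),
    pooled within groups, shrunk toward the common value."""
    num = np.zeros(groups[0].shape[0])
    den = np.zeros_like(num)
    for g in groups:
        mu = g.mean(axis=1)
        v = g.var(axis=1, ddof=1)
        ok = mu > 0
        num[ok] += v[ok] - mu[ok]
        den[ok] += mu[ok] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(den > 0, np.maximum(num / den, 0.0), alpha_common)
    return weight * alpha_common + (1.0 - weight) * alpha_mom


def _exact_tail(s1: int, s2: int, n1: int, n2: int, alpha: float) -> float:
    """One-sided conditional exact test of amplified (group 2) enrichment.

    Conditions on T = s1 + s2; under the null each group sum is NB with
    mean proportional to its replicate count and shape n_g / alpha.  The
    p-value is P(S2 >= s2 | T), reported as 1 when s2 is at or below its
    conditional expectation (no evidence of enrichment).
    """
    total = s1 + s2
    if total == 0:
        return 1.0
    if s2 <= total * n2 / (n1 + n2):
        return 1.0
    mu = total / (n1 + n2)
    alpha = max(alpha, 1e-12)
    r1, r2 = n1 / alpha, n2 / alpha
    pnb = 1.0 / (1.0 + alpha * mu)  # success prob shared by both group sums
    k = np.arange(total + 1)
    logp = sps.nbinom.logpmf(k, r1, pnb) + sps.nbinom.logpmf(k[::-1], r2, pnb)
    logp -= special.logsumexp(logp)
    # k indexes s1; S2 >= s2  <=>  S1 <= s1
    return float(min(1.0, np.exp(special.logsumexp(logp[: s1 + 1]))))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------- assembled table
def build_parasite_table(
    naive: PeptideMultiset,
    amplified: PeptideMultiset,
    naive_reps: ReplicateMatrix | None = None,
    amp_reps: ReplicateMatrix | None = None,
    alpha: float = 0.05,
    min_copy: int = 10,
    min_fold: float = 3.0,
    dispersion: str = "common",
) -> pd.DataFrame:
    """Assemble the full per-sequence parasite table.

    Always contains counts, abundances, the normalized ratio and the
    P10/P1R flags; if replicate matrices are supplied, adds the volcano
    statistics (f, t, p, P_BR) and the NB exact-test q-values with the
    P_ER flag (q < alpha and amplified enrichment).
    """
    table = classify_p10_p1r(ratio_table(naive, amplified), min_copy, min_fold)
    if naive_reps is not None and amp_reps is not None:
        vol = volcano(naive_reps, amp_reps, alpha=alpha)
        table = table.join(vol[["f", "t", "p", "PBR"]], how="outer")
        nb = nb_exact_test(naive_reps, amp_reps, dispersion=dispersion)
        table = table.join(nb[["q"]], how="left")
        enriched = (nb["amp_sum"] / max(amp_reps.n_replicates, 1)) > (
            nb["naive_sum"] / max(naive_reps.n_replicates, 1)
        )
        table["PER"] = (nb["q"] < alpha) & enriched
        table["PER"] = table["PER"].fillna(False)
        for flag in ("P10", "P1R", "PBR"):
            table[flag] = table[flag].fillna(False)
    return table
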