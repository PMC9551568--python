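"""Expression containers, TMM normalization, and weak-threshold differential screening.

The screening pipeline operates on TPM-scale non-negative expression values:

1. between-sample scaling factors by the trimmed mean of M-values (TMM),
2. ``log2(value / factor + pseudocount)`` transformation,
3. a per-gene two-group linear model with empirical-Bayes variance
   moderation (a moderated t on the log scale), with an unmoderated
   pooled/Welch t available as an option,
4. gene screening at deliberately *weak* thresholds (the regime of interest
   is small fold changes, roughly 1.1-1.5, that strong-signal screens miss),
5. intersection of screened sets across independent cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

CONTROL, CASE = "control", "case"


@dataclass
class LabeledExpressionMatrix:
    """Gene x sample non-negative expression values with group labels.

    ``values`` is a DataFrame indexed by gene symbol with one column per
    sample; ``group`` maps every sample id to ``"control"`` or ``"case"``.
    """

    values: pd.DataFrame
    group: dict[str, str] = field(default_factory=dict)
    cohort: str = "cohort"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        missing = [s for s in self.values.columns if s not in self.group]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = sorted(set(self.group.values()) - {CONTROL, CASE})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group[s] == group]

    def with_values(self, values: pd.DataFrame) -> "LabeledExpressionMatrix":
        return LabeledExpressionMatrix(values, dict(self.group), self.cohort)


def read_expression_tsv(
    expr_path: str | Path, meta_path: str | Path, cohort: str | None = None
) -> list[LabeledExpressionMatrix]:
    """Load expression + metadata TSVs into one matrix per cohort.

    The expression TSV has a ``gene`` first column and one column per sample;
    the metadata TSV has columns ``sample_id``, ``group`` and optionally
    ``cohort``. When *cohort* is given only that cohort is returned.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "cohort" not in meta.columns:
        meta["cohort"] = "cohort"
    out = []
    for name, sub in meta.groupby("cohort", sort=True):
        if cohort is not None and name != cohort:
            continue
        cols = [s for s in sub["sample_id"] if s in values.columns]
        group = dict(zip(sub["sample_id"], sub["group"]))
        out.append(LabeledExpressionMatrix(values[cols], {s: group[s] for s in cols}, str(name)))
    if not out:
        raise ValueError(f"no samples found for cohort {cohort!r}")
    return out


def write_expression_tsv(
    matrix: LabeledExpressionMatrix, expr_path: str | Path
) -> None:
    matrix.values.to_csv(expr_path, sep="\t", index_label="gene", float_format="%.6g")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    matrix: LabeledExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose library-size-scaled upper quartile
    is closest to the mean upper quartile. Per sample, the factor is
    ``2**(weighted mean of M values)`` after trimming the most extreme
    *trim_m* of M (log-ratio) values and *trim_a* of A (log-abundance)
    values on each side; weights are the inverse asymptotic variances of M.
    """
    x = matrix.values.to_numpy(dtype=float)
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = x.sum(axis=0)
    for s, tot in zip(samples, lib):
        if tot <= 0:
            raise ValueError(f"sample {s!r} has zero total expression")

    # reference: upper quartile of scaled values closest to the mean
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(len(samples))])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(len(samples))
    for j in range(len(samples)):
        factors[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)
    # rescale so factors multiply to 1 (comparisons are relative)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    if o.size == 0:
        return 1.0
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic variance of M under the binomial sampling model
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    m, w = m[keep2], w[keep2]
    with np.errstate(divide="ignore"):
        inv = 1.0 / w
    inv[~np.isfinite(inv)] = 0.0
    if inv.sum() == 0:
        f = float(np.mean(m))
    else:
        f = float(np.sum(m * inv) / np.sum(inv))
    return 2.0**f


def normalize_log(
    matrix: LabeledExpressionMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> LabeledExpressionMatrix:
    """``log2(value / factor + pseudocount)`` per sample; shape preserved."""
    if factors is None:
        factors = tmm_factors(matrix)
    missing = [s for s in matrix.samples if s not in factors.index]
    if missing:
        raise ValueError(f"factors missing for samples: {missing[:5]}")
    scaled = matrix.values / factors.reindex(matrix.values.columns)
    return matrix.with_values(np.log2(scaled + pseudocount))


# ---------------------------------------------------------------------------
# Two-group differential test with empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit a scaled-F prior (d0, s0^2) to per-gene sample variances.

    Method-of-moments on log variances: ``log s2`` is ``log s0^2 +
    log chi2_d/d - log chi2_d0/d0`` under the hierarchical model, so the
    excess variance of ``log s2`` over ``trigamma(d/2)`` identifies d0.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    # small-sample correction for the variance of the mean
    e_var -= float(special.polygamma(1, df / 2))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def de_two_group(
    log_matrix: LabeledExpressionMatrix,
    moderate: bool = True,
    variance: str = "pooled",
) -> pd.DataFrame:
    """Per-gene case-vs-control test on normalized log2 values.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (case minus
    control group mean), ``fc`` (= 2**log2fc), ``t_stat``, ``p_value``,
    ``mean_control``, ``mean_case``.

    With ``moderate=True`` (default) the pooled per-gene variance is shrunk
    toward a prior fitted across genes, and the t statistic uses the
    augmented degrees of freedom. ``variance="welch"`` gives a plain Welch t
    (moderation is ignored); ``moderate=False, variance="pooled"`` is the
    textbook two-sample pooled t.
    """
    ctrl = log_matrix.samples_in_group(CONTROL)
    case = log_matrix.samples_in_group(CASE)
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(ctrl)} control / {len(case)} case"
        )
    xc = log_matrix.values[ctrl].to_numpy(dtype=float)
    xa = log_matrix.values[case].to_numpy(dtype=float)
    n1, n2 = xc.shape[1], xa.shape[1]
    mean_c, mean_a = xc.mean(axis=1), xa.mean(axis=1)
    var_c = xc.var(axis=1, ddof=1)
    var_a = xa.var(axis=1, ddof=1)
    log2fc = mean_a - mean_c

    if variance == "welch":
        se2 = var_c / n1 + var_a / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 > 0, log2fc / np.sqrt(se2), 0.0)
            df = np.where(
                se2 > 0,
                se2**2
                / ((var_c / n1) ** 2 / (n1 - 1) + (var_a / n2) ** 2 / (n2 - 1)),
                n1 + n2 - 2,
            )
    elif variance == "pooled":
        df_res = n1 + n2 - 2
        s2 = ((n1 - 1) * var_c + (n2 - 1) * var_a) / df_res
        if moderate:
            d0, s0_sq = _fit_f_dist(s2, df_res)
            if np.isinf(d0):
                s2_tilde = np.full_like(s2, s0_sq)
                df = np.full(s2.shape, 1e6)
            else:
                s2_tilde = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
                df = np.full(s2.shape, d0 + df_res)
        else:
            s2_tilde = s2
            df = np.full(s2.shape, float(df_res))
        se2 = s2_tilde * (1.0 / n1 + 1.0 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 > 0, log2fc / np.sqrt(se2), 0.0)
    else:
        raise ValueError(f"unknown variance option {variance!r}")

    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1e-6))
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "t_stat": t,
            "p_value": p,
            "mean_control": mean_c,
            "mean_case": mean_a,
        },
        index=log_matrix.values.index,
    )


def screen_degs(
    result: pd.DataFrame,
    fc_threshold: float = 1.1,
    p_threshold: float = 0.1,
    direction: str = "up",
) -> frozenset:
    """Genes passing a weak (fold change, p) screen in one direction.

    ``up``: fc >= fc_threshold; ``down``: fc <= 1/fc_threshold; both
    additionally require p <= p_threshold. The defaults are the weak-signal
    screen (fc >= 1.1, p <= 0.1).
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    passing_p = result["p_value"] <= p_threshold
    if direction == "up":
        hit = (result["fc"] >= fc_threshold) & passing_p
    elif direction == "down":
        hit = (result["fc"] <= 1.0 / fc_threshold) & passing_p
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return frozenset(result.index[hit])


def intersect_degs(sets: list) -> frozenset:
    """Genes screened in every cohort (plain set intersection)."""
    if not sets:
        raise ValueError("need at least one gene set")
    out = frozenset(sets[0])
    for s in sets[1:]:
        out &= frozenset(s)
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    out = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(out, 0, 1)
    return q
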