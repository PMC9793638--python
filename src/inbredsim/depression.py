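"""Inbreeding-depression regression, power, paired comparisons and the load.

The rate of inbreeding depression (ΔID) is the negated slope of an ordinary
least-squares regression of log individual fitness on the inbreeding
coefficient, so depression is reported as a positive number.  Individuals with
zero fitness are excluded (their log fitness is undefined); the count of
exclusions is carried on the result.

The inbreeding load ``B`` (lethal equivalents per haploid genome) is
``sum_l 2 d p q`` with ``d = s (1 - 2 h) / 2``; in the absence of selection it
equals ΔID to first order in ``s``.  The exact expectation of the log-fitness
slope, ``sum_l p q (2 ln(1 - s h) - ln(1 - s))``, is also provided — it is the
quantity the ΔID regression actually estimates and exceeds ``B`` when strong
deleterious alleles segregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "LoadComponents",
    "BootstrapResult",
    "delta_id",
    "power",
    "bootstrap_compare",
    "paired_t",
    "inbreeding_load",
    "expected_delta_id",
    "summarize_replicate",
    "correlation_matrix",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    stderr: float
    t: float
    p: float
    n_used: int
    n_excluded: int
    degenerate: bool = False

    @property
    def delta_id(self) -> float:
        """Rate of inbreeding depression: -slope (positive under depression)."""
        return -self.slope


def delta_id(f_values: np.ndarray, fitness: np.ndarray) -> RegressionResult:
    """OLS of ln(fitness) on F over individuals with fitness > 0."""
    f_values = np.asarray(f_values, float)
    fitness = np.asarray(fitness, float)
    if f_values.shape != fitness.shape:
        raise ValueError("F and fitness vectors must have equal length")
    ok = fitness > 0
    n_excluded = int((~ok).sum())
    f_used = f_values[ok]
    y = np.log(fitness[ok])
    if f_used.size < 3:
        raise ValueError("need at least 3 individuals with positive fitness")
    if np.ptp(f_used) == 0.0:
        return RegressionResult(
            math.nan, math.nan, math.nan, math.nan, math.nan,
            int(f_used.size), n_excluded, degenerate=True,
        )
    res = stats.linregress(f_used, y)
    tval = res.slope / res.stderr if res.stderr > 0 else math.copysign(math.inf, res.slope)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.stderr),
        float(tval), float(res.pvalue), int(f_used.size), n_excluded,
    )


def power(p_values, alpha: float = 0.05) -> float:
    """Percentage of replicates whose slope test reached P < alpha."""
    p_values = np.asarray(list(p_values), float)
    if p_values.size == 0:
        raise ValueError("need at least one replicate")
    return 100.0 * float(np.mean(p_values < alpha))


@dataclass(frozen=True)
class BootstrapResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    n_boot: int


def bootstrap_compare(
    reference: np.ndarray,
    estimate: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> BootstrapResult:
    """Percentile bootstrap of the mean paired difference reference - estimate.

    A positive mean difference means the estimator underestimates the
    reference ΔID (the reference is typically the F_IBD-based estimate).
    """
    reference = np.asarray(reference, float)
    estimate = np.asarray(estimate, float)
    if reference.shape != estimate.shape or reference.size < 2:
        raise ValueError("need >= 2 paired estimates of equal length")
    rng = np.random.default_rng(rng)
    diffs = reference - estimate
    n = diffs.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = diffs[idx].mean(axis=1)
    return BootstrapResult(
        float(diffs.mean()),
        float(np.percentile(boot_means, 2.5)),
        float(np.percentile(boot_means, 97.5)),
        n_boot,
    )


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired-sample t-test on a - b.

    Conventions for the degenerate zero-variance case: identical pairs give
    (0, 1); a constant nonzero difference gives (±inf, 0).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), d.size - 1)
    return float(t), float(p)


@dataclass(frozen=True)
class LoadComponents:
    b: float
    v_a: float
    v_d: float
    d: np.ndarray
    alpha: np.ndarray


def inbreeding_load(q: np.ndarray, s: np.ndarray, h: np.ndarray) -> LoadComponents:
    """Inbreeding load and fitness variance components from per-locus (q, s, h).

    ``q`` is the deleterious-allele frequency.  B = sum 2 d p q with
    d = s(1-2h)/2; V_A = sum 2 α² p q with α = s/2 + d(1-2q);
    V_D = sum (2 d p q)².
    """
    q = np.asarray(q, float)
    s = np.asarray(s, float)
    h = np.asarray(h, float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    p = 1.0 - q
    d = s * (1.0 - 2.0 * h) / 2.0
    alpha = s / 2.0 + d * (1.0 - 2.0 * q)
    return LoadComponents(
        b=float((2.0 * d * p * q).sum()),
        v_a=float((2.0 * alpha**2 * p * q).sum()),
        v_d=float(((2.0 * d * p * q) ** 2).sum()),
        d=d,
        alpha=alpha,
    )


def expected_delta_id(q: np.ndarray, s: np.ndarray, h: np.ndarray) -> float:
    """Exact expected slope magnitude of ln(w) on F under the IBD mixture.

    At one locus with genotype frequencies p²+pqF, 2pq(1-F), q²+pqF the
    expectation of ln(w) is linear in F with slope p q (ln(1-s) - 2 ln(1-s h));
    summing the negated slope over loci gives the log-scale analogue of B.
    Loci with s = 1 (lethal homozygotes are excluded from any log-fitness
    regression) contribute their heterozygote term only.
    """
    q = np.asarray(q, float)
    s = np.asarray(s, float)
    h = np.asarray(h, float)
    p = 1.0 - q
    with np.errstate(divide="ignore"):
        log_het = np.log1p(-s * h)
        log_hom = np.where(s < 1.0, np.log1p(-np.minimum(s, 1 - 1e-12)), 0.0)
    return float((p * q * (2.0 * log_het - log_hom)).sum())


# ---------------------------------------------------------------------------
# replicate summaries


def summarize_replicate(ftable: pd.DataFrame, fitness: np.ndarray,
                        ibd_col: str = "IBD") -> pd.DataFrame:
    """Mean/variance/min/max, correlation with F_IBD and ΔID per measure."""
    rows = {}
    ibd = ftable[ibd_col].to_numpy() if ibd_col in ftable else None
    for col in ftable.columns:
        v = ftable[col].to_numpy(float)
        if ibd is not None and np.std(v) > 0 and np.std(ibd) > 0:
            r = float(np.corrcoef(v, ibd)[0, 1])
        else:
            r = math.nan
        try:
            reg = delta_id(v, fitness)
            did, pval = reg.delta_id, reg.p
        except ValueError:
            did, pval = math.nan, math.nan
        rows[col] = {
            "mean": float(v.mean()),
            "var": float(v.var(ddof=1)) if v.size > 1 else math.nan,
            "min": float(v.min()),
            "max": float(v.max()),
            "r_ibd": r,
            "delta_id": did,
            "p_value": pval,
        }
    return pd.DataFrame(rows).T


def correlation_matrix(ftable: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between all measures (NaN if degenerate)."""
    return ftable.corr(method="pearson")


def aggregate_replicates(summaries: list[pd.DataFrame],
                         n_boot: int = 1000,
                         rng: np.random.Generator | int | None = None) -> dict:
    """Average per-replicate summaries and compare ΔID estimates with F_IBD's.

    Returns a dict with the averaged summary table, the power per measure,
    and (when an IBD column is present) bootstrap and paired-t comparisons of
    each measure's per-replicate ΔID with the F_IBD-based ΔID.
    """
    if not summaries:
        raise ValueError("no replicate summaries given")
    rng = np.random.default_rng(rng)
    stacked = pd.concat(summaries, keys=range(len(summaries)), names=["replicate"])
    mean_table = stacked.groupby(level=1, sort=False).mean()
    pvals = stacked["p_value"].unstack(level=1)
    power_row = pvals.apply(lambda col: power(col.dropna()) if col.notna().any() else math.nan)
    out = {"summary": mean_table, "power": power_row}
    dids = stacked["delta_id"].unstack(level=1)
    if "IBD" in dids.columns:
        ref = dids["IBD"].to_numpy()
        comps = {}
        for col in dids.columns:
            if col == "IBD":
                continue
            est = dids[col].to_numpy()
            ok = np.isfinite(ref) & np.isfinite(est)
            if ok.sum() >= 2:
                boot = bootstrap_compare(ref[ok], est[ok], n_boot=n_boot, rng=rng)
                t, p = paired_t(ref[ok], est[ok])
                comps[col] = {
                    "mean_difference": boot.mean_difference,
                    "ci_low": boot.ci_low,
                    "ci_high": boot.ci_high,
                    "t": t,
                    "p": p,
                }
        out["delta_id_vs_ibd"] = pd.DataFrame(comps).T
    return out
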