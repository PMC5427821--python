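"""Genotype QC and genotype-risk-score (GRS) construction.

The instrument is the per-subject count of resistin-increasing alleles summed
over two SNPs (0–4), with the sparse top categories (3 and 4 alleles) pooled
into a single "3+" group for categorical analyses.  QC is a Hardy–Weinberg
equilibrium chi-square test per SNP and a complete-case missingness policy:
subjects missing either genotype get no score and drop out of GRS analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "GRSProfile",
    "genotype_counts",
    "hwe_test",
    "build_grs",
    "confounder_balance",
]

GRS_CATEGORIES = ["0", "1", "2", "3+"]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts (hom-ref, het, hom-alt) at one biallelic SNP."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self):
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be nonnegative")
        if self.total == 0:
            raise ValueError("all genotype counts are zero")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def allele_freq(self) -> float:
        """Estimated frequency of the alternate (risk) allele."""
        return (self.n_het + 2 * self.n_hom_alt) / (2 * self.total)


def genotype_counts(g: pd.Series | np.ndarray) -> GenotypeCounts:
    """Tabulate a vector of allele counts {0,1,2}, ignoring missing entries."""
    arr = np.asarray(pd.Series(g).dropna(), dtype=float)
    if not np.isin(arr, (0.0, 1.0, 2.0)).all():
        bad = sorted(set(arr) - {0.0, 1.0, 2.0})
        raise ValueError(f"allele counts outside {{0,1,2}}: {bad}")
    return GenotypeCounts(int((arr == 0).sum()), int((arr == 1).sum()),
                          int((arr == 2).sum()))


def hwe_test(counts: GenotypeCounts, method: str = "chi2") -> tuple[float, float]:
    """Test genotype counts against Hardy–Weinberg proportions.

    ``method="chi2"`` (default) is the Pearson chi-square with 1 df and no
    continuity correction against expected counts (n(1-p)^2, 2np(1-p), np^2)
    at the estimated allele frequency p. ``method="exact"`` is the conditional
    exact test of Wigginton, Cutler & Abecasis (two-sided, by heterozygote
    probability ordering).

    Returns (statistic, p).  For the exact test the statistic slot carries the
    observed heterozygote count.
    """
    n = counts.total
    p = counts.allele_freq
    if method == "chi2":
        if p in (0.0, 1.0):
            return 0.0, 1.0  # monomorphic: fits HWE exactly
        expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        observed = np.array([counts.n_hom_ref, counts.n_het, counts.n_hom_alt],
                            dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        return chi2, float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(counts)
    raise ValueError(f"unknown method {method!r}")


def _hwe_exact(counts: GenotypeCounts) -> tuple[float, float]:
    n = counts.total
    n_alt = counts.n_het + 2 * counts.n_hom_alt
    n_alt = min(n_alt, 2 * n - n_alt)  # work with the minor allele
    het_obs = counts.n_het
    # conditional distribution of the heterozygote count given allele counts
    hets = np.arange(n_alt % 2, n_alt + 1, 2)
    logp = np.zeros_like(hets, dtype=float)
    from scipy.special import gammaln

    def lfact(x):
        return gammaln(np.asarray(x, dtype=float) + 1.0)

    hom_alt = (n_alt - hets) // 2
    hom_ref = n - hets - hom_alt
    logp = (hets * np.log(2.0) + lfact(n) - lfact(hets) - lfact(hom_alt)
            - lfact(hom_ref) + lfact(n_alt) + lfact(2 * n - n_alt) - lfact(2 * n))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == het_obs]
    p_obs = float(p_obs[0]) if p_obs.size else 0.0
    pval = float(prob[prob <= p_obs + 1e-12].sum())
    return float(het_obs), min(pval, 1.0)


@dataclass
class GRSProfile:
    """Per-subject genotype risk scores with pooled category assignments."""

    score: pd.Series  # integer 0–4 or NaN, aligned to the source table index
    category: pd.Series  # one of GRS_CATEGORIES or NaN
    category_counts: dict[str, int]
    pool_threshold: int = 3

    @property
    def n_complete(self) -> int:
        return int(self.score.notna().sum())

    @property
    def n_excluded(self) -> int:
        return int(self.score.isna().sum())


def build_grs(table: pd.DataFrame, pool_threshold: int = 3) -> GRSProfile:
    """Sum risk-allele counts across the two SNPs and pool the top categories.

    The score is ``g1 + g2`` when both genotypes are present (missing
    otherwise, complete-case policy); scores at or above ``pool_threshold``
    collapse into a single "<threshold>+" category.
    """
    for col in ("g1", "g2"):
        if col not in table.columns:
            raise ValueError(f"table lacks genotype column {col!r}")
        vals = table[col].dropna()
        if not vals.isin([0, 1, 2]).all():
            bad = sorted(set(vals) - {0, 1, 2})
            raise ValueError(f"{col}: allele counts outside {{0,1,2}}: {bad}")
    score = table["g1"] + table["g2"]  # NaN-propagating
    top = f"{pool_threshold}+"
    labels = [str(k) for k in range(pool_threshold)] + [top]

    def categorize(s):
        if pd.isna(s):
            return np.nan
        return top if s >= pool_threshold else str(int(s))

    category = score.map(categorize)
    counts = {lab: int((category == lab).sum()) for lab in labels}
    return GRSProfile(score=score, category=category, category_counts=counts,
                      pool_threshold=pool_threshold)


def confounder_balance(table: pd.DataFrame, grs: GRSProfile,
                       covariates: list[str]) -> pd.DataFrame:
    """Association of each candidate confounder with the risk score.

    Continuous covariates: slope t-test from OLS of covariate on score.
    Binary covariates: Cochran–Armitage style trend test (score test of the
    logistic slope).  A valid instrument should show roughly uniform p-values.
    Constant covariates are flagged (p = NaN), not raised.
    """
    if not covariates:
        raise ValueError("empty covariate list")
    from .exposure import _numeric_covariate  # shared sex/boolean coding

    keep = grs.score.notna()
    s = grs.score[keep].astype(float)
    rows = []
    for cov in covariates:
        x = _numeric_covariate(table, cov)[keep]
        mask = x.notna()
        xv, sv = x[mask].to_numpy(float), s[mask].to_numpy(float)
        binary = set(np.unique(xv)) <= {0.0, 1.0}
        if np.ptp(xv) == 0 or np.ptp(sv) == 0:
            rows.append((cov, "constant", np.nan, np.nan))
            continue
        if binary:
            # trend chi-square: corr^2 * n  ~ chi2(1) under independence
            r = np.corrcoef(xv, sv)[0, 1]
            stat = r**2 * len(xv)
            p = float(stats.chi2.sf(stat, df=1))
            rows.append((cov, "trend_chi2", float(stat), p))
        else:
            res = stats.linregress(sv, xv)
            rows.append((cov, "linear", float(res.slope), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["covariate", "test", "statistic", "p"])
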