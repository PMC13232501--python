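"""Pool-based association statistics and region-level parentage tests.

Per-site association between extreme activity pools is tested with
Fisher's exact test on the (allele x pool) 2x2 table with Bonferroni
correction; per-region Hi-parentage fractions are compared between pools
with the Wilcoxon rank-sum test.  Also houses the expected-mapping-
resolution arithmetic and the classical centimorgan-vs-Mb regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .origins import HI, LO  # noqa: F401 - LO used by callers building tables
from .painting import PaintedChromosome
from .xo_rates import Region, RegionSet

__all__ = [
    "fisher_exact_2x2",
    "fisher_site_association",
    "bonferroni",
    "hi_fraction",
    "parentage_fractions",
    "compare_fractions",
    "expected_resolution",
    "cm_mb_fit",
]


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value by the probability-mass method.

    Sums the hypergeometric probability of every table with the observed
    margins whose point probability does not exceed the observed table's
    (with a small relative fudge against float ties) — the convention of
    R's fisher.test and of PLINK.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0:
        return 1.0
    k = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(k, n, r1, c1)
    obs = pmf[np.searchsorted(k, a)]
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-7)].sum()))


def fisher_site_association(
    calls: np.ndarray,
    positions: np.ndarray,
    pools: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-site Fisher exact association between the two extreme pools.

    ``calls`` is the haploid genotype matrix (flies x sites, -1 missing);
    ``pools`` gives per-fly labels among {'high', 'low', 'unassayed'}.
    Missing calls drop that fly at that site only.  Monomorphic sites get
    p = 1 and are flagged.  Bonferroni significance uses alpha over the
    number of polymorphic sites tested.
    """
    high = pools == "high"
    low = pools == "low"
    if not high.any() or not low.any():
        raise ValueError("both pools must be non-empty")
    rows = []
    for j, pos in enumerate(positions):
        col = calls[:, j]
        n_hi_alt = int(((col == 1) & high).sum())
        n_hi_ref = int(((col == 0) & high).sum())
        n_lo_alt = int(((col == 1) & low).sum())
        n_lo_ref = int(((col == 0) & low).sum())
        table = np.array([[n_hi_alt, n_hi_ref], [n_lo_alt, n_lo_ref]])
        monomorphic = (n_hi_alt + n_lo_alt == 0) or (n_hi_ref + n_lo_ref == 0)
        p = 1.0 if monomorphic else fisher_exact_2x2(table)
        rows.append(
            {
                "position": int(pos),
                "high_alt": n_hi_alt,
                "high_ref": n_hi_ref,
                "low_alt": n_lo_alt,
                "low_ref": n_lo_ref,
                "monomorphic": monomorphic,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    m = int((~out["monomorphic"]).sum())
    threshold, flags = bonferroni(out["p"].to_numpy(), alpha, m=max(m, 1))
    out["significant"] = flags & ~out["monomorphic"]
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tests"] = m
    out["neg_log10_p"] = -np.log10(out["p"])
    return out


def bonferroni(
    p_values: np.ndarray, alpha: float = 0.05, m: int | None = None
) -> tuple[float, np.ndarray]:
    """Bonferroni threshold alpha/m and per-test significance flags."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("need at least one test")
    threshold = alpha / m
    return threshold, p < threshold


def hi_fraction(painting: PaintedChromosome, region: Region) -> float:
    """Fraction of determinable bp in a region painted as Hi parentage.

    Hi bp / (Hi + Lo bp) within [start, end); 0 is a full Lo tract, 1 a
    full Hi tract, fractions arise from crossovers inside the region.
    Raises if the region is entirely Unknown.
    """
    starts = painting.tract_starts
    ends = np.append(starts[1:], painting.chrom_len)
    overlap = np.clip(
        np.minimum(ends, region.end) - np.maximum(starts, region.start), 0, None
    )
    hi_bp = overlap[painting.tract_origins == HI].sum()
    lo_bp = overlap[painting.tract_origins == LO].sum()
    if hi_bp + lo_bp == 0:
        raise ValueError(
            f"region {region.label} has no determinable parentage for "
            f"fly {painting.fly_id!r}"
        )
    return float(hi_bp / (hi_bp + lo_bp))


def parentage_fractions(
    paintings: list[PaintedChromosome], regions: RegionSet
) -> pd.DataFrame:
    """Per-fly Hi-parentage fraction in every dense region (NaN if unknown)."""
    rows = []
    for p in paintings:
        row: dict = {"fly_id": p.fly_id}
        for region in regions.dense():
            try:
                row[region.label] = hi_fraction(p, region)
            except ValueError:
                row[region.label] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("fly_id")


def compare_fractions(
    fractions: pd.DataFrame,
    pools: pd.Series,
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Wilcoxon rank-sum test of Hi fraction between pools, per region.

    Two-sided; the tie-free exact null distribution is used when the
    smaller pool has at most ``exact_max_n`` flies (conservative under
    ties), otherwise the normal approximation with tie and continuity
    correction.  P-values are Bonferroni-corrected over the number of
    regions (multiplied by the region count, capped at 1).
    """
    regions = list(fractions.columns)
    rows = []
    for label in regions:
        vals = fractions[label]
        hi_vals = vals[pools.reindex(vals.index) == "high"].dropna().to_numpy()
        lo_vals = vals[pools.reindex(vals.index) == "low"].dropna().to_numpy()
        if len(hi_vals) == 0 or len(lo_vals) == 0:
            raise ValueError(f"empty pool for region {label}")
        pooled = np.concatenate([hi_vals, lo_vals])
        if np.all(pooled == pooled[0]):
            p = 1.0  # degenerate: every observation tied
        else:
            method = (
                "exact"
                if min(len(hi_vals), len(lo_vals)) <= exact_max_n
                else "asymptotic"
            )
            p = float(
                stats.mannwhitneyu(
                    hi_vals, lo_vals, alternative="two-sided", method=method
                ).pvalue
            )
        rows.append(
            {
                "region": label,
                "n_high": len(hi_vals),
                "n_low": len(lo_vals),
                "mean_high": float(hi_vals.mean()),
                "mean_low": float(lo_vals.mean()),
                "p": p,
                "p_bonferroni": min(1.0, p * len(regions)),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def expected_resolution(chrom_len_mb: float, n_recomb_opportunities: int) -> float:
    """Expected mapping resolution in Mb for uniformly placed crossovers.

    With n independent opportunities for a single reciprocal crossover,
    uniformly placed breakpoints partition the chromosome into segments of
    expected length chrom_len / 2**n Mb.
    """
    if n_recomb_opportunities < 0:
        raise ValueError("number of opportunities must be >= 0")
    return chrom_len_mb / 2**n_recomb_opportunities


def cm_mb_fit(points) -> tuple[float, float, float]:
    """Least-squares fit of genetic map position (cM) on physical position (Mb).

    Returns (slope, intercept, r_squared).  Requires at least three points
    with non-degenerate physical positions.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (cM, Mb) points")
    cm, mb = pts[:, 0], pts[:, 1]
    if np.ptp(mb) == 0:
        raise ValueError("physical positions have zero variance")
    fit = stats.linregress(mb, cm)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
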