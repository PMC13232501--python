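"""Region-wise crossover counting, per-meiosis rate estimation and the
exact conditional rate test.

The chromosome is segmented into SNP-dense blocks and sparse gaps.  Within
dense blocks crossovers are counted directly as switches in painted
parentage; within a sparse gap parentage cannot be read off directly, so a
single crossover is inferred whenever the flanking dense blocks disagree in
origin at their facing edges (a lower bound — an even number of gap
crossovers is invisible).  Counts are normalised to crossovers per Mb per
fly per effective female meiosis, with percentile-bootstrap confidence
intervals over flies, and dense-vs-sparse rate differences are tested by
conditioning on the total count, under which one region's count is binomial
with length-proportional success probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .origins import UNKNOWN
from .painting import InformativeSiteSet, PaintedChromosome

__all__ = [
    "Region",
    "RegionSet",
    "segment_by_density",
    "count_crossovers",
    "infer_flanking_crossover",
    "per_meiosis_rate",
    "bootstrap_ci",
    "exact_conditional_rate_test",
    "crossover_table",
    "rate_table",
]


@dataclass(frozen=True)
class Region:
    label: str
    start: int  # bp, 0-based
    end: int  # bp, half-open
    kind: str  # "dense" | "sparse"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.label} is empty")
        if self.kind not in ("dense", "sparse"):
            raise ValueError(f"unknown region class {self.kind!r}")

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass
class RegionSet:
    """Sorted, disjoint labelled intervals classified dense/sparse."""

    regions: list[Region]

    def __post_init__(self) -> None:
        for a, b in zip(self.regions, self.regions[1:]):
            if b.start < a.end:
                raise ValueError(f"regions {a.label} and {b.label} overlap/unsorted")

    def dense(self) -> list[Region]:
        return [r for r in self.regions if r.kind == "dense"]

    def sparse(self) -> list[Region]:
        return [r for r in self.regions if r.kind == "sparse"]

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)


def segment_by_density(
    sites: InformativeSiteSet,
    window: int = 100_000,
    dense_threshold: float = 10.0,
) -> RegionSet:
    """Classify the chromosome into dense blocks and sparse gaps.

    Tiles the chromosome with windows of ``window`` bp, computes SNP
    density per window in SNPs/10 kb, and takes maximal runs of windows at
    or above ``dense_threshold`` as dense blocks (labelled A, B, ... in
    coordinate order); dense blocks separated by a gap shorter than one
    window are merged.  The complement intervals are the sparse gaps,
    labelled ``gap_<left><right>`` after their flanking blocks (or
    ``gap_start``/``gap_end`` at the chromosome ends).
    """
    if window < 10_000:
        raise ValueError("window must be >= 10 kb")
    if sites.n_sites == 0:
        raise ValueError("empty site set")
    L = sites.chrom_len
    n_win = max(1, -(-L // window))
    edges = np.minimum(np.arange(n_win + 1) * window, L)
    counts = np.histogram(sites.positions, bins=edges)[0]
    density = counts / np.diff(edges) * 10_000  # SNPs / 10 kb
    dense_win = density >= dense_threshold

    blocks: list[list[int]] = []  # [start_bp, end_bp]
    for i in np.nonzero(dense_win)[0]:
        s, e = int(edges[i]), int(edges[i + 1])
        if blocks and s - blocks[-1][1] < window:
            blocks[-1][1] = e
        else:
            blocks.append([s, e])

    regions: list[Region] = []
    cursor = 0
    prev_label = "start"
    for i, (s, e) in enumerate(blocks):
        label = _dense_label(i)
        if s > cursor:
            regions.append(Region(f"gap_{prev_label}{label}", cursor, s, "sparse"))
        regions.append(Region(label, s, e, "dense"))
        cursor, prev_label = e, label
    if cursor < L:
        regions.append(Region(f"gap_{prev_label}end", cursor, L, "sparse"))
    return RegionSet(regions)


def _dense_label(i: int) -> str:
    if i < 26:
        return chr(ord("A") + i)
    return f"Z{i - 25}"


def count_crossovers(painting: PaintedChromosome, region: Region) -> int:
    """Crossovers within a region for one fly.

    A crossover is a Hi<->Lo switch in painted parentage; its breakpoint is
    only localised to the interval between the flanking informative sites,
    so a switch is assigned to the region containing that interval's
    midpoint (a straddling interval goes to whichever side holds the
    midpoint).
    """
    if region.start < 0 or region.end > painting.chrom_len:
        raise ValueError(f"region {region.label} outside chromosome")
    n = 0
    for left, right in painting.switch_intervals():
        mid = (left + right) // 2
        if region.start <= mid < region.end:
            n += 1
    return n


def infer_flanking_crossover(
    painting: PaintedChromosome, left: Region, right: Region
) -> int | None:
    """Minimum-crossover inference for the sparse gap between two dense blocks.

    Returns 1 if the painted origin at the facing edges of the flanking
    dense blocks differs (at least one crossover must lie between), 0 if
    they agree, and None when either edge is Unknown (not evaluable).
    Parity caveat: an even number of gap crossovers returns 0.
    """
    if left.end > right.start:
        raise ValueError("left region must precede right region")
    edges = np.array([left.end - 1, right.start], dtype=np.int64)
    o_left, o_right = painting.origin_at(edges)
    if o_left == UNKNOWN or o_right == UNKNOWN:
        return None
    return int(o_left != o_right)


def per_meiosis_rate(
    count: int, length_mb: float, n_flies: int = 84, n_meioses: int = 5
) -> float:
    """Crossovers per Mb per fly per effective female meiosis.

    The default denominators are the study's: 84 flies passing QC and 5
    effective opportunities for a transmitted chromatid to carry a single
    reciprocal crossover over the intermating scheme.
    """
    if length_mb <= 0:
        raise ValueError("region length must be positive")
    if n_flies <= 0 or n_meioses <= 0:
        raise ValueError("denominators must be positive")
    return count / length_mb / n_flies / n_meioses


def bootstrap_ci(
    per_fly_counts: np.ndarray,
    length_mb: float,
    n_meioses: int = 5,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
    n_flies: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI of the per-meiosis rate.

    Flies are the exchangeable unit: resample flies with replacement
    ``n_boot`` times, recompute the rate each time, and return the
    2.5/97.5 percentiles.  ``n_flies`` defaults to the number of counts
    supplied.
    """
    counts = np.asarray(per_fly_counts)
    if counts.size < 1:
        raise ValueError("need at least one fly")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = counts.size
    denom = n_flies if n_flies is not None else n
    idx = rng.integers(0, n, size=(n_boot, n))
    rates = counts[idx].sum(axis=1) / length_mb / denom / n_meioses
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_rate_ratio(
    counts_num: np.ndarray,
    length_num_mb: float,
    counts_den: np.ndarray,
    length_den_mb: float,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Per-Mb rate ratio between two region groups with a bootstrap 95% CI.

    ``counts_num``/``counts_den`` are per-fly crossover counts summed over
    the numerator (e.g. a sparse gap) and denominator (e.g. pooled dense
    blocks) regions; rows correspond to the same flies and are resampled
    jointly, preserving the within-fly coupling of the two counts.
    Resamples with a zero denominator (or an all-zero numerator when the
    observed numerator is zero) are undefined and excluded.  Returns
    (point_ratio, (lo, hi)); the point ratio is NaN when not evaluable.
    """
    num = np.asarray(counts_num, dtype=float)
    den = np.asarray(counts_den, dtype=float)
    if num.shape != den.shape or num.ndim != 1:
        raise ValueError("need matching per-fly count vectors")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = num.size

    def ratio(ns: np.ndarray, ds: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ns / length_num_mb) / (ds / length_den_mb)

    point = float(ratio(num.sum(), den.sum()))
    idx = rng.integers(0, n, size=(n_boot, n))
    rates = ratio(num[idx].sum(axis=1), den[idx].sum(axis=1))
    rates = rates[np.isfinite(rates)]
    if rates.size == 0:
        return point, (float("nan"), float("nan"))
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return point, (float(lo), float(hi))


def exact_conditional_rate_test(
    c_a: int, length_a_mb: float, c_b: int, length_b_mb: float
) -> float:
    """Exact conditional test of equal per-Mb Poisson rates in two regions.

    Conditions on the total N = c_a + c_b, under which c_a is
    Binomial(N, L_a / (L_a + L_b)) when the per-Mb rates are equal.  The
    two-sided p-value is the probability-mass (minimum-likelihood) sum:
    the total probability of all outcomes no more likely than the observed
    one.  Both counts zero returns p = 1 by convention.
    """
    if c_a < 0 or c_b < 0:
        raise ValueError("counts must be >= 0")
    if length_a_mb <= 0 or length_b_mb <= 0:
        raise ValueError("lengths must be positive")
    n = c_a + c_b
    if n == 0:
        return 1.0
    p0 = length_a_mb / (length_a_mb + length_b_mb)
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    # relative fudge guards float noise in genuine probability ties
    return float(min(1.0, pmf[pmf <= pmf[c_a] * (1 + 1e-7)].sum()))


# ---------------------------------------------------------------------------
# cohort-level tables


def crossover_table(
    paintings: list[PaintedChromosome],
    regions: RegionSet,
    sparse_gaps: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Per-fly per-region crossover counts.

    Dense-block columns hold direct switch counts; for each sparse gap
    (``gap_label, left_dense, right_dense``) the column holds the 0/1
    inferred-flanking-crossover indicator (NaN when not evaluable).  By
    default every sparse gap lying between two dense blocks is included.
    """
    if sparse_gaps is None:
        sparse_gaps = _internal_gaps(regions)
    rows = []
    for p in paintings:
        row: dict = {"fly_id": p.fly_id}
        for region in regions.dense():
            row[region.label] = count_crossovers(p, region)
        for gap_label, left, right in sparse_gaps:
            ind = infer_flanking_crossover(p, regions[left], regions[right])
            row[gap_label] = np.nan if ind is None else ind
        rows.append(row)
    return pd.DataFrame(rows).set_index("fly_id")


def _internal_gaps(regions: RegionSet) -> list[tuple[str, str, str]]:
    out = []
    dense = regions.dense()
    for r in regions.sparse():
        left = [d for d in dense if d.end <= r.start]
        right = [d for d in dense if d.start >= r.end]
        if left and right:
            out.append((r.label, left[-1].label, right[0].label))
    return out


def rate_table(
    counts: pd.DataFrame,
    regions: RegionSet,
    n_flies: int = 84,
    n_meioses: int = 5,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
    sparse_reference: str | None = None,
) -> pd.DataFrame:
    """Region-wise rate estimates with bootstrap CIs and rate tests.

    ``sparse_reference`` names the sparse gap used as comparator for the
    per-region exact conditional tests (default: the shortest evaluated
    sparse gap, the study's choice).  Flies with a non-evaluable gap
    indicator are dropped for that gap only.
    """
    rng = np.random.default_rng(seed)
    labels = [c for c in counts.columns]
    region_by_label = {r.label: r for r in regions}
    rows = []
    for label in labels:
        region = region_by_label[label]
        per_fly = counts[label].dropna().to_numpy()
        total = int(per_fly.sum())
        rate = per_meiosis_rate(total, region.length_mb, n_flies, n_meioses)
        lo, hi = bootstrap_ci(
            per_fly, region.length_mb, n_meioses, n_boot, rng, n_flies=n_flies
        )
        rows.append(
            {
                "region": label,
                "class": region.kind,
                "count": total,
                "length_mb": region.length_mb,
                "rate": rate,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    table = pd.DataFrame(rows).set_index("region")
    if sparse_reference is None:
        sparse = table[table["class"] == "sparse"]
        if len(sparse):
            sparse_reference = sparse["length_mb"].idxmin()
    if sparse_reference is not None:
        ref = table.loc[sparse_reference]
        table["p_vs_sparse"] = [
            exact_conditional_rate_test(
                int(row["count"]),
                row["length_mb"],
                int(ref["count"]),
                ref["length_mb"],
            )
            if label != sparse_reference
            else np.nan
            for label, row in table.iterrows()
        ]
    return table
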