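"""Forward simulator of the free-intermating bulk segregant design.

Generates truth-tagged recombinant X chromosomes, genotype calls and
activity phenotypes with the statistical structure the downstream analysis
assumes: SNPs clustered into dense blocks on a sparse background, female-only
recombination with crossover placement down-weighted inside dense blocks,
an activity phenotype driven by Hi parentage of causal regions, and
genotype dropout/error mimicking low-coverage single-fly sequencing.

The X-specific transmission rules are modelled explicitly: females carry
two X's and recombine at meiosis, males carry one X transmitted intact to
daughters only, sons receive a (possibly recombinant) maternal gamete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .origins import HI, LO

__all__ = [
    "ParentalHaplotypes",
    "TruthChromosome",
    "CrossoverWeights",
    "build_parental_snps",
    "crossover_weights",
    "sample_crossover_positions",
    "simulate_generations",
    "simulate_phenotypes",
    "genotype_cohort",
    "parental_genotypes",
    "select_extreme_pools",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# parental haplotypes


@dataclass
class ParentalHaplotypes:
    """Positions and alleles of the two parental X lines.

    ``hi_allele``/``lo_allele`` are 0/1 codes (REF/ALT) and differ at every
    site; sites flagged heterozygous in either line (``het_hi``/``het_lo``)
    are non-fixed in that line and must be dropped by informative-site QC.
    """

    positions: np.ndarray  # int64, strictly increasing
    hi_allele: np.ndarray  # int8 in {0, 1}
    lo_allele: np.ndarray  # int8 in {0, 1}
    het_hi: np.ndarray  # bool
    het_lo: np.ndarray  # bool
    chrom_len: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        informative = ~(self.het_hi | self.het_lo)
        if np.any(self.hi_allele[informative] == self.lo_allele[informative]):
            raise ValueError("hi and lo alleles must differ at informative sites")

    @property
    def het_mask(self) -> np.ndarray:
        """Sites excluded as non-fixed in at least one parental line."""
        return self.het_hi | self.het_lo

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def divergence(self) -> float:
        """Genome-wide fraction of divergent sites (SNPs per bp)."""
        return self.n_sites / self.chrom_len


def build_parental_snps(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> ParentalHaplotypes:
    """Draw parental SNP positions as an inhomogeneous Poisson process.

    The rate is ``dense_snp_rate`` inside the configured dense blocks and
    ``sparse_snp_rate`` elsewhere.  Each site is independently flagged
    heterozygous in the Hi / Lo line with the configured probabilities.
    """
    rng = np.random.default_rng(seed)
    segments = _density_segments(config)
    pos_chunks: list[np.ndarray] = []
    for start, end, dense in segments:
        rate = config.dense_snp_rate if dense else config.sparse_snp_rate
        n = rng.poisson(rate * (end - start))
        pos_chunks.append(
            np.sort(rng.integers(start, end, size=n, dtype=np.int64))
        )
    positions = np.concatenate(pos_chunks) if pos_chunks else np.empty(0, np.int64)
    positions = np.unique(positions)  # Poisson collisions at bp resolution
    n = len(positions)
    hi = rng.integers(0, 2, size=n).astype(np.int8)
    lo = (1 - hi).astype(np.int8)
    p_hi, p_lo = config.parental_het_frac
    het_hi = rng.random(n) < p_hi
    het_lo = rng.random(n) < p_lo
    return ParentalHaplotypes(positions, hi, lo, het_hi, het_lo, config.chrom_len)


def _density_segments(config: SimulationConfig) -> list[tuple[int, int, bool]]:
    """Tile [0, chrom_len) into (start, end, is_dense) segments."""
    segs: list[tuple[int, int, bool]] = []
    cursor = 0
    for _, start, end in config.dense_regions:
        if start > cursor:
            segs.append((cursor, start, False))
        segs.append((start, end, True))
        cursor = end
    if cursor < config.chrom_len:
        segs.append((cursor, config.chrom_len, False))
    return segs


# ---------------------------------------------------------------------------
# crossover placement


@dataclass(frozen=True)
class CrossoverWeights:
    """Piecewise-constant crossover-placement density over the chromosome.

    ``bounds`` has one more entry than ``weights``; segment i spans
    [bounds[i], bounds[i+1]) with relative density weights[i].
    """

    bounds: np.ndarray  # int64, bounds[0] == 0, bounds[-1] == chrom_len
    weights: np.ndarray  # float, >= 0

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.weights) + 1:
            raise ValueError("bounds must have len(weights) + 1 entries")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        mass = self.weights * np.diff(self.bounds)
        if mass.sum() <= 0:
            raise ValueError("all-zero crossover weight profile")


def crossover_weights(config: SimulationConfig) -> CrossoverWeights:
    """Weight 1 in sparse sequence, 1/suppression_factor inside dense blocks."""
    segs = _density_segments(config)
    bounds = np.array([s[0] for s in segs] + [config.chrom_len], dtype=np.int64)
    weights = np.array(
        [1.0 / config.suppression_factor if dense else 1.0 for _, _, dense in segs]
    )
    return CrossoverWeights(bounds, weights)


def sample_crossover_positions(
    weights: CrossoverWeights, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. crossover positions with density prop. to the profile."""
    rng = np.random.default_rng(seed)
    seg_len = np.diff(weights.bounds).astype(float)
    mass = weights.weights * seg_len
    cum = np.cumsum(mass)
    u = rng.random(n) * cum[-1]
    seg = np.searchsorted(cum, u, side="right")
    offset = (u - (cum[seg] - mass[seg])) / weights.weights[seg]
    pos = weights.bounds[seg] + offset.astype(np.int64)
    return np.sort(pos)


# ---------------------------------------------------------------------------
# truth chromosomes and meiosis


@dataclass
class TruthChromosome:
    """Parental-origin tracts of one X, with full crossover lineage.

    Tracts tile [0, chrom_len) with no gaps and alternating origins:
    tract i spans [starts[i], starts[i+1]) (the last runs to chrom_len) and
    has origin ``origins[i]``.  ``lineage`` records realised crossover
    breakpoints as (position, generation) pairs.
    """

    starts: np.ndarray  # int64, starts[0] == 0, strictly increasing
    origins: np.ndarray  # int8 in {HI, LO}, adjacent entries differ
    chrom_len: int
    lineage: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def pure(cls, origin: int, chrom_len: int) -> "TruthChromosome":
        return cls(
            np.zeros(1, np.int64), np.array([origin], np.int8), chrom_len, []
        )

    @property
    def n_tracts(self) -> int:
        return len(self.starts)

    def tracts(self) -> list[tuple[int, int, int]]:
        """As (origin, start, end) triples."""
        ends = np.append(self.starts[1:], self.chrom_len)
        return [
            (int(o), int(s), int(e))
            for o, s, e in zip(self.origins, self.starts, ends)
        ]

    def origin_at(self, positions: np.ndarray) -> np.ndarray:
        """Origin code of the tract covering each position."""
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        return self.origins[idx]

    def hi_fraction(self, start: int, end: int) -> float:
        """Fraction of [start, end) descending from the Hi line."""
        if end <= start:
            raise ValueError("empty interval")
        ends = np.append(self.starts[1:], self.chrom_len)
        overlap = np.clip(
            np.minimum(ends, end) - np.maximum(self.starts, start), 0, None
        )
        return float(overlap[self.origins == HI].sum() / (end - start))

    def is_pure(self) -> bool:
        return self.n_tracts == 1


def _splice(
    h_first: TruthChromosome,
    h_other: TruthChromosome,
    breakpoints: np.ndarray,
    generation: int,
) -> TruthChromosome:
    """Build a gamete that follows ``h_first`` up to the first breakpoint,
    then alternates homologs at each subsequent breakpoint."""
    chrom_len = h_first.chrom_len
    homologs = (h_first, h_other)
    cuts = [0, *[int(b) for b in breakpoints], chrom_len]
    starts: list[int] = []
    origins: list[int] = []
    lineage: list[tuple[int, int]] = []
    for i in range(len(cuts) - 1):
        a, b = cuts[i], cuts[i + 1]
        if a >= b:
            continue
        h = homologs[i % 2]
        # tracts of h overlapping [a, b)
        lo_idx = int(np.searchsorted(h.starts, a, side="right")) - 1
        hi_idx = int(np.searchsorted(h.starts, b, side="left"))
        for j in range(lo_idx, hi_idx):
            s = max(int(h.starts[j]), a)
            o = int(h.origins[j])
            if origins and origins[-1] == o:
                pass  # merge with previous tract
            else:
                starts.append(s)
                origins.append(o)
        lineage.extend((p, g) for p, g in h.lineage if a < p < b)
        if i + 1 < len(cuts) - 1:
            lineage.append((cuts[i + 1], generation))
    lineage.sort()
    return TruthChromosome(
        np.array(starts, np.int64), np.array(origins, np.int8), chrom_len, lineage
    )


def _meiosis(
    x1: TruthChromosome,
    x2: TruthChromosome,
    weights: CrossoverWeights,
    mean_cos: float,
    rng: np.random.Generator,
    generation: int,
) -> TruthChromosome:
    """One female meiosis: Poisson crossovers on the bivalent, each carried
    by the transmitted chromatid with probability 1/2 (no interference)."""
    n_co = rng.poisson(mean_cos)
    positions = sample_crossover_positions(weights, n_co, rng)
    retained = positions[rng.random(n_co) < 0.5]
    first, other = (x1, x2) if rng.random() < 0.5 else (x2, x1)
    if len(retained) == 0:
        return TruthChromosome(
            first.starts.copy(), first.origins.copy(), first.chrom_len,
            list(first.lineage),
        )
    return _splice(first, other, retained, generation)


def simulate_generations(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> list[TruthChromosome]:
    """Run the intermating design and return the assayed males' X's.

    Discrete non-overlapping generations with random union of gametes and
    an equal sex ratio.  Founders are Hi/Hi females and hemizygous Lo
    males; after ``generations`` rounds of free intermating,
    ``n_assayed_males`` sons are drawn from the final parental pool.
    With ``generations == 0`` the assayed males are founder males.
    """
    rng = np.random.default_rng(seed)
    weights = crossover_weights(config)
    L = config.chrom_len
    females: list[tuple[TruthChromosome, TruthChromosome]] = [
        (TruthChromosome.pure(HI, L), TruthChromosome.pure(HI, L))
        for _ in range(config.n_founder_hi_females)
    ]
    males: list[TruthChromosome] = [
        TruthChromosome.pure(LO, L) for _ in range(config.n_founder_lo_males)
    ]

    def son(gen: int) -> TruthChromosome:
        x1, x2 = females[rng.integers(len(females))]
        return _meiosis(x1, x2, weights, config.mean_cos_per_meiosis, rng, gen)

    def daughter(gen: int) -> tuple[TruthChromosome, TruthChromosome]:
        x1, x2 = females[rng.integers(len(females))]
        gamete = _meiosis(x1, x2, weights, config.mean_cos_per_meiosis, rng, gen)
        paternal = males[rng.integers(len(males))]
        return (gamete, paternal)

    if config.generations == 0:
        return [males[rng.integers(len(males))] for _ in range(config.n_assayed_males)]

    for gen in range(1, config.generations):
        n_f = config.pop_size // 2
        n_m = config.pop_size - n_f
        new_females = [daughter(gen) for _ in range(n_f)]
        new_males = [son(gen) for _ in range(n_m)]
        females, males = new_females, new_males

    return [son(config.generations) for _ in range(config.n_assayed_males)]


# ---------------------------------------------------------------------------
# phenotypes, genotyping, pooling


def _region_lookup(config: SimulationConfig) -> dict[str, tuple[int, int]]:
    return {label: (start, end) for label, start, end in config.dense_regions}


def simulate_phenotypes(
    cohort: list[TruthChromosome],
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> "pd.DataFrame":
    """Activity = baseline + sum of per-region effects x Hi fraction + noise.

    Gaussian noise with sd ``activity_sd``; activity floored at 0 counts/day.
    """
    import pandas as pd

    if config.activity_sd < 0:
        raise ValueError("activity_sd must be >= 0")
    rng = np.random.default_rng(seed)
    regions = _region_lookup(config)
    n = len(cohort)
    activity = np.full(n, config.baseline_activity)
    for label in config.causal_regions:
        start, end = regions[label]
        effect = config.effect_sizes.get(label, 0.0)
        activity += effect * np.array([c.hi_fraction(start, end) for c in cohort])
    activity = np.maximum(activity + rng.normal(0, config.activity_sd, n), 0.0)
    return pd.DataFrame(
        {"fly_id": [f"fly{i:04d}" for i in range(n)], "activity": activity}
    )


def select_extreme_pools(
    phenotypes: "pd.DataFrame", pool_size: int
) -> "pd.DataFrame":
    """Label the lowest/highest ``pool_size`` flies by activity.

    Ties are broken by fly id, so the split is deterministic.  Returns the
    table with a ``pool`` column in {'low', 'high', 'unassayed'}.
    """
    if len(phenotypes) < 2 * pool_size:
        raise ValueError(
            f"need >= {2 * pool_size} flies for two pools of {pool_size}, "
            f"got {len(phenotypes)}"
        )
    out = phenotypes.copy()
    order = out.sort_values(["activity", "fly_id"], kind="mergesort").index
    out["pool"] = "unassayed"
    out.loc[order[:pool_size], "pool"] = "low"
    out.loc[order[len(order) - pool_size:], "pool"] = "high"
    return out


def genotype_cohort(
    cohort: list[TruthChromosome],
    parental: ParentalHaplotypes,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Haploid genotype calls for each fly at every parental site.

    Returns an int8 matrix (flies x sites): the allele of the covering
    truth tract, flipped with ``genotype_error_prob`` and replaced by -1
    (missing) with ``dropout_prob``.
    """
    rng = np.random.default_rng(seed)
    pos = parental.positions
    if len(pos) and (pos[0] < 0 or pos[-1] >= config.chrom_len):
        raise ValueError("site outside chromosome")
    n_flies, n_sites = len(cohort), len(pos)
    calls = np.empty((n_flies, n_sites), dtype=np.int8)
    for i, chrom in enumerate(cohort):
        origin = chrom.origin_at(pos)
        calls[i] = np.where(origin == HI, parental.hi_allele, parental.lo_allele)
    flip = rng.random(calls.shape) < config.genotype_error_prob
    calls[flip] = 1 - calls[flip]
    calls[rng.random(calls.shape) < config.dropout_prob] = -1
    return calls


def parental_genotypes(
    parental: ParentalHaplotypes, n_hi: int = 3, n_lo: int = 2
) -> np.ndarray:
    """Diploid parental sample genotypes as an int8 array
    (samples x sites x 2 alleles); Hi samples first.

    At sites flagged heterozygous in a line, that line's samples carry a
    het call, so informative-site QC can recognise and drop them.
    """
    n_sites = parental.n_sites
    geno = np.empty((n_hi + n_lo, n_sites, 2), dtype=np.int8)
    for s in range(n_hi):
        geno[s, :, 0] = parental.hi_allele
        geno[s, :, 1] = np.where(
            parental.het_hi, 1 - parental.hi_allele, parental.hi_allele
        )
    for s in range(n_lo):
        geno[n_hi + s, :, 0] = parental.lo_allele
        geno[n_hi + s, :, 1] = np.where(
            parental.het_lo, 1 - parental.lo_allele, parental.lo_allele
        )
    return geno


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_study(config: SimulationConfig, seed: int | None = None):
    """Run the full generator: parents, cohort, phenotypes, pools, genotypes.

    Returns a dict with keys ``parental``, ``cohort``, ``phenotypes``
    (with pool labels), ``calls`` and ``parental_calls``.  All randomness
    derives from ``seed`` (falling back to ``config.seed``).
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_par, s_gen, s_phen, s_call = root.spawn(4)
    parental = build_parental_snps(config, np.random.default_rng(s_par))
    cohort = simulate_generations(config, np.random.default_rng(s_gen))
    phen = simulate_phenotypes(cohort, config, np.random.default_rng(s_phen))
    phen = select_extreme_pools(phen, config.pool_size)
    calls = genotype_cohort(cohort, parental, config, np.random.default_rng(s_call))
    return {
        "parental": parental,
        "cohort": cohort,
        "phenotypes": phen,
        "calls": calls,
        "parental_calls": parental_genotypes(parental),
    }
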