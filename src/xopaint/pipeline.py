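"""End-to-end analysis driver: VCF in, tracts/rates/association tables out.

Stages: informative-site QC -> per-fly painting -> density segmentation ->
crossover counting and per-meiosis rates with bootstrap CIs and exact
conditional tests -> pool association and region parentage fractions.
Every output embeds the config hash and seed so identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import io as io_mod
from . import painting as painting_mod
from . import xo_rates

logger = logging.getLogger("xopaint")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and analysis constants for one pipeline run."""

    vcf: str
    sample_sheet: str
    phenotypes: str
    outdir: str
    regions_bed: str | None = None  # None: segment from SNP density
    n_flies: int | None = None  # None: number of painted flies
    n_meioses: int = 5
    bootstrap_n: int = 10_000
    alpha: float = 0.05
    smooth_k: int = 3
    window: int = 100_000
    dense_threshold: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_meioses", "bootstrap_n", "smooth_k", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for name in ("vcf", "sample_sheet", "phenotypes"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} input not found: {path}")
        if self.regions_bed is not None and not Path(self.regions_bed).exists():
            raise FileNotFoundError(f"regions_bed input not found: {self.regions_bed}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # where results land must not change what they are
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle into ``config.outdir``.

    Returns a dict with the in-memory results: ``sites``, ``paintings``,
    ``regions``, ``counts``, ``rates``, ``association``, ``fractions``.
    """
    try:
        config.validate()
    except Exception as exc:
        raise PipelineError("configure", exc) from exc
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"xopaint config={config.config_hash()} seed={config.seed}"
    log_lines = [stamp]

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        roles = io_mod.read_sample_sheet(config.sample_sheet)
        data = io_mod.read_vcf(config.vcf, roles)
        phen = io_mod.read_phenotypes(config.phenotypes)
    except Exception as exc:
        raise PipelineError("read_inputs", exc) from exc

    try:
        sites = painting_mod.select_informative_sites(
            data.positions, data.parental_calls, data.n_hi, data.chrom_len
        )
        log(
            f"informative sites: {sites.n_sites}/{len(data.positions)} retained; "
            f"dropped het Hi={sites.qc['frac_dropped_het_hi']:.3f} "
            f"Lo={sites.qc['frac_dropped_het_lo']:.3f}"
        )
    except Exception as exc:
        raise PipelineError("select_informative_sites", exc) from exc

    try:
        site_idx = np.searchsorted(data.positions, sites.positions)
        paintings = [
            painting_mod.paint_fly(
                data.calls[i, site_idx], sites, fly_id=fly, smooth_k=config.smooth_k
            )
            for i, fly in enumerate(data.fly_ids)
        ]
        log(
            f"painted {len(paintings)} flies (smoothing k={config.smooth_k}, "
            "nearest-site ties to lower coordinate)"
        )
    except Exception as exc:
        raise PipelineError("paint", exc) from exc

    try:
        if config.regions_bed is not None:
            regions = io_mod.read_regions_bed(config.regions_bed)
        else:
            regions = xo_rates.segment_by_density(
                sites, config.window, config.dense_threshold
            )
        log(
            f"regions: {len(regions.dense())} dense, {len(regions.sparse())} sparse "
            f"(window={config.window}, threshold={config.dense_threshold}/10kb)"
        )
    except Exception as exc:
        raise PipelineError("segment", exc) from exc

    try:
        counts = xo_rates.crossover_table(paintings, regions)
        n_flies = config.n_flies if config.n_flies is not None else len(paintings)
        rates = xo_rates.rate_table(
            counts,
            regions,
            n_flies=n_flies,
            n_meioses=config.n_meioses,
            n_boot=config.bootstrap_n,
            seed=np.random.default_rng(config.seed),
        )
        log(
            f"rates over n_flies={n_flies}, n_meioses={config.n_meioses}, "
            f"bootstrap n={config.bootstrap_n}; exact conditional test "
            "two-sided by probability mass"
        )
    except Exception as exc:
        raise PipelineError("rates", exc) from exc

    try:
        phen_idx = phen.set_index("fly_id").reindex(data.fly_ids)
        pools = phen_idx["pool"] if "pool" in phen_idx else None
        if pools is None:
            raise ValueError("phenotype table lacks a 'pool' column")
        site_calls = data.calls[:, site_idx]
        association = assoc_mod.fisher_site_association(
            site_calls, sites.positions, pools.to_numpy(), alpha=config.alpha
        )
        fractions = assoc_mod.parentage_fractions(paintings, regions)
        fraction_tests = assoc_mod.compare_fractions(fractions, pools)
        log(
            f"association: {int(association['significant'].sum())} sites "
            f"below Bonferroni threshold "
            f"{association.attrs['bonferroni_threshold']:.3e}"
        )
    except Exception as exc:
        raise PipelineError("assoc", exc) from exc

    try:
        order = (
            phen_idx.sort_values("activity", ascending=False)
            .index.tolist()
        )
        io_mod.write_tracts_bed(
            outdir / "tracts.bed", paintings, chrom=data.chrom, header=stamp
        )
        io_mod.write_regions_bed(outdir / "regions.bed", regions, chrom=data.chrom)
        _write_tsv(outdir / "rates.tsv", rates.reset_index(), stamp)
        _write_tsv(outdir / "association.tsv", association, stamp)
        _write_tsv(outdir / "fractions.tsv", fractions.reset_index(), stamp)
        _write_tsv(
            outdir / "fraction_tests.tsv", fraction_tests.reset_index(), stamp
        )
        io_mod.write_label_matrix(outdir / "label_matrix.tsv", paintings, order)
        (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        raise PipelineError("write_outputs", exc) from exc

    return {
        "sites": sites,
        "paintings": paintings,
        "regions": regions,
        "counts": counts,
        "rates": rates,
        "association": association,
        "fractions": fractions,
        "fraction_tests": fraction_tests,
    }


def simulate_and_estimate_ratio(
    sim_config,
    seed: int,
    n_analysis: int = 84,
    smooth_k: int = 3,
    n_boot: int = 10_000,
    gap: tuple[str, str, str] = ("gap_CD", "C", "D"),
):
    """Simulate the breeding design and recover the sparse:dense rate ratio.

    Runs the generator at ``sim_config``, draws a random analysis cohort of
    ``n_analysis`` assayed males (the study's sequencing scale; an unbiased
    subsample, since under the additive region-fraction phenotype model the
    phenotypic extremes are depleted of crossovers in the causal regions),
    genotypes and paints them, counts crossovers per dense block plus the
    inferred-minimum count in the sparse gap between the two causal blocks,
    and returns ``(point_ratio, (ci_lo, ci_hi), counts)`` for the
    gap : pooled-flanking-dense per-Mb rate ratio with a fly-bootstrap CI.
    """
    from . import simkit

    gap_label, left_label, right_label = gap
    root = np.random.SeedSequence(seed)
    s_par, s_gen, _, s_call, s_sub, s_boot = root.spawn(6)
    parental = simkit.build_parental_snps(sim_config, np.random.default_rng(s_par))
    cohort = simkit.simulate_generations(sim_config, np.random.default_rng(s_gen))
    sub_rng = np.random.default_rng(s_sub)
    keep = sub_rng.choice(len(cohort), min(n_analysis, len(cohort)), replace=False)
    cohort = [cohort[i] for i in keep]
    calls = simkit.genotype_cohort(
        cohort, parental, sim_config, np.random.default_rng(s_call)
    )
    parental_calls = simkit.parental_genotypes(parental)
    sites = painting_mod.select_informative_sites(
        parental.positions, parental_calls, 3, sim_config.chrom_len
    )
    site_idx = np.searchsorted(parental.positions, sites.positions)
    paintings = [
        painting_mod.paint_fly(
            calls[i, site_idx], sites, fly_id=f"fly{i}", smooth_k=smooth_k
        )
        for i in range(len(cohort))
    ]
    regions = xo_rates.segment_by_density(sites)
    counts = xo_rates.crossover_table(paintings, regions)
    sub = counts[[left_label, right_label, gap_label]].dropna()
    dense_len = regions[left_label].length_mb + regions[right_label].length_mb
    point, ci = xo_rates.bootstrap_rate_ratio(
        sub[gap_label].to_numpy(),
        regions[gap_label].length_mb,
        (sub[left_label] + sub[right_label]).to_numpy(),
        dense_len,
        n_boot=n_boot,
        seed=np.random.default_rng(s_boot),
    )
    return point, ci, counts


def _write_tsv(path, df: pd.DataFrame, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{stamp}\n")
        df.to_csv(fh, sep="\t", index=False)
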