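"""End-to-end strain-discovery pipeline.

Composes the full inference chain on simulated (or user-supplied)
inputs: diagnostic-site generation -> pool pileups -> allele
frequencies -> sliding-window FST -> per-individual LD and the
co-segregation verdict -> pooled mixture estimate -> chromatogram
typing and cohort tables -> selection response u-test. Writes every
intermediate file, a JSON report and a human-readable markdown report
into the output directory, and logs each stage.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, bioassay, genotyping, io, linkage, popgen, simulate

logger = logging.getLogger("symbiostrain.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of a discovery run (simulation block + thresholds)."""

    n_scaffolds: int = 5
    scaffold_length: int = 50_000
    divergence_rate: float = 0.65
    resistant_depth: float = 96.0
    susceptible_depth: float = 40.0
    s_fraction: float = 0.47
    error_rate: float = 0.0
    n_individuals: int = 40
    window: int = 5_000
    step: int = 1_000
    min_depth: int = 10
    tau: float = 0.25
    r2_threshold: float = 0.33
    selection_survival: dict = field(
        default_factory=lambda: {"N": 0.5, "S": 0.25, "Mix": 0.35}
    )
    selection_generations: int = 3
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        if not 0 <= self.s_fraction <= 1:
            raise ValueError("s_fraction must be in [0, 1]")
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be > 0")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")


@dataclass
class DiscoveryReport:
    """Aggregated outputs of one discovery run."""

    fst_summary: dict
    cosegregation: dict
    mixture: dict
    cohorts: dict
    selection_test: dict
    n_diagnostic_sites: int
    snp_rate_per_100bp: float
    version: str
    config: dict

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_discovery(config: PipelineConfig, out_dir: str | Path) -> DiscoveryReport:
    """Run every stage of the strain-discovery analysis and write reports."""
    config.validate()
    out = io.ensure_dir(out_dir)
    _setup_logging(out / "run.log")
    seeds = _seeds(config.seed, 6)

    logger.info("stage simulate: generating two-strain data")
    pair = simulate.gen_strain_pair(
        simulate.StrainPairModel(
            n_scaffolds=config.n_scaffolds,
            scaffold_length=config.scaffold_length,
            divergence_rate=config.divergence_rate,
            seed=seeds[0],
        )
    )
    if len(pair.sites) == 0:
        raise RuntimeError("simulation produced no diagnostic sites")
    io.write_sites_tsv(pair.sites, out / "diagnostic_sites.tsv")
    io.write_sites_vcf(pair.sites, out / "diagnostic_sites.vcf")
    io.write_fasta(pair.n_haplotype, out / "n_haplotype.fasta")
    io.write_fasta(pair.s_haplotype, out / "s_haplotype.fasta")

    res_pileup = simulate.simulate_pool_pileup(
        pair.sites,
        simulate.PoolSpec(
            label="resistant",
            s_fraction=0.0,
            depth_mean=config.resistant_depth,
            error_rate=config.error_rate,
            seed=seeds[1],
        ),
    )
    sus_pileup = simulate.simulate_pool_pileup(
        pair.sites,
        simulate.PoolSpec(
            label="susceptible",
            s_fraction=config.s_fraction,
            depth_mean=config.susceptible_depth,
            error_rate=config.error_rate,
            seed=seeds[2],
        ),
    )
    io.write_pileup_tsv(res_pileup, out / "pileup_resistant.tsv")
    io.write_pileup_tsv(sus_pileup, out / "pileup_susceptible.tsv")

    logger.info("stage fst: allele frequencies and sliding windows")
    f_res = popgen.allele_frequencies(res_pileup, min_depth=config.min_depth)
    f_sus = popgen.allele_frequencies(sus_pileup, min_depth=config.min_depth)
    windows = popgen.window_fst(f_res, f_sus, window=config.window, step=config.step)
    io.write_windows_bed(windows, out / "fst_windows.bed", value_col="fst")
    if len(windows) == 0:
        # both pools fixed for the same allele at every site: FST is
        # undefined genome-wide, i.e. no differentiation signal at all
        logger.info("stage fst: no window with defined FST")
        summary = popgen.FstSummary(mean_fst=0.0, n_windows=0, band_fractions={})
    else:
        summary = popgen.fst_summary(windows)
    rate = popgen.snp_rate(pair.sites, pair.genome_length)

    logger.info("stage ld: per-individual haplotypes and co-segregation")
    class_probs = (1 - config.s_fraction, config.s_fraction, 0.0)
    individuals, hap, peaks = simulate.simulate_individuals(
        config.n_individuals, class_probs, pair.sites, seed=seeds[3]
    )
    chrom = hap.reshape(-1, hap.shape[2])  # chromosomes x sites
    ld = linkage.window_ld(
        pair.sites, chrom, window=config.window, step=config.step, phased=True
    )
    if len(ld) == 0:
        # monomorphic among sampled individuals: no LD evidence, no strain
        logger.info("stage ld: no polymorphic site pair; verdict false")
        verdict = linkage.CosegregationVerdict(
            single_strain=False,
            min_scaffold_median_r2=float("nan"),
            freq_sd=float("nan"),
            r2_threshold=config.r2_threshold,
            coherence_sd_max=float("nan"),
            n_scaffolds=0,
        )
    else:
        verdict = linkage.cosegregation_test(
            f_sus, ld, r2_threshold=config.r2_threshold
        )
        io.write_windows_bed(ld, out / "ld_windows.bed", value_col="mean_r2")

    logger.info("stage mixture: pooled-binomial S fraction")
    mixture = genotyping.estimate_mixture_fraction(sus_pileup, min_depth=config.min_depth)

    logger.info("stage typing: chromatogram calls and cohorts")
    frag_calls = genotyping.call_individuals(peaks, tau=config.tau)
    frag_calls.to_csv(out / "fragment_calls.csv", index=False)
    consensus = frag_calls.groupby("individual", sort=True)["consensus"].first()
    initial = genotyping.cohort_frequencies(consensus, label="initial")

    logger.info("stage selection: %d generations of class-specific survival",
                config.selection_generations)
    model = simulate.SelectionModel(
        survival=config.selection_survival,
        generations=config.selection_generations,
        pool_size=max(10 * config.n_individuals, 200),
    )
    traj = simulate.simulate_selection(list(consensus), model, seed=seeds[4])
    traj.to_csv(out / "selection_trajectory.csv", index=False)
    final = traj.iloc[-1]
    test = bioassay.two_proportion_u_test(
        initial.counts["S"], initial.n, int(final["n_S"]), int(final["n"])
    )

    report = DiscoveryReport(
        fst_summary=summary.to_dict(),
        cosegregation=verdict.to_dict(),
        mixture=mixture.to_dict(),
        cohorts={
            "initial": initial.to_dict(),
            "selected": {
                "n": int(final["n"]),
                "counts": {c: int(final[f"n_{c}"]) for c in simulate.STRAIN_CLASSES},
                "s_frequency": float(final["freq_S"]),
            },
        },
        selection_test=test.to_dict(),
        n_diagnostic_sites=len(pair.sites),
        snp_rate_per_100bp=rate,
        version=__version__,
        config=config.__dict__.copy(),
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)
    _write_markdown(report, out / "report.md")
    logger.info("discovery run complete: %s", out)
    return report


def _write_markdown(report: DiscoveryReport, path: Path) -> None:
    r = report
    lines = [
        "# Strain-discovery report",
        "",
        f"symbiostrain {r.version}",
        "",
        f"- Diagnostic sites: {r.n_diagnostic_sites} "
        f"({r.snp_rate_per_100bp:.3f} SNPs / 100 bp)",
        f"- Genome-wide mean window FST: {r.fst_summary['mean_fst']:.4f} "
        f"over {r.fst_summary['n_windows']} windows",
        f"- Single-strain verdict: {r.cosegregation['single_strain']} "
        f"(min scaffold median r2 = {r.cosegregation['min_scaffold_median_r2']:.3f}, "
        f"site-frequency sd = {r.cosegregation['freq_sd']:.4f})",
        f"- S-strain mixture fraction: {r.mixture['fraction']:.4f} "
        f"[{r.mixture['ci_low']:.4f}, {r.mixture['ci_high']:.4f}] "
        f"from {r.mixture['n_sites']} sites",
        f"- Initial cohort S frequency: {r.cohorts['initial']['s_frequency']:.2%} "
        f"(n = {r.cohorts['initial']['n']})",
        f"- Selected cohort S frequency: {r.cohorts['selected']['s_frequency']:.2%} "
        f"(n = {r.cohorts['selected']['n']})",
        f"- Selection u-test: z = {r.selection_test['z']:.3f}, "
        f"P = {r.selection_test['p_value']:.3g}",
        "",
    ]
    path.write_text("\n".join(lines))


def _setup_logging(log_path: Path) -> None:
    root = logging.getLogger("symbiostrain")
    root.setLevel(logging.INFO)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", None) == str(log_path)
        for h in root.handlers
    )
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    if not have_file:
        fh = logging.FileHandler(log_path)
        fh.setFormatter(fmt)
        root.addHandler(fh)
    if not any(
        isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
        for h in root.handlers
    ):
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(fmt)
        root.addHandler(sh)
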