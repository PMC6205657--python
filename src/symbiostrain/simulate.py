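"""Synthetic two-strain endosymbiont data generator.

Every downstream stage of the strain-discovery pipeline (pool allele
frequencies, windowed FST, linkage disequilibrium, chromatogram typing,
bioassay statistics) can be exercised on data produced here, with the
statistical structure the analysis assumes:

* two clonal symbiont haplotypes (N = resident/reference, S = novel)
  diverged at a fixed substitution rate, with no within-strain
  polymorphism — so every diagnostic SNP is a biallelic fixed difference
  and its pooled-read frequency equals the S-strain mixture fraction;
* pooled resequencing as independent Poisson depths and binomial allele
  sampling per site, with a symmetric per-base miscall rate;
* Sanger chromatogram peak heights proportional to per-individual strain
  titer share, with multiplicative noise;
* dose-dependent mortality under a log10-concentration probit model;
* multi-generation insecticide selection with carrier-class-specific
  survival.

All randomness flows through explicit integer seeds carried on the model
dataclasses; there is no module-level RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

BASES = np.array(["A", "C", "G", "T"])

STRAIN_CLASSES = ("N", "S", "Mix")

SITE_COLUMNS = ["scaffold", "pos", "n_allele", "s_allele", "gene_id"]
PILEUP_COLUMNS = ["scaffold", "pos", "depth", "s_count"]
PEAK_COLUMNS = ["individual", "fragment", "scaffold", "pos", "height_n", "height_s"]


@dataclass(frozen=True)
class StrainPairModel:
    """Parameters of the two-haplotype divergence model.

    ``divergence_rate`` is expressed as substitutions per 100 bp between
    the N and S haplotypes, matching how symbiont SNP density is usually
    summarised (the novel-strain regime in planthopper *Arsenophonus* is
    ~0.65/100 bp).
    """

    n_scaffolds: int = 1
    scaffold_length: int = 100_000
    divergence_rate: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        if self.scaffold_length < 1:
            raise ValueError("scaffold_length must be >= 1")
        if self.divergence_rate <= 0:
            raise ValueError("divergence_rate must be > 0")

    @property
    def expected_sites_per_scaffold(self) -> float:
        return self.scaffold_length * self.divergence_rate / 100.0


@dataclass(frozen=True)
class PoolSpec:
    """One pooled sequencing library of symbiont chromosomes.

    ``s_fraction`` is the proportion of symbiont chromosomes in the pool
    carrying the S haplotype; ``depth_mean`` the mean reads per site;
    ``error_rate`` the per-base miscall probability (a miscall flips the
    observed allele to the other diagnostic allele with probability e).
    """

    label: str = "pool"
    s_fraction: float = 0.0
    depth_mean: float = 40.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_fraction <= 1.0:
            raise ValueError("s_fraction must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class IndividualSpec:
    """Defaults for simulated host individuals.

    ``cryptic_fraction`` is the minor-strain titer share carried below
    the chromatogram detection limit by nominally pure individuals
    (0 by default; ~0.0859 reproduces the deep-sequencing scenario).
    ``noise_sd`` is the sd of the multiplicative peak-height noise.
    """

    cryptic_fraction: float = 0.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.cryptic_fraction < 0.5:
            raise ValueError("cryptic_fraction must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SelectionModel:
    """Carrier-class survival under repeated insecticide challenge."""

    survival: dict[str, float] = field(
        default_factory=lambda: {"N": 0.5, "S": 0.25, "Mix": 0.35}
    )
    generations: int = 3
    pool_size: int = 500

    def __post_init__(self) -> None:
        for cls in STRAIN_CLASSES:
            p = self.survival.get(cls)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValueError(f"survival[{cls!r}] must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


@dataclass
class StrainPair:
    """A simulated pair of clonal haplotypes plus their fixed differences.

    ``sites`` has columns scaffold, pos (1-based), n_allele, s_allele,
    gene_id; the N haplotype equals the reference sequence.
    """

    sites: pd.DataFrame
    n_haplotype: dict[str, str]
    s_haplotype: dict[str, str]
    model: StrainPairModel

    @property
    def reference(self) -> dict[str, str]:
        return self.n_haplotype

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.n_haplotype.values())


def gen_strain_pair(model: StrainPairModel) -> StrainPair:
    """Draw a reference genome and a diverged clonal S haplotype.

    The number of diagnostic sites per scaffold is
    Binomial(length, rate/100); sites are placed uniformly without
    replacement and sorted. Raises if the expected site count exceeds
    the scaffold length (divergence too high to place fixed differences).
    """
    per_site = model.divergence_rate / 100.0
    if per_site > 1.0:
        raise ValueError(
            "divergence_rate implies more diagnostic sites than positions: "
            f"{model.divergence_rate}/100 bp exceeds 1 per bp"
        )
    rng = np.random.default_rng(model.seed)
    rows = []
    n_hap: dict[str, str] = {}
    s_hap: dict[str, str] = {}
    for i in range(model.n_scaffolds):
        name = f"scaffold_{i + 1}"
        ref = rng.choice(BASES, size=model.scaffold_length)
        n_sites = rng.binomial(model.scaffold_length, per_site)
        positions = np.sort(
            rng.choice(model.scaffold_length, size=n_sites, replace=False)
        )
        alt = ref.copy()
        for p in positions:
            others = BASES[BASES != ref[p]]
            alt[p] = rng.choice(others)
            rows.append((name, int(p) + 1, ref[p], alt[p], ""))
        n_hap[name] = "".join(ref)
        s_hap[name] = "".join(alt)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return StrainPair(sites=sites, n_haplotype=n_hap, s_haplotype=s_hap, model=model)


def simulate_pool_pileup(sites: pd.DataFrame, spec: PoolSpec) -> pd.DataFrame:
    """Per-site read counts for a pooled library over the diagnostic sites.

    Depth ~ Poisson(depth_mean); the S-allele read count is
    Binomial(depth, p) with p = f(1-e) + (1-f)e, i.e. true mixture
    fraction pushed toward 0.5 by the symmetric miscall rate.
    """
    if len(sites) == 0:
        raise ValueError("sites table is empty")
    rng = np.random.default_rng(spec.seed)
    n = len(sites)
    depth = rng.poisson(spec.depth_mean, size=n)
    p = spec.s_fraction * (1 - spec.error_rate) + (1 - spec.s_fraction) * spec.error_rate
    s_count = rng.binomial(depth, p)
    return pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "depth": depth,
            "s_count": s_count,
        }
    )


def assign_fragments(sites: pd.DataFrame, n_fragments: int = 5) -> pd.DataFrame:
    """Group diagnostic sites into genotyping amplicons ("fragments").

    Sites are split into ``n_fragments`` contiguous blocks in genome
    order, emulating PCR fragments each covering a handful of SNPs.
    """
    out = sites.reset_index(drop=True).copy()
    idx = np.arange(len(out))
    out["fragment"] = 1 + (idx * n_fragments) // max(len(out), 1)
    return out


def simulate_individuals(
    n: int,
    class_probs: tuple[float, float, float],
    sites: pd.DataFrame,
    spec: IndividualSpec = IndividualSpec(),
    seed: int = 0,
    n_fragments: int = 5,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Simulate host individuals, their symbiont haplotype pairs, and peaks.

    Each individual carries two sampled symbiont chromosomes: N-class
    individuals carry (N, N), S-class (S, S) and Mix-class (N, S) — the
    clonality assumption means allele identity at one site determines all
    others on a chromosome. The titer composition (S share) is ~0, ~1 or
    0.5 respectively, shifted by the cryptic minor fraction for pure
    classes. Chromatogram peak heights at each diagnostic site are the
    titer shares times multiplicative noise ``1 + Normal(0, sd)``
    truncated at 0.

    Returns ``(individuals, haplotypes, peaks)``: a per-individual table
    (id, strain_class, composition), a ``(n, 2, n_sites)`` 0/1 array of
    S-allele indicators per chromosome copy, and the long-format peak
    table (individual, fragment, scaffold, pos, height_n, height_s).
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_probs must be non-negative and sum to 1")
    frag_sites = assign_fragments(sites, n_fragments=n_fragments)
    n_sites = len(frag_sites)
    if n == 0:
        empty = pd.DataFrame(columns=["individual", "strain_class", "composition"])
        return empty, np.zeros((0, 2, n_sites), dtype=int), pd.DataFrame(columns=PEAK_COLUMNS + ["fragment"])
    rng = np.random.default_rng(seed)
    classes = rng.choice(np.array(STRAIN_CLASSES), size=n, p=probs)
    comp = np.where(
        classes == "N",
        spec.cryptic_fraction,
        np.where(classes == "S", 1.0 - spec.cryptic_fraction, 0.5),
    )
    hap = np.zeros((n, 2, n_sites), dtype=int)
    hap[classes == "S"] = 1
    hap[classes == "Mix", 1, :] = 1

    individuals = pd.DataFrame(
        {
            "individual": [f"ind_{i + 1}" for i in range(n)],
            "strain_class": classes,
            "composition": comp,
        }
    )

    noise = lambda size: np.clip(1.0 + rng.normal(0.0, spec.noise_sd, size=size), 0.0, None)
    frames = []
    for i in range(n):
        hs = comp[i] * noise(n_sites)
        hn = (1.0 - comp[i]) * noise(n_sites)
        frames.append(
            pd.DataFrame(
                {
                    "individual": individuals["individual"].iloc[i],
                    "fragment": frag_sites["fragment"].to_numpy(),
                    "scaffold": frag_sites["scaffold"].to_numpy(),
                    "pos": frag_sites["pos"].to_numpy(),
                    "height_n": 100.0 * hn,
                    "height_s": 100.0 * hs,
                }
            )
        )
    peaks = pd.concat(frames, ignore_index=True)
    return individuals, hap, peaks


def simulate_dose_response(
    lc50: float,
    slope: float,
    doses: list[float],
    n_per_dose: int,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Dose-mortality table under a probit model.

    Deaths per replicate ~ Binomial(n, Phi(slope * (log10 d - log10 LC50))).
    Defaults mirror the standard planthopper stem-dip assay layout of
    triplicate cups of nymphs per concentration.
    """
    if lc50 <= 0 or slope <= 0:
        raise ValueError("lc50 and slope must be > 0")
    doses_arr = np.asarray(doses, dtype=float)
    if np.any(doses_arr <= 0):
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses_arr:
        p = norm.cdf(slope * (np.log10(d) - np.log10(lc50)))
        for rep in range(1, n_replicates + 1):
            dead = rng.binomial(n_per_dose, p)
            rows.append((d, rep, n_per_dose, dead))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "n", "dead"])


def expected_selection_frequencies(
    initial_freqs: dict[str, float], model: SelectionModel
) -> dict[str, float]:
    """Closed-form expected class frequencies after selection.

    Under deterministic selection the frequency of class c after g
    generations is f_c * s_c^g renormalised over classes.
    """
    w = {
        c: initial_freqs.get(c, 0.0) * model.survival[c] ** model.generations
        for c in STRAIN_CLASSES
    }
    total = sum(w.values())
    if total == 0:
        raise ValueError("all classes have zero expected survival")
    return {c: w[c] / total for c in STRAIN_CLASSES}


def simulate_selection(
    initial_classes: list[str] | np.ndarray,
    model: SelectionModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Stochastic multi-generation selection on strain-carrier classes.

    Each generation, individuals survive with their class's probability;
    survivors reproduce to refill the pool, offspring classes drawn
    multinomially at the survivor class proportions (maternal
    transmission of the symbiont composition). Returns per-generation
    counts and frequencies, generation 0 being the initial cohort.
    Raises if every class goes extinct, reporting the generation.
    """
    classes = np.asarray(initial_classes)
    if classes.size == 0:
        raise ValueError("initial cohort is empty")
    rng = np.random.default_rng(seed)
    counts = {c: int(np.sum(classes == c)) for c in STRAIN_CLASSES}
    rows = [_selection_row(0, counts)]
    for g in range(1, model.generations + 1):
        survivors = {
            c: rng.binomial(counts[c], model.survival[c]) for c in STRAIN_CLASSES
        }
        n_surv = sum(survivors.values())
        if n_surv == 0:
            raise RuntimeError(f"all carrier classes extinct at generation {g}")
        props = np.array([survivors[c] / n_surv for c in STRAIN_CLASSES])
        drawn = rng.multinomial(model.pool_size, props)
        counts = dict(zip(STRAIN_CLASSES, (int(x) for x in drawn)))
        rows.append(_selection_row(g, counts))
    return pd.DataFrame(rows)


def _selection_row(generation: int, counts: dict[str, int]) -> dict:
    n = sum(counts.values())
    row = {"generation": generation, "n": n}
    for c in STRAIN_CLASSES:
        row[f"n_{c}"] = counts[c]
        row[f"freq_{c}"] = counts[c] / n if n else float("nan")
    return row
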