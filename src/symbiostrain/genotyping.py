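"""Strain typing: mixture fractions, chromatogram calls, cohort tables.

Two complementary views of a host's symbiont composition:

* **Read counts** — at diagnostic sites the pooled S-allele read
  fraction is a binomial estimate of the S-strain titer share; pooling
  counts across sites gives the MLE f-hat = sum(s_count) / sum(depth)
  with a Wilson score interval (which behaves sensibly near 0, the
  regime of cryptic low-titer co-infection, e.g. the ~8.59% minor strain
  detectable only by deep sequencing).
* **Sanger chromatogram peaks** — a secondary peak whose height relative
  to the major one reaches a threshold tau marks both alleles present
  (Mix); otherwise the call is the major peak's strain. Per-site calls
  are combined by majority vote, with any N/S discordance resolved as
  Mix (under clonal strains, conflicting dominant calls at different
  sites imply genuine co-infection).

The clonality expectation is checked by cross-amplicon consistency:
for one individual, every genotyping fragment must give the same call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

DEFAULT_TAU = 0.25
CALLS = ("N", "S", "Mix")


@dataclass
class MixtureEstimate:
    """Pooled-binomial estimate of the S-strain fraction with 95% CI."""

    fraction: float
    ci_low: float
    ci_high: float
    n_sites: int
    total_depth: int
    total_s: int
    site_freqs: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_sites": self.n_sites,
            "total_depth": self.total_depth,
            "total_s": self.total_s,
        }


def estimate_mixture_fraction(
    pileup: pd.DataFrame, min_depth: int = 10, alpha: float = 0.05
) -> MixtureEstimate:
    """S-strain fraction from read counts at diagnostic sites.

    f-hat = sum(s_count)/sum(depth) over sites passing the depth filter;
    the CI is the Wilson score interval on the pooled counts. Per-site
    frequencies are kept for heterogeneity inspection.
    """
    ok = pileup["depth"].to_numpy() >= min_depth
    if not ok.any():
        raise ValueError(f"no site passes min_depth={min_depth}")
    sub = pileup.loc[ok].copy()
    total_depth = int(sub["depth"].sum())
    total_s = int(sub["s_count"].sum())
    f_hat = total_s / total_depth
    lo, hi = proportion_confint(total_s, total_depth, alpha=alpha, method="wilson")
    sub["freq"] = sub["s_count"] / sub["depth"]
    return MixtureEstimate(
        fraction=float(f_hat),
        ci_low=float(lo),
        ci_high=float(hi),
        n_sites=int(ok.sum()),
        total_depth=total_depth,
        total_s=total_s,
        site_freqs=sub,
    )


def classify_site(height_n: float, height_s: float, tau: float = DEFAULT_TAU) -> str:
    """Per-site chromatogram call from the two diagnostic peak heights.

    The minor/major height ratio at or above ``tau`` calls Mix
    (boundary inclusive); below it the call is the major peak's strain.
    Both peaks absent gives "no-call". The rule is scale-invariant.
    """
    if height_n < 0 or height_s < 0:
        raise ValueError("peak heights must be >= 0")
    if height_n == 0 and height_s == 0:
        return "no-call"
    major, minor = max(height_n, height_s), min(height_n, height_s)
    if minor / major >= tau:
        return "Mix"
    return "N" if height_n > height_s else "S"


@dataclass
class ChromatogramCall:
    """Consensus strain type for one individual (or one amplicon)."""

    individual: str
    consensus: str
    site_calls: list[str]
    n_discordant: int
    tau: float


def consensus_call(
    site_calls: list[str], individual: str = "", tau: float = DEFAULT_TAU
) -> ChromatogramCall:
    """Majority vote over per-site calls, co-infection-aware.

    No-calls are ignored. If both dominant classes (N and S) appear the
    consensus is Mix regardless of counts — clonal haplotypes cannot
    give genuinely discordant dominant alleles. Otherwise the majority
    of {dominant class, Mix} wins, ties going to Mix. The discordance
    count is the number of called sites disagreeing with the consensus.
    """
    called = [c for c in site_calls if c in CALLS]
    if not called:
        raise ValueError("all sites are no-call")
    counts = Counter(called)
    if counts["N"] > 0 and counts["S"] > 0:
        consensus = "Mix"
    else:
        dominant = "N" if counts["N"] > 0 else "S"
        consensus = dominant if counts[dominant] > counts["Mix"] else "Mix"
        if counts[dominant] == 0:
            consensus = "Mix"
    n_disc = sum(1 for c in called if c != consensus)
    return ChromatogramCall(
        individual=individual,
        consensus=consensus,
        site_calls=list(site_calls),
        n_discordant=n_disc,
        tau=tau,
    )


def call_individuals(peaks: pd.DataFrame, tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Fragment-level and consensus calls for every individual.

    ``peaks`` is long-format (individual, fragment, scaffold, pos,
    height_n, height_s). Returns one row per (individual, fragment) with
    the fragment call, plus a ``consensus`` column repeating the
    individual-level call derived from the fragment calls.
    """
    rows = []
    for (ind, frag), grp in peaks.groupby(["individual", "fragment"], sort=True):
        calls = [
            classify_site(hn, hs, tau=tau)
            for hn, hs in zip(grp["height_n"], grp["height_s"])
        ]
        cc = consensus_call(calls, individual=str(ind), tau=tau)
        rows.append((ind, frag, cc.consensus, cc.n_discordant, len(calls)))
    frag_df = pd.DataFrame(
        rows, columns=["individual", "fragment", "call", "n_discordant", "n_sites"]
    )
    cons = {
        ind: consensus_call(list(grp["call"]), individual=str(ind), tau=tau).consensus
        for ind, grp in frag_df.groupby("individual", sort=True)
    }
    frag_df["consensus"] = frag_df["individual"].map(cons)
    return frag_df


@dataclass
class ConsistencyReport:
    """Cross-amplicon agreement: the clonality check."""

    rate: float
    n_individuals: int
    discordant: list[str]


def amplicon_consistency(fragment_calls: pd.DataFrame) -> ConsistencyReport:
    """Fraction of individuals whose genotyping fragments all agree.

    Under two clonal strains, detecting the novel allele at one site
    implies it at all others, so every fragment of an individual must
    yield the same call; individuals violating this are listed.
    Individuals with fewer than two fragments are excluded.
    """
    disc = []
    n = 0
    for ind, grp in fragment_calls.groupby("individual", sort=True):
        if grp["fragment"].nunique() < 2:
            continue
        n += 1
        if grp["call"].nunique() > 1:
            disc.append(str(ind))
    rate = 1.0 if n == 0 else (n - len(disc)) / n
    return ConsistencyReport(rate=float(rate), n_individuals=n, discordant=disc)


@dataclass
class CohortCount:
    """Strain-type composition of one cohort of individuals."""

    label: str
    n: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    s_frequency: float          # S-type only
    s_or_mix_frequency: float   # S counted together with Mix

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "counts": self.counts,
            "frequencies": self.frequencies,
            "s_frequency": self.s_frequency,
            "s_or_mix_frequency": self.s_or_mix_frequency,
        }


def cohort_frequencies(consensus_calls: list[str] | pd.Series, label: str = "") -> CohortCount:
    """Counts and frequencies of N/S/Mix consensus types in a cohort.

    Both tabulations of the S burden are emitted: strict S-type
    frequency and S-or-Mix frequency (it is often ambiguous whether
    population surveys count even co-infections with the novel strain).
    """
    calls = list(consensus_calls)
    if not calls:
        raise ValueError("empty cohort")
    n = len(calls)
    counts = {c: calls.count(c) for c in CALLS}
    freqs = {c: counts[c] / n for c in CALLS}
    return CohortCount(
        label=label,
        n=n,
        counts=counts,
        frequencies=freqs,
        s_frequency=freqs["S"],
        s_or_mix_frequency=freqs["S"] + freqs["Mix"],
    )
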