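"""Linkage disequilibrium of strain-diagnostic SNPs.

If all polymorphism in a symbiont population comes from a mixture of two
clonal haplotypes, every pair of diagnostic sites is in complete LD
(r^2 = 1) and every site segregates at the same frequency (the strain
mixture fraction). This module quantifies both signatures — pairwise
r^2 = D^2 / (pA pa pB pb) in 5-kb sliding windows, and the coherence of
per-site pool frequencies — and combines them into a single-strain
verdict.

LD is computed from per-individual data: phased haplotypes when known
(each simulated chromosome copy), or unphased two-site genotypes via EM
estimation of haplotype frequencies (the classical ambiguity being the
double heterozygote). The EM route equals the phased computation
whenever phase is actually known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_R2_THRESHOLD = 0.33
EM_MAX_ITER = 50
EM_TOL = 1e-8


def haplotype_r2(h_i: np.ndarray, h_j: np.ndarray) -> float:
    """r^2 between two sites from phased 0/1 haplotype vectors.

    Entries are S-allele indicators per chromosome; NaN marks missing.
    Returns NaN for monomorphic sites or < 2 informative chromosomes.
    """
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    ok = ~(np.isnan(h_i) | np.isnan(h_j))
    if ok.sum() < 2:
        return float("nan")
    x, y = h_i[ok], h_j[ok]
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = np.mean(x * y) - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def em_haplotype_freqs(g_i: np.ndarray, g_j: np.ndarray) -> np.ndarray:
    """EM haplotype-frequency estimates from unphased two-site genotypes.

    ``g_i``/``g_j`` count S alleles per individual (0/1/2; NaN missing).
    Only the double heterozygote (1, 1) is phase-ambiguous; EM splits it
    between coupling (NN/SS) and repulsion (NS/SN) resolutions by the
    current haplotype frequencies. Initialised at linkage equilibrium;
    deterministic; returns frequencies in order (NN, NS, SN, SS) where
    the letters are the alleles at site i and j.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    ok = ~(np.isnan(g_i) | np.isnan(g_j))
    gi, gj = g_i[ok].astype(int), g_j[ok].astype(int)
    n = gi.size
    if n < 2:
        return np.full(4, np.nan)
    n_chrom = 2 * n
    pa = gi.sum() / n_chrom  # S-allele freq at site i
    pb = gj.sum() / n_chrom
    # haplotype order: index 0 = N_i N_j, 1 = N_i S_j, 2 = S_i N_j, 3 = S_i S_j
    f = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])
    dh = int(np.sum((gi == 1) & (gj == 1)))  # double heterozygotes
    # unambiguous haplotype counts from all other genotype combinations
    base = np.zeros(4)
    for a in range(3):
        for b in range(3):
            if a == 1 and b == 1:
                continue
            m = int(np.sum((gi == a) & (gj == b)))
            if m == 0:
                continue
            # each individual contributes two chromosomes with known phase
            hap_s_i = [1] * a + [0] * (2 - a)
            hap_s_j = [1] * b + [0] * (2 - b)
            for si, sj in zip(sorted(hap_s_i, reverse=True), sorted(hap_s_j, reverse=True)):
                base[2 * si + sj] += m
    for _ in range(EM_MAX_ITER):
        denom = f[0] * f[3] + f[1] * f[2]
        coupling = 0.5 if denom == 0 else f[0] * f[3] / denom
        counts = base.copy()
        counts[0] += dh * coupling
        counts[3] += dh * coupling
        counts[1] += dh * (1 - coupling)
        counts[2] += dh * (1 - coupling)
        f_new = counts / n_chrom
        if np.abs(f_new - f).max() < EM_TOL:
            f = f_new
            break
        f = f_new
    return f


def genotype_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """r^2 from unphased genotypes via EM haplotype frequencies."""
    f = em_haplotype_freqs(g_i, g_j)
    if np.any(np.isnan(f)):
        return float("nan")
    pa = f[2] + f[3]
    pb = f[1] + f[3]
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = f[3] - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _pairwise_r2_matrix(data: np.ndarray, phased: bool) -> np.ndarray:
    """Dense r^2 matrix over sites; vectorised for phased 0/1 data."""
    n_sites = data.shape[1]
    if phased:
        x = data.astype(float)
        p = x.mean(axis=0)
        poly = (p > 0) & (p < 1)
        c = np.cov(x, rowvar=False, bias=True)
        var = np.diag(c).copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = c**2 / np.outer(var, var)
        r2[~poly, :] = np.nan
        r2[:, ~poly] = np.nan
        return r2
    r2 = np.full((n_sites, n_sites), np.nan)
    for i in range(n_sites):
        r2[i, i] = 1.0
        for j in range(i + 1, n_sites):
            v = genotype_r2(data[:, i], data[:, j])
            r2[i, j] = r2[j, i] = v
    return r2


def window_ld(
    sites: pd.DataFrame,
    data: np.ndarray,
    window: int = 5_000,
    step: int = 1_000,
    phased: bool = True,
) -> pd.DataFrame:
    """Mean pairwise r^2 in sliding windows along each scaffold.

    ``sites`` carries scaffold and 1-based pos for each column of
    ``data`` (chromosomes x sites if phased, individuals x sites of 0/1/2
    genotypes otherwise). Windows with fewer than two sites, or no
    defined pair, are omitted.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    rows = []
    for scaf in sorted(sites["scaffold"].unique()):
        mask = (sites["scaffold"] == scaf).to_numpy()
        pos0 = sites["pos"].to_numpy()[mask] - 1
        sub = data[:, mask]
        r2 = _pairwise_r2_matrix(sub, phased=phased)
        length = int(pos0.max()) + 1
        starts = np.arange(0, max(length - window, 0) + step, step)
        if length <= window:
            starts = np.array([0])
        for start in starts:
            in_w = np.flatnonzero((pos0 >= start) & (pos0 < start + window))
            if in_w.size < 2:
                continue
            block = r2[np.ix_(in_w, in_w)]
            iu = np.triu_indices(in_w.size, k=1)
            vals = block[iu]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            rows.append(
                (scaf, int(start), int(start + window), int(vals.size), float(vals.mean()))
            )
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_pairs", "mean_r2"])


def scaffold_r2(sites: pd.DataFrame, data: np.ndarray, phased: bool = True) -> pd.DataFrame:
    """Mean and median pairwise r^2 per scaffold (all within-scaffold pairs)."""
    rows = []
    for scaf in sorted(sites["scaffold"].unique()):
        mask = (sites["scaffold"] == scaf).to_numpy()
        sub = data[:, mask]
        r2 = _pairwise_r2_matrix(sub, phased=phased)
        iu = np.triu_indices(r2.shape[0], k=1)
        vals = r2[iu]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        rows.append((scaf, int(vals.size), float(vals.mean()), float(np.median(vals))))
    return pd.DataFrame(rows, columns=["scaffold", "n_pairs", "mean_r2", "median_r2"])


@dataclass
class CosegregationVerdict:
    """Decision on whether diagnostic SNPs behave as one coherent strain."""

    single_strain: bool
    min_scaffold_median_r2: float
    freq_sd: float
    r2_threshold: float
    coherence_sd_max: float
    n_scaffolds: int

    def to_dict(self) -> dict:
        return {
            "single_strain": self.single_strain,
            "min_scaffold_median_r2": self.min_scaffold_median_r2,
            "freq_sd": self.freq_sd,
            "r2_threshold": self.r2_threshold,
            "coherence_sd_max": self.coherence_sd_max,
            "n_scaffolds": self.n_scaffolds,
        }


def cosegregation_test(
    freqs: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    coherence_sd_max: float | None = None,
) -> CosegregationVerdict:
    """Combine LD and frequency coherence into a single-strain verdict.

    True iff (a) every scaffold's median window mean-r^2 meets
    ``r2_threshold`` and (b) the sd of diagnostic-site pool frequencies
    does not exceed ``coherence_sd_max`` — a coherent mixture shares one
    frequency (the strain fraction) across all sites, so the observed
    spread should be explained by read-sampling noise alone. The default
    tolerance is twice the binomial sd implied by the median depth.
    """
    if len(ld) == 0:
        raise ValueError("no scaffold with at least two diagnostic sites")
    passing = freqs[freqs["passed"]] if "passed" in freqs else freqs
    p = passing["freq"].to_numpy(dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no passing site frequencies")
    freq_sd = float(p.std(ddof=1)) if p.size > 1 else 0.0
    if coherence_sd_max is None:
        med_depth = float(np.median(passing["depth"].to_numpy(dtype=float)))
        pbar = float(np.clip(p.mean(), 1e-6, 1 - 1e-6))
        coherence_sd_max = 2.0 * float(np.sqrt(pbar * (1 - pbar) / med_depth))
    med = ld.groupby("scaffold")["mean_r2"].median()
    min_median = float(med.min())
    verdict = (min_median >= r2_threshold) and (freq_sd <= coherence_sd_max)
    return CosegregationVerdict(
        single_strain=bool(verdict),
        min_scaffold_median_r2=min_median,
        freq_sd=freq_sd,
        r2_threshold=r2_threshold,
        coherence_sd_max=float(coherence_sd_max),
        n_scaffolds=int(med.size),
    )
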