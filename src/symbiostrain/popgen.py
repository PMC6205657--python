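"""Pool-seq allele frequencies and sliding-window FST.

Works from per-site read counts of two pooled libraries (e.g. an
insecticide-resistant and a susceptible host pool). The default FST
estimator is the Hudson form on pool allele frequencies,

    1 - Hw/Hb,  Hw = (2 p1 q1 + 2 p2 q2) / 2,  Hb = p1 q2 + p2 q1,

aggregated over windows as a ratio of averages (sum of per-site
numerators over sum of per-site denominators), which is the recommended
way to combine multi-site FST. A Weir & Cockerham variant that accounts
for the (haploid) sample sizes behind each frequency is available for
comparison.

Key identity used throughout: if pool 1 is fixed (p1 = 0) and pool 2
segregates at frequency f, Hudson FST equals f exactly — a coherent
two-strain mixture at fraction f therefore shows genome-wide FST ~ f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 5_000
DEFAULT_STEP = 1_000
DEFAULT_MIN_DEPTH = 10
ZERO_BAND_TOL = 0.005


def allele_frequencies(pileup: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-site S-allele frequencies with a depth filter.

    Adds ``freq`` (s_count/depth, NaN where failed) and boolean
    ``passed`` columns. Sites with depth < min_depth carry no frequency.
    """
    out = pileup.copy()
    depth = out["depth"].to_numpy(dtype=float)
    passed = depth >= min_depth
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(passed, out["s_count"].to_numpy(dtype=float) / depth, np.nan)
    out["freq"] = freq
    out["passed"] = passed
    if not passed.any():
        logger.warning("no site passes the depth filter (min_depth=%d)", min_depth)
    return out


def hudson_components(p1, p2):
    """Per-site Hudson numerator (Hb - Hw) and denominator (Hb)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    hw = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    return hb - hw, hb


def wc_components(p1, p2, n1, n2):
    """Weir & Cockerham (haploid samples) per-site variance components.

    ``n1``/``n2`` are the numbers of sampled chromosomes (pool depths).
    Returns (a, a + b) so windows combine as ratio of averages. Per-site
    estimates can be negative; they are kept in sums.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    n = n1 + n2
    nbar = n / 2.0
    nc = (n - (n1**2 + n2**2) / n)  # over (r-1)=1
    pbar = (n1 * p1 + n2 * p2) / n
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # over (r-1)=1
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0)
    return a, a + b


def site_fst(p1: float, p2: float) -> float:
    """Hudson FST for one frequency pair; NaN when both pools are fixed
    for the same allele (between-pool heterozygosity zero)."""
    num, den = hudson_components(p1, p2)
    if np.ndim(den) == 0:
        return float(num / den) if den > 0 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _windows_for(length: int, window: int, step: int):
    starts = np.arange(0, max(length - window, 0) + step, step)
    if length <= window:
        starts = np.array([0])
    return [(int(s), int(min(s + window, max(length, s + window)))) for s in starts]


def window_fst(
    freqs1: pd.DataFrame,
    freqs2: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    method: str = "hudson",
    scaffold_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window FST between two pools over matched site tables.

    The two frequency tables must cover the same (scaffold, pos) sites
    in the same order (as produced by :func:`allele_frequencies` on
    pileups of the same diagnostic-site table). Windows are half-open,
    0-based internally (length ``window``, advancing by ``step``);
    per-window FST is the ratio of summed per-site numerators to summed
    denominators over passing sites. Windows containing no usable site
    are omitted (their count is logged).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    if len(freqs1) != len(freqs2) or not (
        freqs1["pos"].to_numpy() == freqs2["pos"].to_numpy()
    ).all():
        raise ValueError("frequency tables must cover identical sites")
    ok = (
        freqs1["passed"].to_numpy()
        & freqs2["passed"].to_numpy()
    )
    p1 = freqs1["freq"].to_numpy(dtype=float)
    p2 = freqs2["freq"].to_numpy(dtype=float)
    if method == "hudson":
        num, den = hudson_components(p1, p2)
    elif method == "wc":
        num, den = wc_components(
            p1, p2, freqs1["depth"].to_numpy(), freqs2["depth"].to_numpy()
        )
    else:
        raise ValueError(f"unknown FST method: {method!r}")
    usable = ok & (den != 0) & np.isfinite(den)
    rows = []
    n_empty = 0
    for scaf in sorted(freqs1["scaffold"].unique()):
        mask = (freqs1["scaffold"] == scaf).to_numpy()
        pos0 = freqs1["pos"].to_numpy()[mask] - 1  # to 0-based
        s_num, s_den, s_ok = num[mask], den[mask], usable[mask]
        length = (
            scaffold_lengths.get(scaf) if scaffold_lengths else int(pos0.max()) + 1
        )
        for start, end in _windows_for(length, window, step):
            in_w = (pos0 >= start) & (pos0 < end) & s_ok
            n_sites = int(in_w.sum())
            if n_sites == 0:
                n_empty += 1
                continue
            d = s_den[in_w].sum()
            if d == 0:
                n_empty += 1
                continue
            rows.append((scaf, start, end, n_sites, float(s_num[in_w].sum() / d)))
    if n_empty:
        logger.info("omitted %d windows with no usable site", n_empty)
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_sites", "fst"])


@dataclass
class FstSummary:
    """Genome-wide FST summary: mean over windows plus band fractions."""

    mean_fst: float
    n_windows: int
    band_fractions: dict[str, float] = field(default_factory=dict)
    zero_tolerance: float = ZERO_BAND_TOL

    def to_dict(self) -> dict:
        return {
            "mean_fst": self.mean_fst,
            "n_windows": self.n_windows,
            "band_fractions": self.band_fractions,
            "zero_tolerance": self.zero_tolerance,
        }


def fst_summary(
    windows: pd.DataFrame,
    low_band: tuple[float, float] = (0.01, 0.30),
    zero_tolerance: float = ZERO_BAND_TOL,
) -> FstSummary:
    """Mean window FST and the fraction of windows per differentiation band.

    Default bands mirror how disproportionate genome-wide differentiation
    is usually reported: a "no difference" band (|FST| below a small
    tolerance), an intermediate band, and the remainder (strongly
    differentiated windows). Fractions sum to 1 over reported windows.
    Negative window estimates are clamped to 0 for banding only.
    """
    if len(windows) == 0:
        raise ValueError("no windows to summarise")
    vals = windows["fst"].to_numpy(dtype=float)
    clamped = np.clip(vals, 0.0, 1.0)
    zero = np.abs(vals) < zero_tolerance
    low = (~zero) & (clamped >= low_band[0]) & (clamped <= low_band[1])
    rest = ~(zero | low)
    n = len(vals)
    bands = {
        "no_difference": float(zero.sum() / n),
        f"[{low_band[0]},{low_band[1]}]": float(low.sum() / n),
        "remainder": float(rest.sum() / n),
    }
    return FstSummary(
        mean_fst=float(vals.mean()),
        n_windows=n,
        band_fractions=bands,
        zero_tolerance=zero_tolerance,
    )


def snp_rate(n_sites: int | pd.DataFrame, genome_length: int) -> float:
    """SNPs per 100 bp: 100 * n_sites / genome_length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if isinstance(n_sites, pd.DataFrame):
        n_sites = len(n_sites)
    return 100.0 * n_sites / genome_length
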