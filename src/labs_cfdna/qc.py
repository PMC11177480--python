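"""Library-complexity and coverage quality metrics.

Metrics that benchmark a low-input bisulfite library: duplication rate
(fraction of reads that repeat an already-seen molecule or coordinate key),
saturation curves of distinct molecules/CpGs versus subsampled depth,
covered-fraction summaries, GC-stratified coverage bias, Lorenz/Gini
coverage uniformity, and inter-sample correlation of per-site methylation
proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError


def read_keys(reads: pd.DataFrame) -> np.ndarray:
    """Coordinate deduplication keys (chrom, start0, end0, strand) for a
    BED-like read frame; the synthetic amplification simulator's molecule
    identifiers are the ground-truth analogue."""
    cols = [c for c in ("chrom", "start0", "end0", "strand") if c in reads.columns]
    if not cols:
        raise ValidationError("read frame has no key columns")
    keys = reads[cols].astype(str).agg("|".join, axis=1).to_numpy()
    return keys


def duplication_rate(keys) -> float:
    """Fraction of reads sharing a key with an earlier read:
    ``(n_reads - n_distinct) / n_reads``."""
    arr = np.asarray(keys)
    if arr.size == 0:
        raise ParameterError("duplication rate of zero reads is undefined")
    return float((arr.size - np.unique(arr).size) / arr.size)


def saturation_curve(keys, depths, seed: int = 0) -> pd.DataFrame:
    """Distinct keys observed when subsampling reads without replacement.

    Returns a frame with columns ``depth, distinct``; the curve is
    nondecreasing in depth and ``distinct <= depth`` everywhere.
    """
    arr = np.asarray(keys)
    depths = np.asarray(depths, dtype=np.int64)
    if (depths > arr.size).any():
        raise ParameterError("subsampling depth exceeds the number of reads")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(arr)  # one permutation: nested subsamples, monotone curve
    rows = []
    for d in np.sort(depths):
        rows.append((int(d), int(np.unique(perm[:d]).size)))
    return pd.DataFrame(rows, columns=["depth", "distinct"])


def expected_distinct(n_molecules: int, depth: int) -> float:
    """Closed-form expectation of distinct molecules after ``depth`` uniform
    draws with replacement from ``n_molecules``: ``M (1 - (1 - 1/M)^D)``."""
    m = float(n_molecules)
    return m * (1.0 - (1.0 - 1.0 / m) ** depth)


def coverage_summary(calls: pd.DataFrame, site_universe: pd.DataFrame, thresholds=(1, 3)) -> dict[int, float]:
    """Fraction of the assayable site universe covered at each threshold.

    ``site_universe`` lists all assayable CpGs (chrom, pos0).  Coverage of a
    site is ``n_meth + n_unmeth``.
    """
    if len(site_universe) == 0:
        raise ParameterError("empty site universe")
    universe = pd.MultiIndex.from_frame(site_universe[["chrom", "pos0"]])
    cov = (
        calls.assign(cov=calls["n_meth"] + calls["n_unmeth"])
        .groupby(["chrom", "pos0"])["cov"]
        .sum()
    )
    cov = cov.reindex(universe, fill_value=0)
    return {int(t): float((cov >= t).mean()) for t in thresholds}


def gc_bias_profile(bin_counts: pd.DataFrame, bin_gc, width: float = 0.05) -> pd.Series:
    """Mean bin count per GC stratum divided by the global mean count.

    Strata are ``width``-sized GC buckets (5% by default); empty strata are
    absent from the result.  A flat profile near 1.0 indicates unbiased
    coverage even at extreme GC.
    """
    gc = np.asarray(bin_gc, dtype=float)
    if ((gc < 0) | (gc > 1)).any():
        raise ParameterError("GC fractions must lie in [0, 1]")
    counts = bin_counts["count"].to_numpy(np.float64)
    global_mean = counts.mean()
    if global_mean == 0:
        raise ValidationError("all bin counts are zero")
    n_buckets = int(round(1 / width))
    strata = np.minimum((gc / width).astype(int), n_buckets - 1)
    out = {}
    for s in np.unique(strata):
        sel = strata == s
        out[round(s * width, 10)] = float(counts[sel].mean() / global_mean)
    return pd.Series(out, name="normalized_coverage")


def lorenz_curve(counts) -> pd.DataFrame:
    """Cumulative coverage share versus cumulative bin share (bins sorted by
    count).  Perfectly uniform coverage gives the diagonal."""
    c = np.sort(np.asarray(counts, dtype=np.float64))
    if c.sum() == 0:
        raise ValidationError("all counts are zero")
    cum_bins = np.arange(1, c.size + 1) / c.size
    cum_reads = np.cumsum(c) / c.sum()
    return pd.DataFrame({"cum_bins": cum_bins, "cum_reads": cum_reads})


def gini_coefficient(counts) -> float:
    """Gini coefficient of the coverage distribution (0 = perfectly uniform)."""
    c = np.sort(np.asarray(counts, dtype=np.float64))
    n = c.size
    total = c.sum()
    if total == 0:
        raise ValidationError("all counts are zero")
    index = np.arange(1, n + 1)
    return float((2 * (index * c).sum() / (n * total)) - (n + 1) / n)


def sample_correlation(calls_a: pd.DataFrame, calls_b: pd.DataFrame, min_coverage: int = 3) -> float:
    """Pearson correlation of per-site methylation proportions between two
    samples over sites covered at ``min_coverage`` in both."""
    def _props(calls):
        cov = calls["n_meth"] + calls["n_unmeth"]
        sub = calls[cov >= min_coverage]
        return pd.Series(
            (sub["n_meth"] / (sub["n_meth"] + sub["n_unmeth"])).to_numpy(),
            index=pd.MultiIndex.from_frame(sub[["chrom", "pos0", "strand"]]),
        )

    a, b = _props(calls_a), _props(calls_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValidationError(f"only {len(shared)} shared sites at >= {min_coverage}x")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("a sample has constant methylation at shared sites")
    return float(np.corrcoef(x, y)[0, 1])
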