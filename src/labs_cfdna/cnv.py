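"""Copy-number alteration detection from binned fragment counts.

Fragment counts in fixed-size genomic bins (100 kb by default) are compared
against a *panel of normals*: counts from all normal samples pooled into a
single synthetic control whose per-bin proportions serve as the expected
read distribution of a copy-neutral genome.  A sample's per-bin log2 copy
ratio is

    log2( (count_b / total) / panel_proportion_b )

which is 0 for a neutral bin, positive under gain and negative under loss.
Segments of shifted mean ratio are found by recursive binary segmentation
and called gain/loss against a ratio threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .methylome import REGION_COLUMNS


def bin_genome(genome: Mapping[str, int] | Sequence[tuple[str, int]], size: int = 100_000) -> pd.DataFrame:
    """Non-overlapping bins of ``size`` bp; the final partial bin is retained."""
    if size < 1:
        raise ParameterError("bin size must be >= 1")
    items = genome.items() if isinstance(genome, Mapping) else genome
    rows = []
    for chrom, length in items:
        edges = list(range(0, length, size)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((chrom, s, e, f"{chrom}:{s}-{e}", "."))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def count_fragments_in_bins(fragments: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Assign each fragment to the bin containing its midpoint.

    ``fragments`` is a BED-like frame with ``chrom, start0, end0``.  Fragments
    on chromosomes absent from ``bins`` are tallied as unassigned (with a
    warning) so that assigned + unassigned equals the input count.  Returns
    the bin frame with a ``count`` column; ``frame.attrs["unassigned"]``
    records the unassigned tally.
    """
    out = bins.reset_index(drop=True).copy()
    counts = np.zeros(len(out), dtype=np.int64)
    unassigned = 0
    bin_chroms = out["chrom"].to_numpy()
    for chrom, sub in fragments.groupby("chrom", sort=False):
        sel = np.flatnonzero(bin_chroms == chrom)
        if sel.size == 0:
            unassigned += len(sub)
            continue
        starts = out["start0"].to_numpy()[sel]
        ends = out["end0"].to_numpy()[sel]
        # integer midpoint; a midpoint exactly on a boundary belongs to the
        # right bin (half-open convention)
        mid = (sub["start0"].to_numpy(np.int64) + sub["end0"].to_numpy(np.int64)) // 2
        idx = np.searchsorted(starts, mid, side="right") - 1
        ok = (idx >= 0) & (mid < ends[np.clip(idx, 0, len(ends) - 1)])
        unassigned += int((~ok).sum())
        np.add.at(counts, sel[idx[ok]], 1)
    if unassigned:
        warnings.warn(f"{unassigned} fragments fell outside the bin set", stacklevel=2)
    out["count"] = counts
    out.attrs["unassigned"] = unassigned
    return out


@dataclass
class PanelOfNormals:
    """Pooled-normal reference: per-bin proportions of a copy-neutral genome.

    ``proportion`` sums to 1 over unmasked bins; ``dispersion`` is the
    standard deviation of per-normal log2 ratios against the pooled
    reference; bins with zero pooled count are masked.
    """

    bins: pd.DataFrame
    proportion: np.ndarray
    dispersion: np.ndarray
    mask: np.ndarray  # True where the bin is unusable

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def _check_same_bins(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b) or not (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["start0"].to_numpy() == b["start0"].to_numpy()).all()
        and (a["end0"].to_numpy() == b["end0"].to_numpy()).all()
    ):
        raise ValidationError("bin sets do not match")


def build_panel(normal_bincounts: Sequence[pd.DataFrame]) -> PanelOfNormals:
    """Pool counts from all normal samples into a synthetic control.

    ``proportion_b = sum_n count_{n,b} / sum_n total_n``; masked where the
    pooled count is zero.  Dispersion per bin is the SD (ddof=0) of each
    normal's own log2 ratio against the pooled reference, 0 for a single
    normal.
    """
    if len(normal_bincounts) == 0:
        raise ParameterError("panel needs >= 1 normal sample")
    first = normal_bincounts[0]
    for other in normal_bincounts[1:]:
        _check_same_bins(first, other)
    counts = np.stack([bc["count"].to_numpy(np.float64) for bc in normal_bincounts])
    pooled = counts.sum(axis=0)
    total = pooled.sum()
    if total == 0:
        raise ValidationError("panel has zero total reads")
    mask = pooled == 0
    proportion = pooled / total
    # per-normal log2 ratios vs the pooled reference, for the dispersion track
    ratios = np.full_like(counts, np.nan)
    for i in range(counts.shape[0]):
        t = counts[i].sum()
        if t == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2((np.maximum(counts[i], 0.5) / t) / proportion)
        r[mask] = np.nan
        ratios[i] = r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dispersion = np.nanstd(ratios, axis=0)
    dispersion[mask] = np.nan
    bins = first[["chrom", "start0", "end0"]].reset_index(drop=True).copy()
    return PanelOfNormals(bins=bins, proportion=proportion, dispersion=dispersion, mask=mask)


def copy_ratio(sample_bincounts: pd.DataFrame, panel: PanelOfNormals) -> pd.DataFrame:
    """Per-bin log2 copy ratio of a sample against the panel.

    Zero-count sample bins receive a pseudocount of 0.5 reads so the track
    stays dense; bins masked in the panel are missing.  A z-score
    (ratio / panel dispersion) is reported where the dispersion is positive.
    """
    _check_same_bins(sample_bincounts, panel.bins)
    count = sample_bincounts["count"].to_numpy(np.float64)
    total = count.sum()
    if total == 0:
        raise ValidationError("sample has zero total reads")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((np.maximum(count, 0.5) / total) / panel.proportion)
        z = ratio / panel.dispersion
    ratio[panel.mask] = np.nan
    z[panel.mask | ~(panel.dispersion > 0)] = np.nan
    out = panel.bins.copy()
    out["log2_ratio"] = ratio
    out["z"] = z
    return out


def _best_split(values: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best binary split of a segment by the pooled two-sample t statistic.

    Returns ``(split_index, |t|)``; split_index is the size of the left part.
    """
    n = len(values)
    if n < 2 * min_bins:
        return 0, 0.0
    cs = np.concatenate([[0.0], np.cumsum(values)])
    css = np.concatenate([[0.0], np.cumsum(values**2)])
    i = np.arange(min_bins, n - min_bins + 1)
    n1 = i.astype(float)
    n2 = n - n1
    m1 = cs[i] / n1
    m2 = (cs[n] - cs[i]) / n2
    ss1 = css[i] - n1 * m1**2
    ss2 = (css[n] - css[i]) - n2 * m2**2
    pooled_var = (ss1 + ss2) / np.maximum(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    t = np.nan_to_num(t)
    k = int(np.argmax(t))
    return int(i[k]), float(t[k])


def segment_and_call(
    track: pd.DataFrame,
    min_bins: int = 10,
    threshold: float = 0.15,
    stop_t: float = 5.0,
) -> pd.DataFrame:
    """Recursive binary segmentation of a log2-ratio track with gain/loss calls.

    Each chromosome is segmented independently over its unmasked bins.  A
    segment is split at the point maximizing the two-sample t statistic of
    mean log2 ratio, recursing while ``|t| >= stop_t`` and both parts keep at
    least ``min_bins`` bins.  Segments are called ``gain`` when the mean
    ratio exceeds ``threshold``, ``loss`` below ``-threshold``, else
    ``neutral``.  Coordinates span the first to last member bin.
    """
    usable = track[~track["log2_ratio"].isna()]
    if len(usable) == 0:
        raise ValidationError("track has no usable bins")
    segments = []

    def recurse(values: np.ndarray, rows: pd.DataFrame) -> None:
        split, t = _best_split(values, min_bins)
        if t >= stop_t and split > 0:
            recurse(values[:split], rows.iloc[:split])
            recurse(values[split:], rows.iloc[split:])
            return
        mean = float(values.mean())
        state = "gain" if mean > threshold else ("loss" if mean < -threshold else "neutral")
        segments.append(
            (
                rows["chrom"].iloc[0],
                int(rows["start0"].iloc[0]),
                int(rows["end0"].iloc[-1]),
                len(values),
                mean,
                state,
            )
        )

    for chrom, rows in usable.groupby("chrom", sort=False):
        recurse(rows["log2_ratio"].to_numpy(np.float64), rows)
    return pd.DataFrame(
        segments, columns=["chrom", "start0", "end0", "n_bins", "mean_log2", "state"]
    )


def gc_correct(bin_counts: pd.DataFrame, bin_gc: np.ndarray, width: float = 0.05) -> pd.DataFrame:
    """Optional GC normalization: divide counts by the median normalized count
    of each GC stratum (``width``-sized buckets).  Off by default in the
    pipeline since linear amplification shows little GC bias."""
    gc = np.asarray(bin_gc, dtype=float)
    if ((gc < 0) | (gc > 1)).any():
        raise ParameterError("GC fractions must lie in [0, 1]")
    out = bin_counts.reset_index(drop=True).copy()
    counts = out["count"].to_numpy(np.float64)
    strata = np.minimum((gc / width).astype(int), int(1 / width) - 1)
    corrected = counts.copy()
    global_med = np.median(counts[counts > 0]) if (counts > 0).any() else 1.0
    for s in np.unique(strata):
        sel = strata == s
        med = np.median(counts[sel])
        if med > 0:
            corrected[sel] = counts[sel] * global_med / med
    out["count"] = np.round(corrected).astype(np.int64)
    return out


def read_bin_counts(path) -> pd.DataFrame:
    """Read a bin-count TSV (chrom, start, end, count)."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "start0": raw[1].astype(np.int64),
            "end0": raw[2].astype(np.int64),
            "count": raw[3].astype(np.int64),
        }
    )
    if (out["count"] < 0).any():
        raise ValidationError(f"{path}: negative bin count")
    return out


def write_bin_counts(bin_counts: pd.DataFrame, path) -> None:
    bin_counts[["chrom", "start0", "end0", "count"]].to_csv(path, sep="\t", header=False, index=False)
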