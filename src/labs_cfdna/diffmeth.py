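"""Two-group differential methylation on pooled region counts.

Replicates within a group are pooled per region, each region is tested with
a two-sided Fisher's exact test on the 2x2 methylated/unmethylated table
(chi-square with continuity correction available for large counts), p-values
are adjusted by Benjamini-Hochberg, and regions passing both an FDR cutoff
and a methylation-difference cutoff are reported as DMRs.  Two presets mirror
common practice for cfDNA tiling analyses: genome-wide windows at
``|difference| > 0.15`` (strict inequality) and promoters at
``|difference| >= 0.12``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError


def region_test(
    meth1: int, unmeth1: int, meth2: int, unmeth2: int, method: str = "fisher"
) -> float:
    """Two-sided p-value for a difference in methylation proportion.

    Default is Fisher's exact test on ``[[meth1, unmeth1], [meth2, unmeth2]]``;
    ``method="chi2"`` uses the chi-square test with continuity correction,
    appropriate for large counts.  Returns NaN when both groups have zero
    total reads.
    """
    counts = (meth1, unmeth1, meth2, unmeth2)
    if any(c < 0 for c in counts):
        raise ParameterError("counts must be non-negative")
    if meth1 + unmeth1 == 0 and meth2 + unmeth2 == 0:
        return float("nan")
    table = [[meth1, unmeth1], [meth2, unmeth2]]
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "chi2":
        if min(meth1 + unmeth1, meth2 + unmeth2) == 0:
            return 1.0
        return float(stats.chi2_contingency(table, correction=True)[1])
    raise ParameterError(f"unknown test method {method!r}")


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    NaN entries propagate to NaN and do not count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def differential_table(
    meth: pd.DataFrame,
    unmeth: pd.DataFrame,
    labels: pd.Series | dict,
    group1: str,
    group2: str,
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-region two-group test on pooled counts.

    ``meth`` and ``unmeth`` are regions x samples count matrices with
    identical shape and labels; ``labels`` maps sample -> group.  Counts are
    pooled within group before testing.  Returns a frame indexed like
    ``meth`` with columns ``meth1, unmeth1, meth2, unmeth2, level1, level2,
    difference, p_value, q_value, direction`` where ``difference = level1 -
    level2`` and ``direction`` is ``hyper``/``hypo`` for group1 relative to
    group2.
    """
    labels = pd.Series(labels)
    if not meth.columns.equals(unmeth.columns) or not meth.index.equals(unmeth.index):
        raise ValidationError("meth and unmeth matrices must share labels")
    s1 = labels.index[labels == group1]
    s2 = labels.index[labels == group2]
    if len(s1) == 0 or len(s2) == 0:
        raise ParameterError(f"both groups need >=1 sample ({group1}: {len(s1)}, {group2}: {len(s2)})")
    m1 = meth[s1].sum(axis=1).to_numpy(np.int64)
    u1 = unmeth[s1].sum(axis=1).to_numpy(np.int64)
    m2 = meth[s2].sum(axis=1).to_numpy(np.int64)
    u2 = unmeth[s2].sum(axis=1).to_numpy(np.int64)
    p = np.array([region_test(a, b, c, d, method=method) for a, b, c, d in zip(m1, u1, m2, u2)])
    with np.errstate(invalid="ignore", divide="ignore"):
        l1 = np.where(m1 + u1 > 0, m1 / np.maximum(m1 + u1, 1), np.nan)
        l2 = np.where(m2 + u2 > 0, m2 / np.maximum(m2 + u2, 1), np.nan)
    diff = l1 - l2
    out = pd.DataFrame(
        {
            "meth1": m1,
            "unmeth1": u1,
            "meth2": m2,
            "unmeth2": u2,
            "level1": l1,
            "level2": l2,
            "difference": diff,
            "p_value": p,
            "q_value": adjust_fdr(p),
        },
        index=meth.index,
    )
    out["direction"] = np.where(diff >= 0, "hyper", "hypo")
    out.loc[np.isnan(diff), "direction"] = ""
    return out


def call_dmrs(
    meth: pd.DataFrame,
    unmeth: pd.DataFrame,
    labels: pd.Series | dict,
    group1: str,
    group2: str,
    diff_cutoff: float = 0.15,
    fdr_cutoff: float = 0.01,
    strict_diff: bool = True,
    method: str = "fisher",
) -> pd.DataFrame:
    """Call DMRs: regions with ``q < fdr_cutoff`` and a methylation
    difference beyond ``diff_cutoff``.

    ``strict_diff=True`` requires ``|difference| > diff_cutoff`` (the window
    preset, "larger than" the cutoff); ``False`` requires ``>=`` (the
    promoter preset).  Returns the subset of the full test table that passes.
    """
    table = differential_table(meth, unmeth, labels, group1, group2, method=method)
    absdiff = table["difference"].abs()
    passes_diff = absdiff > diff_cutoff if strict_diff else absdiff >= diff_cutoff
    called = table[(table["q_value"] < fdr_cutoff) & passes_diff]
    return called.copy()


def promoter_dmrs(meth, unmeth, labels, group1, group2, diff_cutoff=0.12, fdr_cutoff=0.01):
    """Promoter preset: difference >= 12% and FDR < 0.01."""
    return call_dmrs(
        meth, unmeth, labels, group1, group2,
        diff_cutoff=diff_cutoff, fdr_cutoff=fdr_cutoff, strict_diff=False,
    )


def write_dmrs_bed(dmrs: pd.DataFrame, regions: pd.DataFrame, path) -> None:
    """Write called DMRs as BED6+ (chrom, start, end, name, difference,
    strand, p, q, direction), joining on the region index."""
    reg = regions.loc[dmrs.index]
    out = pd.DataFrame(
        {
            "chrom": reg["chrom"].to_numpy(),
            "start0": reg["start0"].to_numpy(),
            "end0": reg["end0"].to_numpy(),
            "name": reg["name"].to_numpy(),
            "difference": dmrs["difference"].round(6).to_numpy(),
            "strand": reg["strand"].to_numpy(),
            "p_value": dmrs["p_value"].to_numpy(),
            "q_value": dmrs["q_value"].to_numpy(),
            "direction": dmrs["direction"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
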