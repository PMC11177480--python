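"""Per-CpG methylation call tables and region-level summarization.

The on-disk format is the tab-separated bisulfite *coverage* dialect
(1-based inclusive positions)::

    chrom  start  end  methylation_percent  count_methylated  count_unmethylated

optionally extended with ``strand`` and ``context`` columns.  In memory a
call table is a :class:`pandas.DataFrame` with columns

    ``chrom, pos0, strand, context, n_meth, n_unmeth``

where ``pos0`` is a 0-based position.  Regions are half-open 0-based
intervals ``[start0, end0)``.  Region methylation levels are *pooled*
(coverage-weighted): the level of a region is the total number of
methylated reads over all contained CpGs divided by the total read count,
which equals the coverage-weighted mean of per-site proportions.
"""

from __future__ import annotations

import io
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, ValidationError

CALL_COLUMNS = ["chrom", "pos0", "strand", "context", "n_meth", "n_unmeth"]
REGION_COLUMNS = ["chrom", "start0", "end0", "name", "strand"]

_CONTEXTS = ("CpG", "CHG", "CHH")


def empty_calls() -> pd.DataFrame:
    """An empty call table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos0": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_unmeth": pd.Series(dtype=np.int64),
        }
    )


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check call-table invariants: non-negative counts, sorted unique sites."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValidationError(f"call table missing columns: {missing}")
    if len(calls) == 0:
        return calls
    if (calls["n_meth"] < 0).any() or (calls["n_unmeth"] < 0).any():
        raise ValidationError("negative read counts in call table")
    if calls.duplicated(subset=["chrom", "pos0", "strand"]).any():
        raise ValidationError("duplicate (chrom, pos0, strand) records")
    return calls


def read_cpg_calls(path: str | PathLike, min_coverage: int = 0) -> pd.DataFrame:
    """Read a coverage-dialect call file, dropping sites below ``min_coverage``.

    File positions are 1-based inclusive and converted to 0-based ``pos0``.
    Six-column files default to strand ``.`` and context ``CpG``; the
    8-column variant written by :func:`write_cpg_calls` carries both.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return empty_calls()
    ncol = raw.shape[1]
    if ncol not in (6, 8):
        raise ParseError(f"{path}: expected 6 or 8 tab-separated columns, found {ncol}")
    try:
        pos = pd.to_numeric(raw[1], errors="raise").astype(np.int64)
        n_meth = pd.to_numeric(raw[4], errors="raise").astype(np.int64)
        n_unmeth = pd.to_numeric(raw[5], errors="raise").astype(np.int64)
    except (ValueError, TypeError):
        _locate_bad_line(path)
        raise ParseError(f"{path}: malformed numeric field")  # pragma: no cover
    calls = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "pos0": pos - 1,
            "strand": raw[6].astype(str) if ncol == 8 else ".",
            "context": raw[7].astype(str) if ncol == 8 else "CpG",
            "n_meth": n_meth,
            "n_unmeth": n_unmeth,
        }
    )
    if (calls["n_meth"] < 0).any() or (calls["n_unmeth"] < 0).any():
        bad = int((calls["n_meth"] < 0).idxmax())
        raise ValidationError(f"{path}: negative count at record {bad + 1}")
    if min_coverage > 0:
        calls = calls[calls["n_meth"] + calls["n_unmeth"] >= min_coverage]
    calls = calls.sort_values(["chrom", "pos0", "strand"], kind="stable").reset_index(drop=True)
    return validate_calls(calls)


def _locate_bad_line(path: str | PathLike) -> None:
    """Rescan a file that failed bulk parsing to report the first bad line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 columns")
            try:
                int(fields[1]), int(fields[4]), int(fields[5])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed numeric field")


def write_cpg_calls(calls: pd.DataFrame, path: str | PathLike) -> None:
    """Write the 8-column coverage dialect (1-based positions).

    Round-trips exactly through :func:`read_cpg_calls` at ``min_coverage=0``.
    """
    validate_calls(calls)
    cov = (calls["n_meth"] + calls["n_unmeth"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * calls["n_meth"].to_numpy() / np.maximum(cov, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos0"] + 1,
            "end": calls["pos0"] + 1,
            "pct": np.round(pct, 6),
            "n_meth": calls["n_meth"],
            "n_unmeth": calls["n_unmeth"],
            "strand": calls["strand"],
            "context": calls["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_strand_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse opposite-strand CpG records onto the plus-strand cytosine.

    A ``-``-strand CpG at position ``p`` reports the same dyad as the
    ``+``-strand record at ``p - 1``; counts are summed.  Non-CpG contexts
    are passed through unchanged.
    """
    cpg = calls[calls["context"] == "CpG"].copy()
    rest = calls[calls["context"] != "CpG"]
    minus = cpg["strand"] == "-"
    cpg.loc[minus, "pos0"] = cpg.loc[minus, "pos0"] - 1
    cpg["strand"] = "+"
    merged = (
        cpg.groupby(["chrom", "pos0", "strand", "context"], as_index=False)[["n_meth", "n_unmeth"]]
        .sum()
    )
    out = pd.concat([merged[CALL_COLUMNS], rest[CALL_COLUMNS]], ignore_index=True)
    return out.sort_values(["chrom", "pos0", "strand"], kind="stable").reset_index(drop=True)


def make_windows(
    genome: Mapping[str, int] | Sequence[tuple[str, int]],
    size: int = 3000,
    step: int | None = None,
) -> pd.DataFrame:
    """Tile a genome into windows ``[k*step, k*step+size)``; the final partial
    window is retained.  ``step`` defaults to ``size`` (non-overlapping tiles);
    a smaller step produces sliding windows."""
    if size < 1:
        raise ParameterError("window size must be >= 1")
    step = size if step is None else step
    if step < 1:
        raise ParameterError("window step must be >= 1")
    items = genome.items() if isinstance(genome, Mapping) else genome
    rows = []
    for chrom, length in items:
        starts = np.arange(0, length, step, dtype=np.int64)
        for s in starts:
            e = min(s + size, length)
            rows.append((chrom, int(s), int(e), f"{chrom}:{s}-{e}", "."))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def tss_regions(
    tss_table: pd.DataFrame,
    flank: int = 1000,
    genome: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Promoter regions ``[tss - flank, tss + flank)``, clipped at chromosome
    start (and end when ``genome`` is given).

    ``tss_table`` needs columns ``chrom, tss_pos0, strand, gene``.  The strand
    is recorded but both flanks are symmetric, so it does not alter the
    interval.
    """
    for col in ("chrom", "tss_pos0"):
        if col not in tss_table.columns:
            raise ValidationError(f"tss table missing column {col!r}")
    if genome is not None:
        unknown = set(tss_table["chrom"]) - set(genome)
        if unknown:
            raise ValidationError(f"TSS on unknown chromosomes: {sorted(unknown)}")
    start = np.maximum(tss_table["tss_pos0"].to_numpy(np.int64) - flank, 0)
    end = tss_table["tss_pos0"].to_numpy(np.int64) + flank
    if genome is not None:
        lengths = tss_table["chrom"].map(dict(genome)).to_numpy(np.int64)
        end = np.minimum(end, lengths)
    return pd.DataFrame(
        {
            "chrom": tss_table["chrom"].to_numpy(),
            "start0": start,
            "end0": end,
            "name": tss_table.get("gene", pd.Series(["."] * len(tss_table))).to_numpy(),
            "strand": tss_table.get("strand", pd.Series(["."] * len(tss_table))).to_numpy(),
        }
    )


def summarize_regions(calls: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Pool methylated/unmethylated counts over the CpGs inside each region.

    Returns the region frame extended with ``n_meth, n_unmeth, n_sites,
    level``; ``level`` is NaN for regions with no covered site.  Overlapping
    regions are supported (each region is summarized independently).
    """
    out = regions.reset_index(drop=True).copy()
    n = len(out)
    n_meth = np.zeros(n, dtype=np.int64)
    n_unmeth = np.zeros(n, dtype=np.int64)
    n_sites = np.zeros(n, dtype=np.int64)
    if len(calls):
        calls = calls.sort_values(["chrom", "pos0"], kind="stable")
        for chrom, sub in calls.groupby("chrom", sort=False):
            sel = np.flatnonzero(out["chrom"].to_numpy() == chrom)
            if sel.size == 0:
                continue
            pos = sub["pos0"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(sub["n_meth"].to_numpy())])
            cu = np.concatenate([[0], np.cumsum(sub["n_unmeth"].to_numpy())])
            lo = np.searchsorted(pos, out["start0"].to_numpy()[sel], side="left")
            hi = np.searchsorted(pos, out["end0"].to_numpy()[sel], side="left")
            n_meth[sel] = cm[hi] - cm[lo]
            n_unmeth[sel] = cu[hi] - cu[lo]
            n_sites[sel] = hi - lo
    out["n_meth"] = n_meth
    out["n_unmeth"] = n_unmeth
    out["n_sites"] = n_sites
    total = n_meth + n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(total > 0, n_meth / np.maximum(total, 1), np.nan)
    return out


def global_context_levels(calls: pd.DataFrame) -> dict[str, float]:
    """Pooled methylation level per cytosine context (CpG, CHG, CHH).

    Contexts absent from the table are omitted.  The non-CpG (CHG/CHH)
    levels proxy bisulfite conversion failure, since genuine non-CpG
    methylation is near zero in human tissue.
    """
    levels: dict[str, float] = {}
    for context, sub in calls.groupby("context"):
        total = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
        if total > 0:
            levels[str(context)] = float(sub["n_meth"].sum() / total)
    return levels


def read_regions_bed(path: str | PathLike) -> pd.DataFrame:
    """Read BED3/BED6 intervals into the region frame."""
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=REGION_COLUMNS)
    out = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "start0": pd.to_numeric(raw[1]).astype(np.int64),
            "end0": pd.to_numeric(raw[2]).astype(np.int64),
            "name": raw[3].astype(str) if raw.shape[1] > 3 else ".",
            "strand": raw[5].astype(str) if raw.shape[1] > 5 else ".",
        }
    )
    if (out["start0"] >= out["end0"]).any():
        raise ValidationError(f"{path}: degenerate interval (start >= end)")
    return out


def write_regions_bed(regions: pd.DataFrame, path: str | PathLike, extra: Iterable[str] = ()) -> None:
    """Write regions as BED6 (+ optional extra columns already in the frame)."""
    cols = ["chrom", "start0", "end0", "name"]
    frame = regions.copy()
    if "score" not in frame.columns:
        frame["score"] = 0
    cols += ["score", "strand"] + list(extra)
    frame[cols].to_csv(path, sep="\t", header=False, index=False)
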