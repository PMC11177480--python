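"""Synthetic cfDNA methylome cohorts with known ground truth.

Generates everything the analysis stages consume — per-CpG call files,
100-kb bin counts, cell-type reference atlases — from an explicit
generative model, so the whole pipeline runs end to end with no external
data and every planted effect is recoverable for validation:

* **Mixtures.**  Each plasma sample is a mixture of cell-type methylomes.
  Healthy samples draw leukocyte proportions from a Dirichlet
  (neutrophil-dominant, as in real cfDNA); cancer samples additionally
  carry a tumor fraction that displaces an equal share of the normal mix.
* **Reads.**  Per-site coverage is Poisson (linear amplification introduces
  little dispersion; an optional overdispersion parameter is available),
  each read's source cell type is categorical in the sample's proportions,
  and its methylation state is Bernoulli in the source type's probability,
  then flipped by two bisulfite error rates (conversion failure:
  unmethylated read appears methylated; overconversion: the reverse).
* **Differential methylation.**  Planted DMRs shift the tumor component's
  methylation only, so the observable case-control difference scales with
  tumor fraction — the ctDNA dilution effect.
* **Copy number.**  Bin counts are multinomial with per-bin weight
  proportional to ``1 + tumor_fraction * (copy/2 - 1)``.
* **Amplification.**  A molecule-level simulator contrasts linear
  amplification (each molecule amplified independently, Poisson copies)
  with exponential amplification (log-normal copies, heavier tail), whose
  read-level duplication rates differ measurably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from os import PathLike
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cnv as _cnv
from . import deconv as _deconv
from .errors import ParameterError, ValidationError
from .methylome import CALL_COLUMNS, write_cpg_calls

DEFAULT_CELL_TYPES = ("neutrophil", "monocyte", "cd4_t", "cd8_t", "b_cell", "nk", "colon")
# neutrophil-dominant healthy cfDNA composition; colon (the tumor lineage)
# contributes little in health
DEFAULT_DIRICHLET_ALPHA = {
    "neutrophil": 12.0,
    "monocyte": 4.0,
    "cd4_t": 3.0,
    "cd8_t": 2.0,
    "b_cell": 2.0,
    "nk": 1.5,
    "colon": 0.5,
}


# ---------------------------------------------------------------------------
# reference atlas


@dataclass
class ReferenceAtlas:
    """Cell-type methylation probabilities at a fixed set of CpG sites.

    ``meth_prob`` is sites x cell types in [0, 1].  ``marker_type`` flags,
    per site, the cell type the site discriminates (empty string when the
    site is a shared-baseline site) and ``marker_direction`` whether the
    flagged type is hypo- or hyper-methylated relative to all others by at
    least the construction margin.
    """

    cell_types: list[str]
    sites: pd.DataFrame  # chrom, pos0, strand
    meth_prob: np.ndarray
    marker_type: np.ndarray
    marker_direction: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        """Sites x cell-types reference matrix indexed by (chrom, pos0)."""
        index = pd.MultiIndex.from_frame(self.sites[["chrom", "pos0"]])
        return pd.DataFrame(self.meth_prob, index=index, columns=self.cell_types)

    def marker_frame(self) -> pd.DataFrame:
        """Reference matrix restricted to flagged marker sites."""
        keep = self.marker_type != ""
        return self.to_frame()[keep]


def _site_positions(rng, genome: Sequence[tuple[str, int]], cpg_per_kb: float) -> pd.DataFrame:
    rows = []
    for chrom, length in genome:
        n = max(int(length / 1000 * cpg_per_kb), 1)
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False))
        for p in pos:
            rows.append((chrom, int(p), "+"))
    return pd.DataFrame(rows, columns=["chrom", "pos0", "strand"])


def build_reference_atlas(
    n_cell_types: int,
    n_sites: int,
    marker_fraction: float = 0.5,
    margin: float = 0.8,
    seed: int = 0,
    cell_types: Sequence[str] | None = None,
    genome: Sequence[tuple[str, int]] | None = None,
    cpg_per_kb: float = 1.0,
) -> ReferenceAtlas:
    """Construct a reference atlas with guaranteed-margin marker sites.

    A ``marker_fraction`` of sites are markers: the flagged type's
    probability differs from every other type's (shared) value at that site
    by at least ``margin``, alternating hypo/hyper.  Non-marker sites share
    one baseline probability across all types, drawn from a bimodal
    distribution mimicking the mostly-high / promoter-low methylome.
    Deterministic for a fixed seed.  Sites are placed on a synthetic contig
    unless a ``genome`` is given.
    """
    if n_cell_types < 2:
        raise ParameterError("need >= 2 cell types")
    if not 0 < marker_fraction <= 1:
        raise ParameterError("marker_fraction must lie in (0, 1]")
    if not 0 < margin <= 1:
        raise ParameterError("margin must lie in (0, 1]")
    if n_sites < 1:
        raise ParameterError("need >= 1 site")
    if cell_types is None:
        cell_types = [f"type_{i+1}" for i in range(n_cell_types)]
    cell_types = list(cell_types)
    if len(cell_types) != n_cell_types:
        raise ParameterError("cell_types length must equal n_cell_types")
    rng = np.random.default_rng(seed)
    if genome is None:
        sites = pd.DataFrame(
            {
                "chrom": "chrS",
                "pos0": np.arange(n_sites, dtype=np.int64) * 200 + 100,
                "strand": "+",
            }
        )
    else:
        sites = _site_positions(rng, genome, cpg_per_kb)
        if len(sites) < n_sites:
            raise ParameterError("genome too small for the requested site count")
        sites = sites.iloc[np.sort(rng.choice(len(sites), n_sites, replace=False))].reset_index(drop=True)

    # bimodal baseline: most CpGs highly methylated, a minority (promoter-like) low
    high = rng.random(n_sites) < 0.6
    baseline = np.where(high, rng.beta(8, 2, n_sites), rng.beta(2, 8, n_sites))
    prob = np.tile(baseline[:, None], (1, n_cell_types))

    n_markers = max(int(round(marker_fraction * n_sites)), 1)
    marker_idx = np.sort(rng.choice(n_sites, n_markers, replace=False))
    marker_type = np.full(n_sites, "", dtype=object)
    marker_direction = np.full(n_sites, "", dtype=object)
    flagged = rng.integers(0, n_cell_types, n_markers)
    hypo = rng.random(n_markers) < 0.5
    for j, (i, t) in enumerate(zip(marker_idx, flagged)):
        if hypo[j]:
            low = rng.uniform(0, (1 - margin) / 2)
            others = rng.uniform(low + margin, 1.0)
            prob[i, :] = others
            prob[i, t] = low
            marker_direction[i] = "hypo"
        else:
            highv = rng.uniform((1 + margin) / 2, 1.0)
            others = rng.uniform(0.0, highv - margin)
            prob[i, :] = others
            prob[i, t] = highv
            marker_direction[i] = "hyper"
        marker_type[i] = cell_types[t]
    return ReferenceAtlas(
        cell_types=cell_types,
        sites=sites,
        meth_prob=prob,
        marker_type=marker_type,
        marker_direction=marker_direction,
    )


# ---------------------------------------------------------------------------
# per-sample read simulation


def _check_simplex(proportions: np.ndarray) -> None:
    if (proportions < 0).any() or abs(proportions.sum() - 1.0) > 1e-6:
        raise ParameterError("proportions must be non-negative and sum to 1 (within 1e-6)")


def simulate_sample_calls(
    atlas: ReferenceAtlas,
    proportions,
    coverage_mean: float = 30.0,
    conversion_failure: float = 0.0,
    overconversion: float = 0.0,
    seed: int = 0,
    n_noncpg_sites: int = 0,
    overdispersion: float | None = None,
) -> pd.DataFrame:
    """Simulate one sample's per-CpG call table from a mixture of cell types.

    Per site: coverage ~ Poisson(``coverage_mean``) (gamma-Poisson when
    ``overdispersion`` > 0 gives a negative-binomial with that coefficient
    of extra dispersion); each read originates from a cell type drawn from
    ``proportions`` and is methylated with the atlas probability of that
    type, then flipped by the two bisulfite error rates.  Since a mixture
    of Bernoullis is Bernoulli in the mixed probability, counts are drawn
    binomially at the mixed, error-adjusted probability.  Uncovered sites
    are absent from the table.  ``n_noncpg_sites`` appends CHG/CHH sites
    with true methylation 0, whose apparent level estimates conversion
    failure.
    """
    for name, v in (("conversion_failure", conversion_failure), ("overconversion", overconversion)):
        if not 0 <= v <= 1:
            raise ParameterError(f"{name} must lie in [0, 1]")
    if isinstance(proportions, (pd.Series, dict)):
        proportions = pd.Series(proportions).reindex(atlas.cell_types).fillna(0.0).to_numpy()
    w = np.asarray(proportions, dtype=np.float64)
    if w.shape[0] != len(atlas.cell_types):
        raise ParameterError("proportions length must match atlas cell types")
    _check_simplex(w)
    rng = np.random.default_rng(seed)

    p_true = np.clip(atlas.meth_prob @ w, 0.0, 1.0)
    p_obs = p_true * (1.0 - overconversion) + (1.0 - p_true) * conversion_failure

    n = atlas.n_sites
    if overdispersion and overdispersion > 0:
        lam = rng.gamma(shape=1.0 / overdispersion, scale=coverage_mean * overdispersion, size=n)
        cov = rng.poisson(lam)
    else:
        cov = rng.poisson(coverage_mean, size=n)
    n_meth = rng.binomial(cov, p_obs)
    calls = pd.DataFrame(
        {
            "chrom": atlas.sites["chrom"].to_numpy(),
            "pos0": atlas.sites["pos0"].to_numpy(),
            "strand": atlas.sites["strand"].to_numpy(),
            "context": "CpG",
            "n_meth": n_meth,
            "n_unmeth": cov - n_meth,
        }
    )
    if n_noncpg_sites > 0:
        chrom = atlas.sites["chrom"].iloc[-1]
        start = int(atlas.sites["pos0"].max()) + 11
        pos = start + 2 * np.arange(n_noncpg_sites, dtype=np.int64) + 1
        ncov = rng.poisson(coverage_mean, size=n_noncpg_sites)
        nm = rng.binomial(ncov, conversion_failure)
        noncpg = pd.DataFrame(
            {
                "chrom": chrom,
                "pos0": pos,
                "strand": "+",
                "context": np.where(np.arange(n_noncpg_sites) % 2 == 0, "CHH", "CHG"),
                "n_meth": nm,
                "n_unmeth": ncov - nm,
            }
        )
        calls = pd.concat([calls, noncpg], ignore_index=True)
    calls = calls[calls["n_meth"] + calls["n_unmeth"] > 0]
    return calls.sort_values(["chrom", "pos0"], kind="stable").reset_index(drop=True)[CALL_COLUMNS]


def simulate_bin_counts(
    bins: pd.DataFrame,
    cna_segments: Sequence[tuple[str, int, int, float]] = (),
    tumor_fraction: float = 0.0,
    total_reads: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial bin counts under planted copy-number alterations.

    The expected relative weight of bin *b* is proportional to its length
    times ``1 + tumor_fraction * (copy(b)/2 - 1)`` where ``copy(b)`` is the
    planted copy number of the segment containing the bin midpoint (2 when
    neutral).  Counts sum to ``total_reads`` exactly.
    """
    if len(bins) == 0:
        raise ParameterError("empty bin set")
    if not 0 <= tumor_fraction <= 1:
        raise ParameterError("tumor_fraction must lie in [0, 1]")
    out = bins.reset_index(drop=True).copy()
    copy = np.full(len(out), 2.0)
    mid = (out["start0"].to_numpy() + out["end0"].to_numpy()) // 2
    for chrom, s, e, c in cna_segments:
        if c < 0:
            raise ParameterError("copy numbers must be >= 0")
        sel = (out["chrom"].to_numpy() == chrom) & (mid >= s) & (mid < e)
        copy[sel] = c
    length = (out["end0"] - out["start0"]).to_numpy(np.float64)
    weight = length * (1.0 + tumor_fraction * (copy / 2.0 - 1.0))
    weight = np.maximum(weight, 0.0)
    rng = np.random.default_rng(seed)
    out["count"] = rng.multinomial(total_reads, weight / weight.sum())
    return out


def simulate_amplification(
    n_molecules: int,
    n_reads: int,
    mode: str = "linear",
    mean_copies: float = 5.0,
    jitter: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-read molecule identifiers under linear or exponential amplification.

    Linear mode amplifies each molecule independently: copies ~ 1 +
    Poisson(mean_copies - 1).  Exponential mode compounds per-cycle
    efficiency differences, yielding log-normal copy numbers
    (exp(Normal(log mean_copies, jitter))) with a heavier tail, hence more
    read-level duplicates at matched depth.  Reads are drawn with
    probability proportional to copy number; a duplicate is any read
    sharing a molecule identifier with an earlier read.
    """
    if n_molecules < 1 or n_reads < 1:
        raise ParameterError("n_molecules and n_reads must be >= 1")
    if mean_copies < 1:
        raise ParameterError("mean_copies must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "linear":
        copies = 1.0 + rng.poisson(mean_copies - 1.0, size=n_molecules)
    elif mode == "exponential":
        copies = np.exp(rng.normal(np.log(mean_copies), jitter, size=n_molecules))
    else:
        raise ParameterError(f"mode must be 'linear' or 'exponential', got {mode!r}")
    p = copies / copies.sum()
    return rng.choice(n_molecules, size=n_reads, p=p)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimulationConfig:
    """Study design for a synthetic cancer/control cfDNA cohort.

    Defaults mirror a colorectal-cancer plasma study design: 50 cases vs 34
    matched controls, ~30x CpG coverage, ~1% bisulfite error in each
    direction (real non-CpG methylation readouts run near 0.8%), tumor
    fractions up to 40%, and chromosome-arm-scale planted CNAs.  The genome
    is a two-contig desk-scale stand-in; densities and depths are per-site,
    so conclusions about the estimators transfer across genome size.
    """

    n_cases: int = 50
    n_controls: int = 34
    genome: list = field(default_factory=lambda: [("chr1", 3_000_000), ("chr2", 2_000_000)])
    cpg_per_kb: float = 1.0
    coverage_mean: float = 30.0
    conversion_failure: float = 0.01
    overconversion: float = 0.01
    overdispersion: float | None = None
    cell_types: list = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))
    tumor_cell_type: str = "colon"
    dirichlet_alpha: dict = field(default_factory=lambda: dict(DEFAULT_DIRICHLET_ALPHA))
    case_alpha_shift: dict = field(default_factory=lambda: {"cd4_t": 2.0, "monocyte": -2.0})
    tumor_fraction_range: tuple = (0.05, 0.4)
    dmrs: list = field(default_factory=lambda: [("chr1", 1_000_000, 1_050_000, 0.4),
                                                ("chr2", 500_000, 550_000, -0.4)])
    cna_segments: list = field(default_factory=lambda: [("chr1", 2_000_000, 3_000_000, 3.0),
                                                        ("chr2", 0, 600_000, 1.0)])
    bin_size: int = 100_000
    reads_per_sample: int = 1_000_000
    marker_fraction: float = 0.1
    marker_margin: float = 0.8
    n_noncpg_sites: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("conversion_failure", "overconversion"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        lo, hi = self.tumor_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ParameterError("tumor_fraction_range must satisfy 0 <= lo <= hi <= 1")
        for _, _, _, c in self.cna_segments:
            if c < 0:
                raise ParameterError("copy numbers must be >= 0")
        if self.tumor_cell_type not in self.cell_types:
            raise ParameterError("tumor_cell_type must appear in cell_types")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ParameterError("cohort sizes must be non-negative")


@dataclass
class CohortGroundTruth:
    """The generator's planted truth, serialized alongside the cohort."""

    cell_types: list
    samples: list  # dicts: name, group, tumor_fraction, proportions
    dmrs: list
    cna_segments: list

    def to_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | PathLike) -> "CohortGroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def proportions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {s["name"]: s["proportions"] for s in self.samples}
        ).T[self.cell_types]


@dataclass
class CohortResult:
    """In-memory cohort: atlas, per-sample tables, and ground truth."""

    atlas: ReferenceAtlas
    calls: dict  # sample name -> call table
    bins: dict  # sample name -> bin-count frame
    truth: CohortGroundTruth


def _sample_proportions(rng, config: SimulationConfig, case: bool) -> tuple[np.ndarray, float]:
    types = config.cell_types
    alpha = np.array([config.dirichlet_alpha.get(t, 1.0) for t in types], dtype=float)
    if case:
        for t, shift in config.case_alpha_shift.items():
            if t in types:
                alpha[types.index(t)] = max(alpha[types.index(t)] + shift, 0.1)
    base = rng.dirichlet(alpha)
    if not case:
        return base, 0.0
    tf = float(rng.uniform(*config.tumor_fraction_range))
    w = base * (1.0 - tf)
    w[types.index(config.tumor_cell_type)] += tf
    return w, tf


def _case_atlas(atlas: ReferenceAtlas, config: SimulationConfig) -> ReferenceAtlas:
    """Apply planted DMR deltas to the tumor component's methylation only."""
    prob = atlas.meth_prob.copy()
    t = atlas.cell_types.index(config.tumor_cell_type)
    chroms = atlas.sites["chrom"].to_numpy()
    pos = atlas.sites["pos0"].to_numpy()
    for chrom, s, e, delta in config.dmrs:
        sel = (chroms == chrom) & (pos >= s) & (pos < e)
        prob[sel, t] = np.clip(prob[sel, t] + delta, 0.0, 1.0)
    return ReferenceAtlas(
        cell_types=atlas.cell_types,
        sites=atlas.sites,
        meth_prob=prob,
        marker_type=atlas.marker_type,
        marker_direction=atlas.marker_direction,
    )


def simulate_cohort(config: SimulationConfig, out_dir: str | PathLike | None = None) -> CohortResult:
    """Simulate a full case/control cohort; optionally write it to disk.

    Every case carries the configured DMR deltas (applied to its tumor
    component), CNA segments scaled by its own tumor fraction, and a
    group-shifted immune mix; controls are copy-neutral with healthy mixes.
    Outputs are bit-reproducible for a fixed config (per-sample seeds are
    spawned deterministically from ``config.seed``).

    When ``out_dir`` is given the cohort is written as one coverage-dialect
    call file and one bin-count TSV per sample, a ``samples.tsv`` sheet, a
    marker reference matrix, and ``truth.json``.
    """
    root = np.random.SeedSequence(config.seed)
    atlas_seed, mix_seed, calls_seed, bins_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    ]
    n_sites = max(int(sum(l for _, l in config.genome) / 1000 * config.cpg_per_kb), 10)
    atlas = build_reference_atlas(
        n_cell_types=len(config.cell_types),
        n_sites=n_sites,
        marker_fraction=config.marker_fraction,
        margin=config.marker_margin,
        seed=atlas_seed,
        cell_types=config.cell_types,
        genome=config.genome,
        cpg_per_kb=config.cpg_per_kb,
    )
    case_atlas = _case_atlas(atlas, config)
    bins = _cnv.bin_genome(config.genome, size=config.bin_size)

    mix_rng = np.random.default_rng(mix_seed)
    names, groups = [], []
    for i in range(config.n_cases):
        names.append(f"case_{i+1:03d}")
        groups.append("case")
    for i in range(config.n_controls):
        names.append(f"control_{i+1:03d}")
        groups.append("control")

    calls_all, bins_all, sample_truth = {}, {}, []
    for k, (name, group) in enumerate(zip(names, groups)):
        case = group == "case"
        w, tf = _sample_proportions(mix_rng, config, case)
        calls_all[name] = simulate_sample_calls(
            case_atlas if case else atlas,
            w,
            coverage_mean=config.coverage_mean,
            conversion_failure=config.conversion_failure,
            overconversion=config.overconversion,
            seed=(calls_seed + k) % (2**31),
            n_noncpg_sites=config.n_noncpg_sites,
            overdispersion=config.overdispersion,
        )
        segs = [(c, s, e, cp) for c, s, e, cp in config.cna_segments] if case else []
        bins_all[name] = simulate_bin_counts(
            bins,
            cna_segments=segs,
            tumor_fraction=tf,
            total_reads=config.reads_per_sample,
            seed=(bins_seed + k) % (2**31),
        )
        sample_truth.append(
            {
                "name": name,
                "group": group,
                "tumor_fraction": tf,
                "proportions": {t: float(p) for t, p in zip(config.cell_types, w)},
            }
        )
    truth = CohortGroundTruth(
        cell_types=list(config.cell_types),
        samples=sample_truth,
        dmrs=[list(d) for d in config.dmrs],
        cna_segments=[list(s) for s in config.cna_segments],
    )
    result = CohortResult(atlas=atlas, calls=calls_all, bins=bins_all, truth=truth)
    if out_dir is not None:
        write_cohort(result, out_dir)
    return result


def write_cohort(result: CohortResult, out_dir: str | PathLike) -> None:
    """Serialize a cohort: per-sample call and bin files, sample sheet,
    marker reference matrix, and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in result.calls:
        call_path = out / f"{sample}.cov.tsv"
        bin_path = out / f"{sample}.bins.tsv"
        write_cpg_calls(result.calls[sample], call_path)
        _cnv.write_bin_counts(result.bins[sample], bin_path)
        group = next(s["group"] for s in result.truth.samples if s["name"] == sample)
        rows.append((sample, group, call_path.name, bin_path.name))
    pd.DataFrame(rows, columns=["sample", "group", "calls", "bins"]).to_csv(
        out / "samples.tsv", sep="\t", index=False
    )
    marker = result.atlas.marker_frame()
    marker.index = [f"{c}:{p}" for c, p in marker.index]
    marker.to_csv(out / "reference_markers.tsv", sep="\t")
    result.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# feature-level cohort for the integrated classifier


def simulate_classification_cohort(
    seed: int = 0,
    n_cases: int = 42,
    n_controls: int = 42,
    n_regions: int = 200,
    n_dmr_regions: int = 30,
    meth_delta: float = 0.25,
    region_coverage: float = 40.0,
    n_bins: int = 400,
    bin_size: int = 100_000,
    reads_per_sample: int = 200_000,
    n_panel_normals: int = 8,
    tumor_fraction_range: tuple = (0.05, 0.5),
    marker_coverage: float = 30.0,
):
    """A balanced case/control cohort at the feature-block level.

    Produces the three classifier blocks through the same estimators the
    pipeline uses on files: promoter-region betas (binomial reads from
    mixture methylation with tumor-fraction-scaled planted deltas), per-bin
    log2 copy ratios against a pooled panel of simulated normals (two
    planted CNA segments, gain and loss), and immune proportions estimated
    by simplex-constrained deconvolution of noisy marker levels with a
    fixed case shift.  Returns ``(blocks, labels, truth)`` where ``blocks``
    has keys ``meth``, ``cnv``, ``props``.
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    labels = pd.Series(["case"] * n_cases + ["control"] * n_controls,
                       index=[f"s{i+1:03d}" for i in range(n)], name="group")
    tf = np.where(
        np.arange(n) < n_cases, rng.uniform(*tumor_fraction_range, size=n), 0.0
    )

    # --- methylation block: region betas with tumor-diluted planted deltas
    baseline = rng.uniform(0.15, 0.85, size=n_regions)
    dmr_idx = rng.choice(n_regions, size=n_dmr_regions, replace=False)
    direction = rng.choice([-1.0, 1.0], size=n_dmr_regions)
    meth = np.empty((n, n_regions))
    for i in range(n):
        p = baseline.copy()
        p[dmr_idx] = np.clip(p[dmr_idx] + tf[i] * meth_delta * direction, 0.02, 0.98)
        cov = np.maximum(rng.poisson(region_coverage, size=n_regions), 1)
        meth[i] = rng.binomial(cov, p) / cov
    meth_block = pd.DataFrame(meth, index=labels.index,
                              columns=[f"region_{j+1}" for j in range(n_regions)])

    # --- copy-number block: log2 ratios vs a pooled panel of normals
    bins = _cnv.bin_genome([("chrS", n_bins * bin_size)], size=bin_size)
    gain = ("chrS", int(0.25 * n_bins) * bin_size, int(0.40 * n_bins) * bin_size, 3.0)
    loss = ("chrS", int(0.60 * n_bins) * bin_size, int(0.75 * n_bins) * bin_size, 1.0)
    panel = _cnv.build_panel(
        [
            simulate_bin_counts(bins, total_reads=reads_per_sample,
                                seed=int(rng.integers(2**31)))
            for _ in range(n_panel_normals)
        ]
    )
    cn = np.empty((n, len(bins)))
    for i in range(n):
        bc = simulate_bin_counts(
            bins,
            cna_segments=[gain, loss] if tf[i] > 0 else [],
            tumor_fraction=tf[i],
            total_reads=reads_per_sample,
            seed=int(rng.integers(2**31)),
        )
        cn[i] = _cnv.copy_ratio(bc, panel)["log2_ratio"].to_numpy()
    cn_block = pd.DataFrame(np.nan_to_num(cn), index=labels.index,
                            columns=[f"bin_{j+1}" for j in range(len(bins))])

    # --- proportions block: deconvolution of noisy marker levels
    types = ["neutrophil", "monocyte", "cd4_t", "cd8_t", "b_cell", "nk"]
    R = pd.DataFrame(rng.uniform(0, 1, size=(26, len(types))),
                     index=[f"mega_{j+1}" for j in range(26)], columns=types)
    alpha_ctrl = np.array([12.0, 4.0, 3.0, 2.0, 2.0, 1.5])
    alpha_case = np.array([12.0, 2.0, 5.0, 2.0, 2.0, 1.5])  # cd4 up, monocyte down
    props = np.empty((n, len(types)))
    true_props = np.empty((n, len(types)))
    for i in range(n):
        w = rng.dirichlet(alpha_case if labels.iloc[i] == "case" else alpha_ctrl)
        true_props[i] = w
        y_true = np.clip(R.to_numpy() @ w, 0.0, 1.0)
        cov = np.maximum(rng.poisson(marker_coverage, size=len(R)), 1)
        y = rng.binomial(cov, y_true) / cov
        props[i] = _deconv.deconvolve(pd.Series(y, index=R.index), R).proportions.to_numpy()
    props_block = pd.DataFrame(props, index=labels.index, columns=types)

    truth = {
        "tumor_fraction": dict(zip(labels.index, tf.tolist())),
        "dmr_regions": [f"region_{j+1}" for j in sorted(dmr_idx.tolist())],
        "cna_segments": [list(gain), list(loss)],
        "true_proportions": pd.DataFrame(true_props, index=labels.index, columns=types),
    }
    return {"meth": meth_block, "cnv": cn_block, "props": props_block}, labels, truth
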