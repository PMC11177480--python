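"""Pipeline configuration: one YAML file, strict schema, paper-scale defaults.

Every stage parameter lives here with the pipeline's canonical default:
3-kb windows, >=3x CpG coverage, DMR cutoffs FDR < 0.01 with difference
> 15% (>= 12% for promoters), +/-1-kb TSS flanks, 100-kb copy-number bins,
32 dendrogram groups for mega sites, k = 10 for k-NN imputation, a 95%
explained-variance PCA target, a 1:3 train:test split, and fivefold CV.
Unknown keys are rejected with a spelling suggestion.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field
from os import PathLike

import yaml

from .errors import ValidationError
from .synthetic import SimulationConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    window_size: int = 3000
    window_step: int | None = None  # None -> non-overlapping tiles
    min_coverage: int = 3
    deconv_min_coverage: int = 1
    dmr_diff_cutoff: float = 0.15
    dmr_fdr_cutoff: float = 0.01
    promoter_diff_cutoff: float = 0.12
    tss_flank: int = 1000
    bin_size: int = 100_000
    segment_min_bins: int = 10
    segment_threshold: float = 0.15
    segment_stop_t: float = 5.0
    k_groups: int = 32
    knn_k: int = 10
    variance_target: float = 0.95
    train_fraction: float = 0.25
    cv_folds: int = 5
    classifier: str = "random_forest"
    drop_cell_type: str | None = "nk"  # drop one composition column (collinearity)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def _coerce(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        key = sorted(unknown)[0]
        hint = difflib.get_close_matches(key, names, n=1)
        msg = f"unknown config key {context}{key!r}"
        if hint:
            msg += f"; did you mean {hint[0]!r}?"
        raise ValidationError(msg)
    return data


def load_config(path: str | PathLike) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys.

    The ``simulation`` section maps onto :class:`SimulationConfig`; tuples
    inside it (genome contigs, DMR/CNA segments, ranges) may be given as
    YAML lists.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    _coerce(PipelineConfig, data, "")
    sim_data = data.pop("simulation", {}) or {}
    _coerce(SimulationConfig, sim_data, "simulation.")
    if "genome" in sim_data:
        sim_data["genome"] = [tuple(x) for x in sim_data["genome"]]
    for key in ("dmrs", "cna_segments"):
        if key in sim_data:
            sim_data[key] = [tuple(x) for x in sim_data[key]]
    if "tumor_fraction_range" in sim_data:
        sim_data["tumor_fraction_range"] = tuple(sim_data["tumor_fraction_range"])
    sim = SimulationConfig(**sim_data)
    return PipelineConfig(simulation=sim, **data)


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def save_config(config: PipelineConfig, path: str | PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
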