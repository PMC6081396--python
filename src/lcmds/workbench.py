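"""Experiment configuration and reproducible runs.

An :class:`ExperimentConfig` names exactly one data source (three matrix
TSVs, or a synthetic generator config), one method, and one protocol
(hold-out CV, LOOCV degree-bias, ablation, or plain prediction).
``run_experiment`` executes it and writes the report files plus a
manifest echoing the full configuration, so any run is reconstructible
from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .engine import ALL_METHODS, ClassifierConfig, lcm_predict_scores, write_score_matrix
from .evaluation import (
    BASELINE_METHODS,
    HoldoutPlan,
    ablation_run,
    holdout_cv,
    loocv_degree_bias,
)
from .io import read_interaction_matrix, read_similarity_matrix
from .synthetic import SyntheticConfig, generate_synthetic_ddi

__all__ = ["ExperimentConfig", "run_experiment"]

logger = logging.getLogger(__name__)

PROTOCOLS = ("holdout", "loocv", "ablate", "predict")


@dataclass(frozen=True)
class ExperimentConfig:
    """One reproducible experiment: data source, method, protocol."""

    protocol: str = "holdout"
    method: str = "ds"
    interactions: str | None = None
    similarity: str | None = None
    synthetic: SyntheticConfig | None = None
    holdout_ratio: float = 0.25
    repetitions: int = 50
    seed: int = 1
    variant: str = "regular"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    out_dir: str = "lcmds-run"

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        file_source = self.interactions is not None and self.similarity is not None
        if file_source == (self.synthetic is not None):
            raise ValueError(
                "exactly one data source required: interaction+similarity "
                "files, or a synthetic config"
            )
        if self.method not in ALL_METHODS + BASELINE_METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("synthetic"), dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if isinstance(d.get("classifier"), dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _load_data(config: ExperimentConfig):
    if config.synthetic is not None:
        ds = generate_synthetic_ddi(config.synthetic)
        return ds.interactions, ds.similarity
    A = read_interaction_matrix(config.interactions)
    S = read_similarity_matrix(config.similarity)
    if A.drugs.ids != S.drugs.ids:
        raise ValueError("interaction and similarity files list different drugs")
    return A, S


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the configured protocol; returns the output directory."""
    A, S = _load_data(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    plan = HoldoutPlan(
        ratio=config.holdout_ratio,
        repetitions=config.repetitions,
        seeds=tuple(range(config.seed, config.seed + config.repetitions)),
    )
    if config.protocol == "holdout":
        rep = holdout_cv(A, S, plan, config.method, config.classifier)
        rep.write(out / "report.txt")
    elif config.protocol == "ablate":
        rep = ablation_run(A, S, plan, config.variant, config.classifier)
        rep.write(out / "report.txt")
    elif config.protocol == "loocv":
        summary = loocv_degree_bias(A, S, config.method, config.classifier)
        summary.write(out / "ranking.tsv")
        (out / "report.txt").write_text(
            f"method\t{summary.method}\n"
            f"spearman_mean\t{summary.spearman_mean:.17g}\n"
            f"spearman_abs_mean\t{summary.spearman_abs_mean:.17g}\n"
        )
    elif config.protocol == "predict":
        # self-prediction run: score every drug against the training network
        sm = lcm_predict_scores(A, S, S.values, config.method, config.classifier)
        write_score_matrix(sm, out / "scores.tsv")

    manifest = {"package_version": __version__, "config": config.to_dict()}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("experiment written to %s", out)
    return out
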