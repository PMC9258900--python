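"""End-to-end orchestration: data prep, original-model training, extraction, evaluation.

The pipeline mirrors the standard distillation workflow: deduplicate the
MSA, split 9:1 into train and test, reweight the training sequences,
train an original generative model (autoregressive or VAE), draw extraction
samples (uniform and/or from the model itself), fit pairwise and independent
models to the energies, and report NRMSE per test stratum plus
mutational-effect Spearman correlations.  Every stage's seed derives
deterministically from the global seed, so reruns with the same config
reproduce the report exactly.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .alignment import (
    EncodedAlignment,
    MutationalDataset,
    compute_weights,
    deduplicate,
    read_fasta_alignment,
    read_mutational_csv,
    split_train_test,
)
from .ardca import ArDCA
from .distill import ExtractionConfig, extract_sgd, extract_uniform_closed_form
from .energy import save_model
from .evaluate import EvaluationReport, stratified_energy_report
from .synthetic import (
    planted_threebody_model,
    random_pairwise_model,
    sample_model,
    synthetic_mutational_dataset,
)
from .vae import SequenceVAE

#: grids assessed for the VAE when none are specified
DEFAULT_VAE_HIDDEN = [40, 80, 100, 120, 140, 160]
DEFAULT_VAE_LATENT = [5, 10, 20, 40, 80, 120]
DEFAULT_VAE_WEIGHT_DECAY = [0.1, 0.05, 0.01, 0.005, 0.001]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    ``data`` is either ``{"msa_path": ...}`` or a synthetic spec such as
    ``{"synthetic": {"kind": "pairwise", "N": 8, "q": 4, "n_sequences": 2000,
    "coupling_scale": 0.3, "field_scale": 0.5}}``.  ``extractions`` lists
    (distribution, family) pairs with optional overrides of the
    :class:`ExtractionConfig` defaults.  ``mutational`` is a csv path or
    ``{"synthetic": {"n_single_mutants": ..., "noise_sd": ...}}``.
    """

    data: dict[str, Any]
    original: dict[str, Any] = dc_field(default_factory=lambda: {"kind": "ardca"})
    extractions: list[dict[str, Any]] = dc_field(
        default_factory=lambda: [
            {"distribution": d, "family": f}
            for f in ("pairwise", "independent")
            for d in ("U", "M")
        ]
    )
    mutational: dict[str, Any] | str | None = None
    test_fraction: float = 0.1
    distant_fraction: float = 0.1
    similarity_threshold: float = 0.8
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def enumerate_vae_grid(
    hidden_list=None, latent_list=None, wd_list=None, dataset_list=None
) -> list[dict[str, Any]]:
    """Cartesian hyperparameter grid in deterministic order.

    With the default lists this yields 180 configurations per dataset
    (6 hidden sizes x 6 latent dimensions x 5 weight-decay strengths).
    """
    hidden_list = DEFAULT_VAE_HIDDEN if hidden_list is None else hidden_list
    latent_list = DEFAULT_VAE_LATENT if latent_list is None else latent_list
    wd_list = DEFAULT_VAE_WEIGHT_DECAY if wd_list is None else wd_list
    if not (hidden_list and latent_list and wd_list):
        raise ValueError("grid lists must be non-empty")
    datasets = dataset_list if dataset_list is not None else [None]
    if not datasets:
        raise ValueError("dataset list must be non-empty")
    grid = []
    for ds, h, d, wd in itertools.product(datasets, hidden_list, latent_list, wd_list):
        cfg = {"hidden": h, "latent": d, "weight_decay": wd}
        if ds is not None:
            cfg["dataset"] = ds
        grid.append(cfg)
    return grid


def _stage_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence([base, stage]).generate_state(1)[0] % (2**31))


def _load_alignment(cfg: PipelineConfig):
    data = cfg.data
    if "msa_path" in data:
        return read_fasta_alignment(data["msa_path"]), None
    spec = data["synthetic"]
    kind = spec.get("kind", "pairwise")
    seed = _stage_seed(cfg.seed, 1)
    if kind == "pairwise":
        truth = random_pairwise_model(
            spec["N"],
            spec["q"],
            coupling_scale=spec.get("coupling_scale", 0.3),
            field_scale=spec.get("field_scale", 0.5),
            seed=seed,
        )
    elif kind == "threebody":
        truth = planted_threebody_model(
            spec["N"],
            spec["q"],
            n_triplets=spec.get("n_triplets", 1),
            strength=spec.get("strength", 0.5),
            coupling_scale=spec.get("coupling_scale", 0.3),
            field_scale=spec.get("field_scale", 0.5),
            seed=seed,
        )
    else:
        raise ValueError(f"unknown synthetic kind {kind!r}")
    aln = sample_model(
        truth,
        spec.get("n_sequences", 2000),
        seed=_stage_seed(cfg.seed, 2),
        method=spec.get("method", "enumerate"),
    )
    return aln, truth


def _train_original(cfg: PipelineConfig, train: EncodedAlignment, weights: np.ndarray):
    spec = dict(cfg.original)
    kind = spec.pop("kind", "ardca")
    if kind == "ardca":
        model = ArDCA(**spec)
    elif kind == "vae":
        spec.setdefault("seed", _stage_seed(cfg.seed, 3))
        model = SequenceVAE(**spec)
    else:
        raise ValueError(f"unknown original model kind {kind!r}")
    model.fit(train, sample_weight=weights)
    return model


def _get_mutational(cfg: PipelineConfig, original, wildtype) -> MutationalDataset | None:
    if cfg.mutational is None:
        return None
    if isinstance(cfg.mutational, str):
        return read_mutational_csv(cfg.mutational, wildtype)
    if "csv_path" in cfg.mutational:
        return read_mutational_csv(cfg.mutational["csv_path"], wildtype)
    spec = cfg.mutational["synthetic"]
    return synthetic_mutational_dataset(
        original,
        wildtype,
        n_single_mutants=spec.get("n_single_mutants", 100),
        noise_sd=spec.get("noise_sd", 0.0),
        seed=_stage_seed(cfg.seed, 4),
    )


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> EvaluationReport:
    """Execute dedup -> split -> weight -> train -> sample -> extract -> evaluate."""
    timings: dict[str, float] = {}

    def _timed(name):
        timings[name] = time.time()

    _timed("start")
    aln, truth = _load_alignment(config)
    aln = deduplicate(aln)
    split = split_train_test(
        aln,
        test_fraction=config.test_fraction,
        seed=_stage_seed(config.seed, 5),
        distant_fraction=config.distant_fraction,
    )
    weights = compute_weights(split.train, similarity_threshold=config.similarity_threshold)
    if verbose:
        print(f"[pipeline] {len(aln)} unique sequences -> {len(split.train)} train / "
              f"{len(split.test)} test")
    _timed("data")

    original = _train_original(config, split.train, weights)
    _timed("train_original")

    extracted = {}
    for k, ext in enumerate(config.extractions):
        ext = dict(ext)
        dist = ext.pop("distribution", "M")
        family = ext.pop("family", "pairwise")
        label = ("PW" if family == "pairwise" else "IND") + "/" + dist
        seed = _stage_seed(config.seed, 10 + k)
        if dist == "U" and ext.pop("closed_form", True):
            n = ext.pop("n_samples", 10**5)
            k_target = ext.pop("k_target", 5000)
            model, _ = extract_uniform_closed_form(
                original, n_samples=n, seed=seed, family=family, k_target=k_target
            )
        else:
            xcfg = ExtractionConfig(distribution=dist, family=family, seed=seed, **ext)
            model, _ = extract_sgd(original, xcfg)
        extracted[label] = model
        if verbose:
            print(f"[pipeline] extracted {label}")
    _timed("extract")

    wildtype = split.train.codes[0]
    mutdata = _get_mutational(config, original, wildtype)
    report = stratified_energy_report(original, extracted, split, mutdata)
    report.metadata.update(
        {
            "seed": config.seed,
            "original": config.original,
            "n_train": len(split.train),
            "n_test": len(split.test),
        }
    )
    report.timings = {
        "data": timings["data"] - timings["start"],
        "train_original": timings["train_original"] - timings["data"],
        "extract": timings["extract"] - timings["train_original"],
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        report.nrmse_table().to_csv(out / "nrmse.tsv", sep="\t", index=False)
        for label, model in extracted.items():
            save_model(model, out / (label.replace("/", "_") + ".npz"))
    return report
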