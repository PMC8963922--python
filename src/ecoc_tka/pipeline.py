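"""End-to-end orchestration: simulate -> preprocess -> encode -> train ->
decode -> evaluate, driven by one validated config and one global seed.

Every artifact (cohort CSV, rendered films, codebook JSON, predictor
checkpoint, prediction CSV, report JSON, run log) is regenerable from the
config plus seed alone; the report JSON is byte-identical across reruns of
the same config.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict, ValidationError

from . import codes, evaluation, model, preprocessing, synthetic
from .decoder import BitLabelCounts

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger("ecoc_tka")


class ConfigError(ValueError):
    """A run config is missing or mistypes a key; the message names it."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Section):
    n_patients: int = 308
    seed_offset: int = 0


class PreprocessingSection(_Section):
    clip_limit: float = 0.02
    tile_grid: tuple[int, int] = (8, 8)
    spatial_bw: int = 5
    range_bw: float = 10.0
    crop_fraction: float = 0.85
    use_bmi: bool = False


class CodebookSection(_Section):
    scheme: str  # required: "hadamard" or "hamming"
    order: int = 16  # Hadamard order
    m: int = 4  # Hamming parameter


class LossSection(_Section):
    beta: float = 2.0
    gamma: float = 1.0
    bit_weighting: str = "none"


class ModelSection(_Section):
    hidden: tuple[int, ...] = (32,)
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 32
    patience: int = 10
    image_grid: int = 8


class DecodeSection(_Section):
    top_k: int = 3


class RunConfig(_Section):
    seed: int = 17
    use_images: bool = True
    image_size: int = 64
    cohort: CohortSection = CohortSection()
    preprocessing: PreprocessingSection = PreprocessingSection()
    codebook: CodebookSection
    loss: LossSection = LossSection()
    model: ModelSection = ModelSection()
    decode: DecodeSection = DecodeSection()


def default_config(**overrides) -> RunConfig:
    """The shipped default configuration (Hadamard-16 codebooks)."""
    base = {"codebook": {"scheme": "hadamard"}}
    base.update(overrides)
    return load_config(base)


def load_config(source: dict | str | Path) -> RunConfig:
    """Validate a config dict or YAML file into a :class:`RunConfig`.

    Raises :class:`ConfigError` naming the offending dotted key.
    """
    if isinstance(source, (str, Path)):
        source = yaml.safe_load(Path(source).read_text())
    try:
        return RunConfig(**source)
    except ValidationError as err:
        names = sorted({".".join(str(p) for p in e["loc"]) for e in err.errors()})
        raise ConfigError(f"invalid config key(s): {', '.join(names)}") from err


def _build_codebook(cfg: RunConfig, freqs: np.ndarray, classes: list, seed: int) -> codes.CodeBook:
    if cfg.codebook.scheme == "hadamard":
        return codes.assign_hadamard_codewords(freqs, cfg.codebook.order, classes=classes, seed=seed)
    if cfg.codebook.scheme == "hamming":
        words, d_min = codes.select_hamming_codewords(len(classes), m=cfg.codebook.m)
        return codes.CodeBook("hamming", words.shape[1], classes, words, d_min=d_min)
    raise ConfigError(f"invalid config key(s): codebook.scheme (got {cfg.codebook.scheme!r})")


def run_pipeline(config: RunConfig, outdir: str | Path, write_images: bool = False) -> evaluation.EvaluationReport:
    """Run the full pipeline and write all artifacts under ``outdir``.

    Returns the evaluation report (also written to ``report.json``).  With
    ``write_images`` the preprocessed films are saved as PNGs; otherwise they
    only exist in memory, which keeps desk-scale runs fast.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out, write_images)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path, write_images: bool) -> evaluation.EvaluationReport:
    logger.info("config: %s", cfg.model_dump())
    seed = cfg.seed

    cohort_cfg = synthetic.CohortConfig(
        n_patients=cfg.cohort.n_patients, seed=seed + cfg.cohort.seed_offset
    )
    cohort = synthetic.generate_cohort(cohort_cfg)
    cohort.to_csv(out / "cohort.csv", index=False)
    logger.info("generated cohort: n=%d", len(cohort))

    train, val, test = synthetic.split_cohort(cohort, seed=seed)
    logger.info("split sizes: train=%d val=%d test=%d", len(train), len(val), len(test))

    train_stats = preprocessing.TrainStats.fit(train)
    logger.info("train-split standardization stats: %s", train_stats)

    images: Optional[dict] = None
    if cfg.use_images:
        images = {}
        pp = cfg.preprocessing
        img_dir = out / "images"
        if write_images:
            img_dir.mkdir(exist_ok=True)
        for i, (_, rec) in enumerate(cohort.iterrows()):
            pair = synthetic.render_radiograph(
                rec, image_size=cfg.image_size, seed=seed * 100003 + i
            )
            clean = preprocessing.preprocess_radiograph(
                pair,
                clip_limit=pp.clip_limit,
                tile_grid=pp.tile_grid,
                spatial_bw=pp.spatial_bw,
                range_bw=pp.range_bw,
                crop_fraction=pp.crop_fraction,
            )
            images[rec["id"]] = clean
            if write_images:
                Image.fromarray(clean.ap).save(img_dir / f"{rec['id']}_ap.png")
                Image.fromarray(clean.lateral).save(img_dir / f"{rec['id']}_lat.png")
        logger.info("rendered and preprocessed %d film pairs", len(images))

    features = {
        name: model.assemble_features(
            frame, train_stats, images, grid=cfg.model.image_grid, use_bmi=cfg.preprocessing.use_bmi
        )
        for name, frame in (("train", train), ("val", val), ("test", test))
    }

    components = {
        "femoral": ("femoral_size", cohort_cfg.n_femoral_classes),
        "tibial": ("tibial_size", cohort_cfg.n_tibial_classes),
    }
    outputs, codebooks, counts, truths, freqs = {}, {}, {}, {}, {}
    for comp, (col, n_classes) in components.items():
        classes = list(range(1, n_classes + 1))
        train_counts = train[col].value_counts().reindex(classes, fill_value=0)
        comp_freqs = (train_counts / train_counts.sum()).to_numpy()
        cb = _build_codebook(cfg, comp_freqs, classes, seed)
        cb.save(out / f"codebook_{comp}.json")
        logger.info("%s codebook: scheme=%s n=%d d_min=%s active=%d",
                    comp, cb.scheme, cb.n, cb.d_min, int(cb.active_bits.sum()))

        pred_cfg = model.PredictorConfig(
            head="ecoc",
            n_out=cb.n,
            seed=seed,
            hidden=cfg.model.hidden,
            learning_rate=cfg.model.learning_rate,
            epochs=cfg.model.epochs,
            batch_size=cfg.model.batch_size,
            patience=cfg.model.patience,
            bit_weighting=cfg.loss.bit_weighting,
        )
        predictor = model.train_predictor(
            (features["train"], train[col].tolist()),
            (features["val"], val[col].tolist()),
            pred_cfg,
            codebook=cb,
        )
        predictor.save(out / f"predictor_{comp}.json")
        out_probs = model.predict_outputs(predictor, features["test"])
        pd.DataFrame(out_probs, index=test["id"]).to_csv(out / f"predictions_{comp}.csv")

        outputs[comp] = out_probs
        codebooks[comp] = cb
        counts[comp] = BitLabelCounts.from_labels(train[col].tolist(), cb)
        truths[comp] = test[col].tolist()
        freqs[comp] = comp_freqs

    report = evaluation.compare_methods(
        outputs,
        codebooks,
        counts,
        truths,
        train_freqs=freqs,
        k=cfg.decode.top_k,
        seed=seed,
        config=cfg.model_dump(),
    )
    report.save(out / "report.json")
    logger.info("top-%d accuracies: %s", cfg.decode.top_k, report.method_top_k)
    return report
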