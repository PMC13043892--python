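"""End-to-end experiment orchestration.

The showcased experiment: train on clean images from a constant-size history
(source domain), test on noisy dosage-based images from a bottleneck history
(target domain), comparing a source-only CNN against a DANN that also sees
unlabeled target images.  Every stage draws its randomness from a named
substream of one master seed, so staged execution on stored artifacts and a
monolithic run produce identical results.

Seed splitting: ``substream(master, stage, index)`` hashes the stage name
with CRC-32 and feeds ``SeedSequence([master, crc32(stage), index])``; all
derived integer seeds stay below 2**31.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from . import msio
from .evaluate import EvalReport, mean_gradcam
from .images import ImageSet, image_from_dosage, image_from_haplotypes, render_heatmap
from .nn import (
    ArchitectureSpec,
    Classifier,
    ConvBlock,
    TrainConfig,
    build_cnn,
    build_dann,
    predict_scores,
    save_classifier,
    load_classifier,
    train_dann,
    train_source_only,
)
from .reads import collapse_to_genotypes, dosage_from_reads, simulate_pileup, DosageMatrix
from .sim import (
    Demography,
    HaplotypeSample,
    SimParams,
    SweepParams,
    simulate_neutral,
    simulate_sweep,
)

__all__ = [
    "ExperimentConfig",
    "ReadsConfig",
    "EncoderConfig",
    "CountsConfig",
    "ConfigError",
    "StageError",
    "reduced_config",
    "substream",
    "subseed",
    "config_hash",
    "run_experiment",
    "build_datasets",
    "train_models",
    "evaluate_models",
    "STAGES",
]


class ConfigError(ValueError):
    """Invalid experiment configuration; message names the offending field."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def substream(master: int, stage: str, index: int = 0) -> np.random.Generator:
    """Independent generator for (master seed, stage name, replicate index)."""
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([int(master) & 0x7FFFFFFF, key, int(index)])
    )


def subseed(master: int, stage: str, index: int = 0) -> int:
    """Integer seed (< 2**31) derived from the same splitter, for provenance."""
    return int(substream(master, stage, index).integers(1, 2**31 - 1))


# ----------------------------------------------------------------------
# Configuration


@dataclass
class ReadsConfig:
    mean_depth: float = 5.0
    error: float = 0.005
    apply_to_source: bool = False
    apply_to_target: bool = True


@dataclass
class EncoderConfig:
    W: int = 64
    sort_rows: bool = False


@dataclass
class CountsConfig:
    source_per_class: int = 1000
    target_unlabeled: int = 500
    target_test_per_class: int = 500


@dataclass
class ExperimentConfig:
    seed: int = 0
    locus: SimParams = field(default_factory=SimParams)
    source_demography: Demography = field(
        default_factory=lambda: Demography.constant(500, duration=100)
    )
    target_demography: Demography = field(default_factory=lambda: Demography.bottleneck(500))
    sweep: SweepParams = field(default_factory=SweepParams)
    reads: ReadsConfig = field(default_factory=ReadsConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    channels: Tuple[int, ...] = (16, 32, 64)
    pools: Optional[Tuple[Tuple[int, int], ...]] = None  # per-block; default 1x2
    feature_pooling: str = "flatten"
    batch_norm: bool = True
    label_hidden: Tuple[int, ...] = (64,)
    domain_hidden: Tuple[int, ...] = (64,)
    training: TrainConfig = field(default_factory=TrainConfig)
    counts: CountsConfig = field(default_factory=CountsConfig)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        c = self.counts
        for name in ("source_per_class", "target_unlabeled", "target_test_per_class"):
            if getattr(c, name) < 1:
                raise ConfigError(f"counts.{name} must be >= 1")
        if self.encoder.W < 1:
            raise ConfigError("encoder.W must be >= 1")
        if not 0 <= self.reads.error < 0.5:
            raise ConfigError("reads.error must be in [0, 0.5)")
        if self.reads.mean_depth < 0:
            raise ConfigError("reads.mean_depth must be >= 0")
        for demo_name in ("source_demography", "target_demography"):
            try:
                self.locus.validate_against(getattr(self, demo_name))
            except ValueError as e:
                raise ConfigError(f"{demo_name}: {e}") from e
        # architecture must be realizable on the image shape
        try:
            self.architecture()
        except ValueError as e:
            raise ConfigError(f"architecture: {e}") from e

    def architecture(self) -> ArchitectureSpec:
        pools = self.pools
        if pools is None:
            pools = tuple((1, 2) for _ in self.channels)
        if len(pools) != len(self.channels):
            raise ConfigError("architecture.pools must match channels")
        return ArchitectureSpec(
            input_shape=(self.locus.n_sample, self.encoder.W),
            blocks=tuple(
                ConvBlock(ch, pool=tuple(p)) for ch, p in zip(self.channels, pools)
            ),
            label_hidden=tuple(self.label_hidden),
            domain_hidden=tuple(self.domain_hidden),
            feature_pooling=self.feature_pooling,
            batch_norm=self.batch_norm,
        )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "locus": dataclasses.asdict(self.locus),
            "source_demography": {"epochs": [[e.duration, e.size] for e in self.source_demography.epochs]},
            "target_demography": {"epochs": [[e.duration, e.size] for e in self.target_demography.epochs]},
            "sweep": dataclasses.asdict(self.sweep),
            "reads": dataclasses.asdict(self.reads),
            "encoder": dataclasses.asdict(self.encoder),
            "architecture": {
                "channels": list(self.channels),
                "pools": None if self.pools is None else [list(p) for p in self.pools],
                "feature_pooling": self.feature_pooling,
                "batch_norm": self.batch_norm,
                "label_hidden": list(self.label_hidden),
                "domain_hidden": list(self.domain_hidden),
            },
            "training": dataclasses.asdict(self.training),
            "counts": dataclasses.asdict(self.counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def section(name, builder, **extra):
            raw = d.get(name, {})
            if raw is None:
                raw = {}
            try:
                return builder(**{**raw, **extra})
            except (TypeError, ValueError) as e:
                raise ConfigError(f"{name}: {e}") from e

        arch = d.get("architecture", {}) or {}
        kwargs = dict(
            seed=int(d.get("seed", 0)),
            locus=section("locus", SimParams),
            sweep=section("sweep", SweepParams),
            reads=section("reads", ReadsConfig),
            encoder=section("encoder", EncoderConfig),
            training=section("training", TrainConfig),
            counts=section("counts", CountsConfig),
            channels=tuple(arch.get("channels", (16, 32, 64))),
            pools=(
                None
                if arch.get("pools") is None
                else tuple(tuple(p) for p in arch["pools"])
            ),
            feature_pooling=arch.get("feature_pooling", "flatten"),
            batch_norm=bool(arch.get("batch_norm", True)),
            label_hidden=tuple(arch.get("label_hidden", (64,))),
            domain_hidden=tuple(arch.get("domain_hidden", (64,))),
        )
        for name in ("source_demography", "target_demography"):
            if name in d:
                try:
                    kwargs[name] = Demography(
                        epochs=tuple((int(a), int(b)) for a, b in d[name]["epochs"])
                    )
                except (KeyError, TypeError, ValueError) as e:
                    raise ConfigError(f"{name}: {e}") from e
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ExperimentConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def reduced_config(
    seed: int = 0,
    source_per_class: int = 500,
    target_unlabeled: int = 250,
    target_test_per_class: int = 250,
    epochs: int = 12,
) -> ExperimentConfig:
    """The package's reduced-scale domain-shift experiment.

    A rescaled version of the showcased study sized for a single CPU: N=100
    diploids on a 20 kb locus with per-bp 4N*mu = 0.005 and 4N*r = 0.01 (the
    higher recombination keeps the hitchhiking footprint at roughly a quarter
    of the locus, so the sweep stays a localized central band), a strong hard
    sweep (s = 0.6, 2Ns = 120), and a target domain with a 5x / 0.5% error
    read layer plus a recent 10-fold bottleneck lasting 0.12*N generations.
    See docs/methods.md for the full rationale.
    """
    return ExperimentConfig(
        seed=seed,
        locus=SimParams(L=20_000.0, mu=1.25e-5, r=2.5e-5, n_sample=10),
        source_demography=Demography.constant(100, duration=20),
        target_demography=Demography(epochs=((5, 100), (12, 20), (6, 100))),
        sweep=SweepParams(s=0.6),
        reads=ReadsConfig(),
        encoder=EncoderConfig(W=64),
        channels=(8, 16, 32),
        pools=((2, 2), (1, 2), (5, 2)),
        feature_pooling="flatten",
        batch_norm=True,
        training=TrainConfig(epochs=epochs, batch_size=64),
        counts=CountsConfig(
            source_per_class=source_per_class,
            target_unlabeled=target_unlabeled,
            target_test_per_class=target_test_per_class,
        ),
    )


def config_hash(config: ExperimentConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# Dataset construction (shared by the in-memory API and the disk stages)

_DATASETS = ("source_train", "target_train", "target_test")


def _dataset_plan(config: ExperimentConfig) -> Dict[str, List[str]]:
    """Per-dataset ordered list of labels (index = replicate index)."""
    c = config.counts
    n_unl = c.target_unlabeled
    return {
        "source_train": ["neutral"] * c.source_per_class + ["sweep"] * c.source_per_class,
        # unlabeled mixture: the target panel contains both kinds of regions
        "target_train": ["neutral"] * ((n_unl + 1) // 2) + ["sweep"] * (n_unl // 2),
        "target_test": ["neutral"] * c.target_test_per_class
        + ["sweep"] * c.target_test_per_class,
    }


def simulate_dataset(config: ExperimentConfig, dataset: str) -> List[HaplotypeSample]:
    """All replicates of one dataset, each from its own seed substream."""
    plan = _dataset_plan(config)[dataset]
    domain = "source" if dataset.startswith("source") else "target"
    demography = (
        config.source_demography if domain == "source" else config.target_demography
    )
    samples = []
    for i, label in enumerate(plan):
        stage = f"sim/{dataset}/{label}"
        rng = substream(config.seed, stage, i)
        params = dataclasses.replace(config.locus, seed=subseed(config.seed, stage, i))
        if label == "sweep":
            s = simulate_sweep(params, demography, config.sweep, rng=rng, domain=domain)
        else:
            s = simulate_neutral(params, demography, rng=rng, domain=domain)
        samples.append(s)
    return samples


def _sample_to_image(
    config: ExperimentConfig, sample: HaplotypeSample, dataset: str, index: int
):
    """Exact-genotype or read-degraded image for one replicate."""
    use_reads = (
        config.reads.apply_to_source
        if sample.domain == "source"
        else config.reads.apply_to_target
    )
    W = config.encoder.W
    if not use_reads:
        img = image_from_haplotypes(sample, W=W)
    else:
        geno = collapse_to_genotypes(sample)
        rng = substream(config.seed, f"reads/{dataset}", index)
        pile = simulate_pileup(geno, config.reads.mean_depth, config.reads.error, rng=rng)
        dos = dosage_from_reads(pile)
        img = image_from_dosage(dos, sample.L, W=W, label=sample.label, domain=sample.domain)
    if config.encoder.sort_rows:
        order = np.argsort(-img.pixels.sum(axis=1), kind="stable")
        img.pixels = img.pixels[order]
    return img


def images_for_dataset(
    config: ExperimentConfig, dataset: str, samples: Sequence[HaplotypeSample]
) -> ImageSet:
    imgs = [_sample_to_image(config, s, dataset, i) for i, s in enumerate(samples)]
    return ImageSet.from_images(imgs)


def build_datasets(config: ExperimentConfig) -> Dict[str, ImageSet]:
    """Simulate and encode all three datasets in memory."""
    out = {}
    for ds in _DATASETS:
        out[ds] = images_for_dataset(config, ds, simulate_dataset(config, ds))
    return out


def train_models(
    config: ExperimentConfig, datasets: Dict[str, ImageSet]
) -> Dict[str, Classifier]:
    """Source-only CNN and source+unlabeled-target DANN, same init seed."""
    spec = config.architecture()
    tcfg = dataclasses.replace(config.training, seed=subseed(config.seed, "train"))
    cnn = train_source_only(build_cnn(spec, seed=tcfg.seed), datasets["source_train"],
                            config=tcfg)
    dann = train_dann(
        build_dann(spec, seed=tcfg.seed),
        datasets["source_train"],
        datasets["target_train"],
        config=tcfg,
    )
    return {"cnn": cnn, "dann": dann}


def evaluate_models(
    config: ExperimentConfig,
    models: Dict[str, Classifier],
    datasets: Dict[str, ImageSet],
) -> EvalReport:
    """Accuracy / ROC / power at 5% FPR on the labeled target test split,
    plus the (resubstitution) source numbers as a diagnostic."""
    report = EvalReport()
    for model_name, model in sorted(models.items()):
        for ds, domain in (("target_test", "target"), ("source_train", "source")):
            im = datasets[ds]
            scores = predict_scores(model, im)
            report.add(
                model_name,
                domain,
                scores[im.labels == 0],
                scores[im.labels == 1],
            )
    return report


def class_mean_maps(
    models: Dict[str, Classifier], images: ImageSet, max_per_class: int = 1000
) -> Dict[str, np.ndarray]:
    """Class-mean Grad-CAM maps on (source) images, keyed model/class."""
    maps = {}
    for model_name, model in sorted(models.items()):
        for class_index, class_name in enumerate(("neutral", "sweep")):
            sel = np.flatnonzero(images.labels == class_index)[:max_per_class]
            sm = mean_gradcam(model, images.subset(sel), class_index)
            maps[f"{model_name}/{class_name}"] = sm.values
    return maps


# ----------------------------------------------------------------------
# Disk stages (CLI-facing); each reads stored artifacts and writes its own.


def _provenance(config: ExperimentConfig) -> dict:
    return {"config_hash": config_hash(config), "master_seed": config.seed}


def _stale_guard(workdir: Path, stage: str):
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (workdir / "STALE").write_text(f"stage {stage} failed: {exc}\n")
                raise StageError(stage, exc) from exc
            return False

    workdir.mkdir(parents=True, exist_ok=True)
    return _Guard()


def stage_simulate(config: ExperimentConfig, workdir: Union[str, Path]) -> None:
    workdir = Path(workdir)
    with _stale_guard(workdir, "simulate"):
        for ds in _DATASETS:
            store = msio.ReplicateStore(workdir / "sim" / ds)
            samples = simulate_dataset(config, ds)
            store.save(samples)


def stage_reads(config: ExperimentConfig, workdir: Union[str, Path]) -> None:
    """Degrade stored target haplotypes into GL/dosage arrays."""
    workdir = Path(workdir)
    with _stale_guard(workdir, "reads"):
        outdir = workdir / "reads"
        outdir.mkdir(parents=True, exist_ok=True)
        for ds in _DATASETS:
            domain = "source" if ds.startswith("source") else "target"
            use_reads = (
                config.reads.apply_to_source if domain == "source"
                else config.reads.apply_to_target
            )
            if not use_reads:
                continue
            samples = msio.ReplicateStore(workdir / "sim" / ds).load()
            arrays, meta = {}, []
            for i, s in enumerate(samples):
                geno = collapse_to_genotypes(s)
                rng = substream(config.seed, f"reads/{ds}", i)
                pile = simulate_pileup(geno, config.reads.mean_depth, config.reads.error, rng)
                dos = dosage_from_reads(pile)
                arrays[f"rep{i}_dosage"] = dos.dosage
                arrays[f"rep{i}_freq"] = dos.freq
                arrays[f"rep{i}_positions"] = s.positions
                meta.append({"label": s.label, "domain": s.domain, "L": s.L})
            np.savez(outdir / f"{ds}.npz", **arrays)
            (outdir / f"{ds}.json").write_text(
                json.dumps({"replicates": meta, "provenance": _provenance(config)},
                           sort_keys=True)
            )


def stage_encode(config: ExperimentConfig, workdir: Union[str, Path]) -> None:
    workdir = Path(workdir)
    with _stale_guard(workdir, "encode"):
        outdir = workdir / "images"
        outdir.mkdir(parents=True, exist_ok=True)
        W = config.encoder.W
        for ds in _DATASETS:
            domain = "source" if ds.startswith("source") else "target"
            use_reads = (
                config.reads.apply_to_source if domain == "source"
                else config.reads.apply_to_target
            )
            imgs = []
            if use_reads:
                meta = json.loads((workdir / "reads" / f"{ds}.json").read_text())
                with np.load(workdir / "reads" / f"{ds}.npz") as z:
                    for i, m in enumerate(meta["replicates"]):
                        dos = DosageMatrix(
                            dosage=z[f"rep{i}_dosage"],
                            freq=z[f"rep{i}_freq"],
                            positions=z[f"rep{i}_positions"],
                        )
                        imgs.append(
                            image_from_dosage(dos, m["L"], W=W, label=m["label"],
                                              domain=m["domain"])
                        )
            else:
                for s in msio.ReplicateStore(workdir / "sim" / ds).load():
                    imgs.append(image_from_haplotypes(s, W=W))
            if config.encoder.sort_rows:
                for img in imgs:
                    order = np.argsort(-img.pixels.sum(axis=1), kind="stable")
                    img.pixels = img.pixels[order]
            ImageSet.from_images(imgs).save(outdir / f"{ds}.npz",
                                            provenance=_provenance(config))


def stage_train(config: ExperimentConfig, workdir: Union[str, Path]) -> None:
    workdir = Path(workdir)
    with _stale_guard(workdir, "train"):
        datasets = {ds: ImageSet.load(workdir / "images" / f"{ds}.npz") for ds in _DATASETS}
        models = train_models(config, datasets)
        moddir = workdir / "models"
        moddir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        for name, model in models.items():
            save_classifier(model, moddir / f"{name}.npz")
            pd.DataFrame(model.history).to_csv(moddir / f"{name}_history.csv", index=False)


def stage_evaluate(config: ExperimentConfig, workdir: Union[str, Path]) -> EvalReport:
    workdir = Path(workdir)
    with _stale_guard(workdir, "evaluate"):
        datasets = {ds: ImageSet.load(workdir / "images" / f"{ds}.npz") for ds in _DATASETS}
        models = {
            name: load_classifier(workdir / "models" / f"{name}.npz")
            for name in ("cnn", "dann")
        }
        report = evaluate_models(config, models, datasets)
        payload = {"provenance": _provenance(config), "results": report.entries}
        (workdir / "report.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1) + "\n"
        )
        report.to_csv(workdir / "report.csv")
        return report


def stage_explain(config: ExperimentConfig, workdir: Union[str, Path]) -> Dict[str, np.ndarray]:
    workdir = Path(workdir)
    with _stale_guard(workdir, "explain"):
        source = ImageSet.load(workdir / "images" / "source_train.npz")
        models = {
            name: load_classifier(workdir / "models" / f"{name}.npz")
            for name in ("cnn", "dann")
        }
        maps = class_mean_maps(models, source)
        mapdir = workdir / "maps"
        mapdir.mkdir(parents=True, exist_ok=True)
        np.savez(mapdir / "gradcam.npz", **{k.replace("/", "_"): v for k, v in maps.items()})
        (mapdir / "gradcam.json").write_text(
            json.dumps({"maps": sorted(maps), "provenance": _provenance(config)},
                       sort_keys=True)
        )
        for key, values in maps.items():
            render_heatmap(values, mapdir / (key.replace("/", "_") + ".png"), cmap="viridis")
        return maps


STAGES = {
    "simulate": stage_simulate,
    "reads": stage_reads,
    "encode": stage_encode,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "explain": stage_explain,
}


def run_experiment(
    config: ExperimentConfig, workdir: Union[str, Path]
) -> Tuple[EvalReport, Dict[str, np.ndarray]]:
    """All stages in order on ``workdir``; returns (report, class-mean maps)."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stale = workdir / "STALE"
    if stale.exists():
        stale.unlink()
    (workdir / "provenance.json").write_text(
        json.dumps(_provenance(config), sort_keys=True) + "\n"
    )
    config.to_yaml(workdir / "config_used.yaml")
    stage_simulate(config, workdir)
    stage_reads(config, workdir)
    stage_encode(config, workdir)
    stage_train(config, workdir)
    report = stage_evaluate(config, workdir)
    maps = stage_explain(config, workdir)
    return report, maps
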