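"""Run orchestration: pretrain → finetune → generate → evaluate.

A single human-editable YAML config drives the whole workflow; one global
seed deterministically derives the per-stage seeds, so any stage can be
re-run in isolation and reproduce byte-identical outputs.  Every run writes
its resolved config and a manifest (config hash, seeds, stage list) next to
its artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import adapt, datasets, fixtures, gan, metrics
from .chem import parse_smiles_file, write_smiles_file
from .codec import ToyCodec
from .gan import LatentWGAN, config_hash, derive_seeds, load_mlp, save_mlp

STAGES = ("pretrain", "finetune", "generate", "evaluate")


@dataclass
class RunConfig:
    out_dir: str = "runs/toy"
    seed: int = 0
    latent_dim: int = 16
    n_library: int = 48
    task: str = "halogen"
    shots: int = 5
    refs_file: str | None = None
    n_generate: int = 1000
    pretrain_epochs: int = 300
    pretrain_batch_size: int = 16
    finetune_epochs: int = 40
    finetune_batch_size: int = 1
    learning_rate: float = 1e-3
    gp_lambda: float = 10.0
    noise_dim: int = 32

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _codec(cfg: RunConfig) -> ToyCodec:
    library = fixtures.toy_molecule_library(
        fixtures.FixtureSpec(n_molecules=cfg.n_library)
    )
    return ToyCodec(library, latent_dim=cfg.latent_dim)


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in order; returns the artifact directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    seeds = dict(zip(STAGES, derive_seeds(cfg.seed, len(STAGES))))
    codec = _codec(cfg)
    write_smiles_file(codec.library, out / "library.smi")

    if "pretrain" in stages:
        wgan = LatentWGAN(
            noise_dim=cfg.noise_dim, gen_hidden=(64, 64), critic_hidden=(64, 64),
            epochs=cfg.pretrain_epochs, batch_size=cfg.pretrain_batch_size,
            learning_rate=cfg.learning_rate, gp_lambda=cfg.gp_lambda,
            random_state=seeds["pretrain"],
        ).fit(codec.encode(codec.library))
        save_mlp(out / "generator.npz", wgan.generator_,
                 meta={"noise_dim": cfg.noise_dim})
        save_mlp(out / "critic.npz", wgan.critic_)
        wgan.history_.to_csv(out / "pretrain_history.csv", index=False)

    if "finetune" in stages:
        generator = _load_stage(out, "generator.npz", "pretrain")
        critic = _load_stage(out, "critic.npz", "pretrain")
        refs = _reference_molecules(cfg, codec, seeds["finetune"])
        write_smiles_file(refs, out / "refs.smi")
        adaptor, critic_ft, history = adapt.finetune(
            refs, codec, generator, critic,
            adapt.init_adaptor(cfg.noise_dim), adapt.FreezePolicy(),
            adapt.FinetuneConfig(
                epochs=cfg.finetune_epochs, batch_size=cfg.finetune_batch_size,
                learning_rate=cfg.learning_rate, gp_lambda=cfg.gp_lambda,
                seed=seeds["finetune"],
            ),
        )
        np.savez(out / "adaptor.npz", A=adaptor.A, b=adaptor.b)
        save_mlp(out / "critic_finetuned.npz", critic_ft)
        history.to_csv(out / "finetune_history.csv", index=False)

    if "generate" in stages:
        generator = _load_stage(out, "generator.npz", "pretrain")
        adaptor = load_adaptor(out / "adaptor.npz")
        mols = adapt.generate(adaptor, generator, codec, n=cfg.n_generate,
                              seed=seeds["generate"])
        write_smiles_file(mols, out / "generated.smi")

    if "evaluate" in stages:
        gen_file = out / "generated.smi"
        if not gen_file.exists():
            raise FileNotFoundError("no generated.smi; run the generate stage first")
        mols = parse_smiles_file(gen_file)
        predicate = (datasets.task_predicate(cfg.task)
                     if cfg.task in datasets.STRUCTURE_TASKS else None)
        report = metrics.evaluate(mols, predicate=predicate,
                                  score_names=("QED", "PLOGP_RAW"),
                                  subsample_seed=seeds["evaluate"])
        (out / "report.tsv").write_text(report.to_text())
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))

    manifest = {
        "config_hash": config_hash(cfg),
        "seeds": seeds,
        "stages": list(stages),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _load_stage(out: Path, name: str, producer: str):
    path = out / name
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {name}; run the {producer!r} stage first"
        )
    mlp, _ = load_mlp(path)
    return mlp


def load_adaptor(path: str | Path) -> adapt.AdaptorState:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"missing adaptor checkpoint {path}; run the 'finetune' stage first"
        )
    data = np.load(path)
    return adapt.AdaptorState(A=data["A"], b=data["b"])


def _reference_molecules(cfg: RunConfig, codec: ToyCodec, seed: int):
    if cfg.refs_file:
        return parse_smiles_file(cfg.refs_file)
    ds = datasets.build_task_datasets(
        codec.library, cfg.task, sizes=(cfg.shots,), seed=seed
    )[0]
    return ds.molecules
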