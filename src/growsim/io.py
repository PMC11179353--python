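"""Checkpoint serialization: weights plus a full config manifest."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .conditioning import EmbeddingConfig
from .critic import Critic, CriticSpec
from .generator import Generator, GeneratorSpec


def _embedding_from_dict(d: dict) -> EmbeddingConfig:
    d = dict(d)
    d["signature"] = tuple(d["signature"])
    return EmbeddingConfig(**d)


def spec_to_dict(spec) -> dict:
    return asdict(spec)


def generator_spec_from_dict(d: dict) -> GeneratorSpec:
    d = dict(d)
    d["embedding"] = _embedding_from_dict(d["embedding"])
    return GeneratorSpec(**d)


def critic_spec_from_dict(d: dict) -> CriticSpec:
    d = dict(d)
    d["embedding"] = _embedding_from_dict(d["embedding"])
    return CriticSpec(**d)


def save_checkpoint(path, generator: Generator, critic=None, seed=None) -> None:
    """Write weights and the architecture manifest to one ``.npz``."""
    manifest = {
        "generator_spec": spec_to_dict(generator.spec),
        "critic_spec": spec_to_dict(critic.spec) if critic is not None else None,
        "seed": seed,
    }
    arrays = {"manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)}
    for k, v in generator.state_dict().items():
        arrays[f"g::{k}"] = v
    if critic is not None:
        for k, v in critic.state_dict().items():
            arrays[f"d::{k}"] = v
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Rebuild (generator, critic-or-None, manifest) from a checkpoint.

    Loading reproduces the saved model bit-exactly: generation from a
    loaded checkpoint equals generation from the saved model for the
    same inputs and noise."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint {path}")
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        g_state = {
            k[3:]: data[k] for k in data.files if k.startswith("g::")
        }
        d_state = {
            k[3:]: data[k] for k in data.files if k.startswith("d::")
        }
    gen_spec = generator_spec_from_dict(manifest["generator_spec"])
    rng = np.random.default_rng(0)  # immediately overwritten by the state dict
    generator = Generator(gen_spec, rng)
    generator.load_state_dict(g_state)
    generator.eval()
    critic = None
    if manifest["critic_spec"] is not None and d_state:
        critic = Critic(critic_spec_from_dict(manifest["critic_spec"]), rng)
        critic.load_state_dict(d_state)
        critic.eval()
    return generator, critic, manifest
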