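"""Adversarial training of the conditional Wasserstein GAN.

Pair sampling iterates over every training image as the input image and
draws a random other image of the same sequence as the reference; the
treatment class never changes within a sequence, so c_in = c_gen during
training.  Augmentations (flips, 90° rotations, slight translations,
ShadowOut) are applied identically to both images of a pair.  The
critic maximizes E[D(ref)] - E[D(gen)] subject to a gradient penalty on
ε-blends of reference and generated images; the generator minimizes
-E[D(gen)].  The best epoch is the one with the lowest validation
perceptual distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import shift as nd_shift

from .conditioning import ConditionSet
from .critic import Critic, CriticSpec
from .generator import Generator, GeneratorSpec, draw_noise, from_model_range, to_model_range
from .metrics import RandomConvFeatures, lpips
from .nn import Adam, tensor as T


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class AugmentParams:
    p_flip: float = 0.5
    p_rot90: float = 0.5
    translate_frac: float = 0.05
    p_shadow: float = 0.5
    shadow_alpha: Tuple[float, float] = (0.3, 0.7)
    shadow_frac: Tuple[float, float] = (0.2, 0.5)

    @classmethod
    def identity(cls):
        return cls(p_flip=0.0, p_rot90=0.0, translate_frac=0.0, p_shadow=0.0)


@dataclass(frozen=True)
class TrainConfig:
    """Full-scale defaults: Adam lr 1e-4, batch 64, 5000 epochs, model
    selection by lowest validation perceptual distance.  λ_GP = 10 and
    n_critic = 5 follow common WGAN-GP practice."""

    lambda_gp: float = 10.0
    lr: float = 1e-4
    betas: Tuple[float, float] = (0.0, 0.9)
    n_critic: int = 5
    epochs: int = 5000
    batch_size: int = 64
    augment: AugmentParams = field(default_factory=AugmentParams)
    recon_weight: float = 0.0  # optional paired-L1 stabilizer, off by default
    val_every: int = 1
    checkpoint_every: int = 0  # 0: only best + last
    max_val_pairs: int = 32

    def __post_init__(self):
        if self.lambda_gp < 0:
            raise ValueError("lambda_gp must be >= 0")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")


@dataclass
class TrainingPair:
    x_in: np.ndarray
    x_ref: np.ndarray
    input_idx: int
    ref_idx: int
    t_in: int
    t_gen: int
    treatment_id: int
    b_in: Optional[np.ndarray]
    b_gen: Optional[np.ndarray]

    @property
    def delta_t(self) -> int:
        return self.t_gen - self.t_in


# ---------------------------------------------------------------------
# sampling and augmentation
# ---------------------------------------------------------------------

def sample_pair(dataset, index: int, rng) -> TrainingPair:
    """Input image = dataset[index]; reference drawn uniformly from the
    other images of the same sequence (itself if the sequence has only
    one image)."""
    rec = dataset.records[index]
    seq = dataset.sequence_indices()[rec.sequence_id]
    if len(seq) == 0:
        raise ValueError(f"empty sequence {rec.sequence_id!r}")
    others = seq[seq != index]
    ref_idx = int(rng.choice(others)) if len(others) else int(index)
    ref = dataset.records[ref_idx]
    assert ref.treatment_id == rec.treatment_id  # c_in = c_gen within a sequence
    return TrainingPair(
        x_in=rec.image,
        x_ref=ref.image,
        input_idx=index,
        ref_idx=ref_idx,
        t_in=rec.t,
        t_gen=ref.t,
        treatment_id=rec.treatment_id,
        b_in=rec.b,
        b_gen=ref.b,
    )


def _shadowout(img, y0, x0, h, w, alpha):
    out = img.copy()
    out[y0 : y0 + h, x0 : x0 + w] *= alpha
    return out


def augment_pair(x_in, x_ref, rng, params: AugmentParams = AugmentParams()):
    """One transform draw applied identically to both images of a pair.

    ShadowOut multiplies a random rectangle by an opacity alpha < 1
    (alpha = 1 degenerates to a no-op, alpha = 0 to CutOut)."""
    if x_in.shape != x_ref.shape:
        raise ValueError("pair images must share a shape")
    a, b = np.asarray(x_in, dtype=np.float32), np.asarray(x_ref, dtype=np.float32)
    size = a.shape[0]

    if rng.random() < params.p_flip:
        a, b = a[:, ::-1], b[:, ::-1]
    if rng.random() < params.p_flip:
        a, b = a[::-1], b[::-1]
    if rng.random() < params.p_rot90:
        k = int(rng.integers(1, 4))
        a, b = np.rot90(a, k), np.rot90(b, k)
    if params.translate_frac > 0:
        max_px = params.translate_frac * size
        dy, dx = rng.uniform(-max_px, max_px, size=2)
        if abs(dy) > 1e-9 or abs(dx) > 1e-9:
            a = nd_shift(a, (dy, dx, 0), order=1, mode="nearest")
            b = nd_shift(b, (dy, dx, 0), order=1, mode="nearest")
    if rng.random() < params.p_shadow:
        frac = rng.uniform(*params.shadow_frac)
        h = w = max(int(frac * size), 1)
        y0 = int(rng.integers(0, size - h + 1))
        x0 = int(rng.integers(0, size - w + 1))
        alpha = rng.uniform(*params.shadow_alpha)
        a = _shadowout(a, y0, x0, h, w, alpha)
        b = _shadowout(b, y0, x0, h, w, alpha)
    return np.ascontiguousarray(a), np.ascontiguousarray(b)


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def blend(x_ref, x_gen, eps) -> np.ndarray:
    """Convex combination ε X_ref + (1-ε) X_gen, ε per batch element."""
    eps = np.asarray(eps, dtype=float).reshape(-1, *([1] * (np.ndim(x_ref) - 1)))
    xr = x_ref.data if isinstance(x_ref, T.Tensor) else np.asarray(x_ref)
    xg = x_gen.data if isinstance(x_gen, T.Tensor) else np.asarray(x_gen)
    return (eps * xr + (1.0 - eps) * xg).astype(xr.dtype)


def gradient_penalty(critic_fn, x_hat, lambda_gp: float) -> T.Tensor:
    """λ_GP * mean_batch (||∇_x̂ D||₂ − 1)², the norm taken over all
    pixels and channels of each blended image.

    ``critic_fn`` maps a batch image tensor to per-element scores with
    the conditioning context already bound.  Differentiable w.r.t. the
    critic parameters via double backprop."""
    x_hat = T.Tensor(np.asarray(x_hat), requires_grad=True)
    scores = critic_fn(x_hat)
    g, = T.grad(scores.sum(), [x_hat], create_graph=True)
    if not np.all(np.isfinite(g.data)):
        raise TrainingDivergedError("non-finite gradient in penalty term")
    sq = T.tsum(g * g, axis=tuple(range(1, g.ndim)))
    norm = T.sqrt(sq + T.Tensor(1e-12))
    one = T.Tensor(1.0)
    return T.Tensor(float(lambda_gp)) * ((norm - one) * (norm - one)).mean()


def wgan_losses(batch, generator, critic, lambda_gp, rng, recon_weight=0.0):
    """(critic loss, generator loss) for one batch of training pairs.

    Critic loss = E[D(gen)] − E[D(ref)] + GP (descent on this ascends
    the CWGAN objective); generator loss = −E[D(gen)]."""
    x_in, x_ref, y_in, y_gen = batch
    z = draw_noise(rng, x_in.shape[0], generator.spec.z_dim)
    x_gen = generator(x_in, y_in, y_gen, z)

    d_gen = critic(x_gen, x_in, y_in, y_gen)
    d_ref = critic(T.Tensor(x_ref), T.Tensor(x_in), y_in, y_gen)

    eps = rng.random(x_in.shape[0])
    x_hat = blend(x_ref, x_gen.detach(), eps)
    gp = gradient_penalty(
        lambda xh: critic(xh, T.Tensor(x_in), y_in, y_gen), x_hat, lambda_gp
    )
    critic_loss = d_gen.mean() - d_ref.mean() + gp
    gen_loss = -d_gen.mean()
    if recon_weight > 0:
        diff = x_gen - T.Tensor(x_ref)
        gen_loss = gen_loss + T.Tensor(recon_weight) * T.sqrt(diff * diff + T.Tensor(1e-8)).mean()
    return critic_loss, gen_loss, gp


# ---------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------

@dataclass
class TrainResult:
    log: List[dict]
    best_epoch: int
    best_val_lpips: float
    generator: Generator
    critic: Critic
    best_state: dict
    checkpoint_dir: Optional[str] = None

    def best_epoch_is_argmin(self) -> bool:
        vals = [(e["val_lpips"], e["epoch"]) for e in self.log if e.get("val_lpips") is not None]
        return min(vals)[1] == self.best_epoch if vals else False


def _make_condition(dataset, indices, role, signature, b_override=None):
    md = dataset.metadata
    t = md["t"].to_numpy()[indices]
    c = md["treatment_id"].to_numpy()[indices] if "c" in signature else None
    b = None
    if "b" in signature:
        b = md[["bm_sw", "bm_fb"]].to_numpy(dtype=float)[indices]
        if b_override is not None:
            b = b_override
    return ConditionSet(t=t, c=c, b=b, role=role)


def condition_builder(signature):
    """Build a ConditionSet for dataset rows under a model signature."""

    def build(dataset, indices, role):
        return _make_condition(dataset, np.asarray(indices), role, signature)

    return build


def _batch_arrays(dataset, idxs, rng, config, signature):
    pairs = [sample_pair(dataset, int(i), rng) for i in idxs]
    xs, rs = [], []
    for p in pairs:
        a, b = augment_pair(p.x_in, p.x_ref, rng, config.augment)
        xs.append(a)
        rs.append(b)
    x_in = to_model_range(np.stack(xs))
    x_ref = to_model_range(np.stack(rs))
    in_idx = np.array([p.input_idx for p in pairs])
    ref_idx = np.array([p.ref_idx for p in pairs])
    y_in = _make_condition(dataset, in_idx, "input", signature)
    y_gen = _make_condition(dataset, ref_idx, "target", signature)
    return x_in, x_ref, y_in, y_gen


def validation_lpips(generator, dataset, val_pairs, extractor, z_rng, signature):
    generator.eval()
    vals = []
    for start in range(0, len(val_pairs), 16):
        chunk = val_pairs[start : start + 16]
        x_in = to_model_range(
            np.stack([dataset.records[i].image for i, _ in chunk])
        )
        y_in = _make_condition(
            dataset, np.array([i for i, _ in chunk]), "input", signature
        )
        y_gen = _make_condition(
            dataset, np.array([j for _, j in chunk]), "target", signature
        )
        z = draw_noise(z_rng, len(chunk), generator.spec.z_dim)
        with T.no_grad():
            gen = from_model_range(generator(x_in, y_in, y_gen, z))
        for k, (_, j) in enumerate(chunk):
            vals.append(lpips(gen[k], dataset.records[j].image, extractor))
    generator.train()
    return float(np.mean(vals))


def train(
    dataset,
    gen_spec: GeneratorSpec,
    critic_spec: CriticSpec,
    config: TrainConfig,
    seed: int = 0,
    out_dir=None,
    extractor: Optional[RandomConvFeatures] = None,
    progress: bool = False,
) -> TrainResult:
    """Alternating WGAN-GP optimization, fully seeded.

    Runs ``config.n_critic`` critic updates per generator update, logs
    per-epoch mean losses and validation perceptual distance, keeps the
    state of the best (lowest validation distance) epoch, and aborts
    with a diagnostic if losses become non-finite.
    """
    from .io import save_checkpoint

    ss = np.random.SeedSequence(seed)
    ss_init, ss_data, ss_z, ss_val = ss.spawn(4)
    init_rng = np.random.default_rng(ss_init)
    data_rng = np.random.default_rng(ss_data)
    z_rng = np.random.default_rng(ss_z)

    signature = gen_spec.embedding.signature
    if critic_spec.embedding.signature != signature:
        raise ValueError("generator and critic condition signatures differ")
    generator = Generator(gen_spec, init_rng)
    critic = Critic(critic_spec, init_rng)

    if "b" in signature and generator.phi.cont is not None:
        mean, scale = dataset.biomass_stats()
        generator.phi.cont.set_standardization(mean, scale)
        critic.psi.cont.set_standardization(mean, scale)

    g_params = generator.parameters()
    d_params = critic.parameters()
    g_opt = Adam(g_params, lr=config.lr, betas=config.betas)
    d_opt = Adam(d_params, lr=config.lr, betas=config.betas)

    train_idx = dataset.indices_by_split("train")
    if len(train_idx) == 0:
        raise ValueError("dataset has no training split")

    # fixed validation pairs (input, reference) for model selection
    val_rng = np.random.default_rng(ss_val)
    val_pairs = []
    for sid, idxs in dataset.sequence_indices("val").items():
        for i in idxs:
            others = idxs[idxs != i]
            j = int(val_rng.choice(others)) if len(others) else int(i)
            val_pairs.append((int(i), j))
    val_rng.shuffle(val_pairs)
    val_pairs = val_pairs[: config.max_val_pairs]
    if extractor is None:
        extractor = RandomConvFeatures(seed=0)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    log: List[dict] = []
    best_val, best_epoch, best_state = np.inf, -1, None
    step = 0
    for epoch in range(1, config.epochs + 1):
        order = data_rng.permutation(train_idx)
        c_losses, g_losses, gps = [], [], []
        for start in range(0, len(order), config.batch_size):
            idxs = order[start : start + config.batch_size]
            if len(idxs) < 2:
                continue
            batch = _batch_arrays(dataset, idxs, data_rng, config, signature)
            x_in, x_ref, y_in, y_gen = batch

            # critic update
            z = draw_noise(z_rng, x_in.shape[0], gen_spec.z_dim)
            with T.no_grad():
                x_gen = generator(x_in, y_in, y_gen, z)
            d_gen = critic(T.Tensor(x_gen.data), T.Tensor(x_in), y_in, y_gen)
            d_ref = critic(T.Tensor(x_ref), T.Tensor(x_in), y_in, y_gen)
            eps = data_rng.random(x_in.shape[0])
            x_hat = blend(x_ref, x_gen, eps)
            gp = gradient_penalty(
                lambda xh: critic(xh, T.Tensor(x_in), y_in, y_gen),
                x_hat,
                config.lambda_gp,
            )
            d_loss = d_gen.mean() - d_ref.mean() + gp
            if not np.isfinite(d_loss.item()):
                raise TrainingDivergedError(
                    f"critic loss non-finite at epoch {epoch} step {step}"
                )
            d_opt.step(T.grad(d_loss, d_params))
            c_losses.append(d_loss.item())
            gps.append(gp.item())
            step += 1

            # generator update every n_critic critic updates
            if step % config.n_critic == 0:
                z = draw_noise(z_rng, x_in.shape[0], gen_spec.z_dim)
                x_gen = generator(x_in, y_in, y_gen, z)
                g_loss = -critic(x_gen, T.Tensor(x_in), y_in, y_gen).mean()
                if config.recon_weight > 0:
                    diff = x_gen - T.Tensor(x_ref)
                    g_loss = g_loss + T.Tensor(config.recon_weight) * T.sqrt(
                        diff * diff + T.Tensor(1e-8)
                    ).mean()
                if not np.isfinite(g_loss.item()):
                    raise TrainingDivergedError(
                        f"generator loss non-finite at epoch {epoch} step {step}"
                    )
                g_opt.step(T.grad(g_loss, g_params))
                g_losses.append(g_loss.item())

        entry = {
            "epoch": epoch,
            "critic_loss": float(np.mean(c_losses)) if c_losses else None,
            "generator_loss": float(np.mean(g_losses)) if g_losses else None,
            "gp": float(np.mean(gps)) if gps else None,
            "val_lpips": None,
        }
        if val_pairs and (epoch % config.val_every == 0 or epoch == config.epochs):
            entry["val_lpips"] = validation_lpips(
                generator, dataset, val_pairs, extractor, z_rng, signature
            )
            if entry["val_lpips"] < best_val:
                best_val = entry["val_lpips"]
                best_epoch = epoch
                best_state = {
                    "generator": generator.state_dict(),
                    "critic": critic.state_dict(),
                }
        log.append(entry)
        if progress:  # pragma: no cover
            print(
                f"epoch {epoch}: D {entry['critic_loss']:.3f} "
                f"G {entry['generator_loss'] if entry['generator_loss'] else float('nan'):.3f} "
                f"GP {entry['gp']:.3f} val {entry['val_lpips']}"
            )
        if out_dir is not None:
            with open(out_dir / "log.jsonl", "a") as fh:
                fh.write(json.dumps(entry) + "\n")
            if config.checkpoint_every and epoch % config.checkpoint_every == 0:
                save_checkpoint(
                    out_dir / f"epoch_{epoch:05d}.npz", generator, critic, seed=seed
                )

    if best_state is None:
        best_epoch = config.epochs
        best_val = float("nan")
        best_state = {
            "generator": generator.state_dict(),
            "critic": critic.state_dict(),
        }
    if out_dir is not None:
        save_checkpoint(out_dir / "last.npz", generator, critic, seed=seed)
        generator.load_state_dict(best_state["generator"])
        critic.load_state_dict(best_state["critic"])
        save_checkpoint(out_dir / "best.npz", generator, critic, seed=seed)
    else:
        generator.load_state_dict(best_state["generator"])
        critic.load_state_dict(best_state["critic"])

    return TrainResult(
        log=log,
        best_epoch=best_epoch,
        best_val_lpips=float(best_val),
        generator=generator,
        critic=critic,
        best_state=best_state,
        checkpoint_dir=str(out_dir) if out_dir is not None else None,
    )
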