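"""Losses and adversarial training loops for both staining routes.

Supervised (paired) route — discriminator loss

    L_D = D(z_generated)^2 + (1 - D(z_target))^2

halved (weight 0.5) before each update to slow the discriminator down, and
generator loss

    L_G = lambda * MAE(z_generated, z_target) + (1 - D(z_generated))^2

with lambda = 10.  ``D(.)`` is the mean of the PatchGAN sigmoid map.  The
least-squares form printed above is the default for both routes; a binary
cross-entropy option for the paired discriminator is available in the
config.

Unsupervised (unpaired) route — the cycle objective

    L = L_D1 + L_id1 + lambda * L_cyc_forward + lambda * L_cyc_backward

with weights 1 : 5 : 10 : 10, an MSE adversarial term, and MAE identity and
cycle terms.  The adversarial and identity terms of the second
generator/discriminator pair are optional flags, off by default.

Training uses batch size one, Adam (lr 2e-4, beta1 0.5), alternating
discriminator-then-generator updates with gradients never shared between
the two, per-epoch reshuffling from the run seed, and a generator
checkpoint every ``checkpoint_interval`` epochs.  Identical seed and data
give an identical loss trace and identical final weights.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    DiscriminatorSpecPatchGAN,
    GeneratorSpecResNet,
    GeneratorSpecUNet,
    PatchGANDiscriminator,
    ResNetGenerator,
    UNetGenerator,
    aggregate_map,
    init_weights,
)
from .nn import Adam
from .preprocessing import invert_contrast, scale_to_model_range, unscale_from_model_range

__all__ = [
    "TrainConfig",
    "LossRecord",
    "Checkpoint",
    "TrainResult",
    "discriminator_loss",
    "generator_loss_pix2pix",
    "cycle_objective",
    "make_supervised_patches",
    "train_pix2pix",
    "train_cyclegan",
    "select_checkpoint",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 1
    learning_rate: float = 2e-4
    beta1: float = 0.5
    lambda_mae: float = 10.0
    cycle_weights: Tuple[float, float, float, float] = (1.0, 5.0, 10.0, 10.0)  # adv, id, cyc_f, cyc_b
    d_loss_weight: float = 0.5
    halve_cycle_d_loss: bool = True  # apply the 50% slow-down to both cycle discriminators
    adversarial_form: str = "lsq"  # "lsq" (the printed squared-error form) or "bce"
    use_d2_adversarial: bool = False  # optional second-generator adversarial term
    use_identity_g2: bool = False
    init_sigma: float = 0.02
    checkpoint_interval: int = 5
    seed: int = 0
    # architecture profile
    unet_spec: GeneratorSpecUNet = field(default_factory=GeneratorSpecUNet)
    resnet_spec: GeneratorSpecResNet = field(default_factory=GeneratorSpecResNet)
    disc_spec: DiscriminatorSpecPatchGAN = field(default_factory=DiscriminatorSpecPatchGAN)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.cycle_weights) or self.lambda_mae < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epochs % self.checkpoint_interval:
            raise ValueError("checkpoint_interval must divide epochs")
        if self.adversarial_form not in ("lsq", "bce"):
            raise ValueError("adversarial_form must be 'lsq' or 'bce'")

    @classmethod
    def reduced(cls, **kw) -> "TrainConfig":
        """CPU profile: 64×64 patches, filters/8, short runs."""
        kw.setdefault("epochs", 5)
        kw.setdefault("checkpoint_interval", kw["epochs"])
        kw.setdefault("unet_spec", GeneratorSpecUNet.reduced())
        kw.setdefault("resnet_spec", GeneratorSpecResNet.reduced())
        kw.setdefault("disc_spec", DiscriminatorSpecPatchGAN.reduced())
        return cls(**kw)


@dataclass
class LossRecord:
    step: int
    epoch: int
    d_loss: float
    g_loss: float
    terms: Dict[str, float] = field(default_factory=dict)


@dataclass
class Checkpoint:
    epoch: int
    state: dict
    spec: object
    extra_state: Optional[dict] = None  # second generator for the cycle route

    def save(self, path: Path, seed: Optional[int] = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{k: v for k, v in self.state.items()})
        manifest = {"epoch": self.epoch, "spec": repr(self.spec), "seed": seed}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


@dataclass
class TrainResult:
    checkpoints: List[Checkpoint]
    losses: List[LossRecord]
    generator: object
    discriminator: object = None
    generator2: object = None


# ---------------------------------------------------------------------------
# loss arithmetic (scalar level, unit-testable)
# ---------------------------------------------------------------------------

def discriminator_loss(
    d_on_generated: float,
    d_on_target: float,
    d_loss_weight: float = 0.5,
    form: str = "lsq",
) -> Tuple[float, float]:
    """Return ``(raw, weighted)`` discriminator loss from the two aggregated
    map probabilities."""
    for v in (d_on_generated, d_on_target):
        if not 0.0 <= v <= 1.0:
            raise ValueError("discriminator outputs must lie in [0, 1]")
    if form == "lsq":
        raw = d_on_generated**2 + (1.0 - d_on_target) ** 2
    elif form == "bce":
        eps = 1e-12
        raw = -np.log(1.0 - d_on_generated + eps) - np.log(d_on_target + eps)
    else:
        raise ValueError("form must be 'lsq' or 'bce'")
    return float(raw), float(d_loss_weight * raw)


def generator_loss_pix2pix(
    z_generated: np.ndarray,
    z_target: np.ndarray,
    d_on_generated: float,
    lambda_mae: float = 10.0,
) -> Tuple[float, Dict[str, float]]:
    """MAE-plus-adversarial generator loss of the paired route."""
    zg, zt = np.asarray(z_generated), np.asarray(z_target)
    if zg.shape != zt.shape:
        raise ValueError("generated and target patches must share a shape")
    if not 0.0 <= d_on_generated <= 1.0:
        raise ValueError("discriminator output must lie in [0, 1]")
    mae = float(np.mean(np.abs(zg - zt)))
    adv = float((1.0 - d_on_generated) ** 2)
    return lambda_mae * mae + adv, {"mae": mae, "adv": adv}


def cycle_objective(
    g1,
    g2,
    d1,
    nlm_patch: np.ndarray,
    he_patch: np.ndarray,
    weights: Tuple[float, float, float, float] = (1.0, 5.0, 10.0, 10.0),
) -> Dict[str, float]:
    """Evaluate the unpaired objective's per-term values (no updates).

    ``g1``/``g2``/``d1`` may be networks or plain callables; patches are in
    the model range [-1, 1].
    """
    if nlm_patch is None or he_patch is None:
        raise ValueError("the cycle objective needs one patch from each domain")
    w_adv, w_id, w_f, w_b = weights

    def run(net, x):
        return net.forward(x, train=False) if hasattr(net, "forward") else net(x)

    fake_he = run(g1, nlm_patch)
    adv = float((1.0 - _d_prob(d1, fake_he)) ** 2) if d1 is not None else 0.0
    identity = float(np.mean(np.abs(run(g1, he_patch) - he_patch)))
    cyc_f = float(np.mean(np.abs(run(g2, fake_he) - nlm_patch)))
    cyc_b = float(np.mean(np.abs(run(g1, run(g2, he_patch)) - he_patch)))
    total = w_adv * adv + w_id * identity + w_f * cyc_f + w_b * cyc_b
    return {
        "adv": adv,
        "identity": identity,
        "cycle_forward": cyc_f,
        "cycle_backward": cyc_b,
        "weighted_total": total,
    }


def _d_prob(d, x) -> float:
    m = d.forward(x, train=False) if hasattr(d, "forward") else d(x)
    return aggregate_map(np.asarray(m))


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def make_supervised_patches(pairs: Sequence[Tuple[np.ndarray, np.ndarray]]):
    """Turn raw 8-bit (NLM, H&E) patch pairs into model-range training pairs.

    Applies the training-route contrast inversion to the NLM side only, then
    scales both to [-1, 1] in (C, H, W) layout.
    """
    out = []
    for nlm, he in pairs:
        x = scale_to_model_range(invert_contrast(nlm)).transpose(2, 0, 1)
        y = scale_to_model_range(he).transpose(2, 0, 1)
        out.append((x, y))
    return out


def _check_finite(value: float, what: str, record: LossRecord) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"{what} became non-finite at step {record.step}: {record}")


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------

def _adv_gen_grad(p: float, n_map: int, form: str) -> float:
    """d/d(map element) of the generator adversarial term."""
    if form == "lsq":
        return -2.0 * (1.0 - p) / n_map
    eps = 1e-12
    return -1.0 / (p + eps) / n_map  # -log D(z_gen)


def _adv_disc_grads(p_fake: float, p_real: float, weight: float, n_map: int, form: str) -> Tuple[float, float]:
    if form == "lsq":
        return 2.0 * weight * p_fake / n_map, -2.0 * weight * (1.0 - p_real) / n_map
    eps = 1e-12
    return weight / (1.0 - p_fake + eps) / n_map, -weight / (p_real + eps) / n_map


def train_pix2pix(
    paired_patches: Sequence[Tuple[np.ndarray, np.ndarray]],
    config: Optional[TrainConfig] = None,
    out_dir: Optional[Path] = None,
) -> TrainResult:
    """Alternating D/G training of the paired route on scaled patch pairs.

    ``paired_patches`` are ``(x, y)`` float arrays in (C, H, W) layout and
    [-1, 1] range (see :func:`make_supervised_patches`).
    """
    cfg = config or TrainConfig()
    if not paired_patches:
        raise ValueError("empty training set")

    g = UNetGenerator(cfg.unet_spec)
    d = PatchGANDiscriminator(cfg.disc_spec)
    init_weights(g, cfg.init_sigma, seed=cfg.seed)
    init_weights(d, cfg.init_sigma, seed=cfg.seed + 1)
    g.seed_dropout(cfg.seed + 2)
    opt_g = Adam(g.params(), lr=cfg.learning_rate, beta1=cfg.beta1)
    opt_d = Adam(d.params(), lr=cfg.learning_rate, beta1=cfg.beta1)
    shuffle_rng = np.random.default_rng(cfg.seed + 3)

    losses: List[LossRecord] = []
    checkpoints: List[Checkpoint] = []
    step = 0
    n = len(paired_patches)
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(n)
        for idx in order:
            x, y = paired_patches[idx]

            # --- discriminator update (generator frozen) ---
            fake = g.forward(x, train=True)
            d.zero_grad()
            m_fake = d.forward(fake, train=True)
            p_fake = aggregate_map(m_fake)
            gf, gr = _adv_disc_grads(p_fake, 0.0, cfg.d_loss_weight, m_fake.size, cfg.adversarial_form)
            d.backward(np.full_like(m_fake, gf))
            m_real = d.forward(y, train=True)
            p_real = aggregate_map(m_real)
            _, gr = _adv_disc_grads(0.0, p_real, cfg.d_loss_weight, m_real.size, cfg.adversarial_form)
            d.backward(np.full_like(m_real, gr))
            raw_d, weighted_d = discriminator_loss(p_fake, p_real, cfg.d_loss_weight, cfg.adversarial_form)
            opt_d.step()

            # --- generator update (discriminator frozen: its grads are
            #     recomputed but zeroed before its next own update) ---
            g.zero_grad()
            fake = g.forward(x, train=True)
            m_fake = d.forward(fake, train=True)
            p_fake = aggregate_map(m_fake)
            d_adv = np.full_like(m_fake, _adv_gen_grad(p_fake, m_fake.size, cfg.adversarial_form))
            dz = d.backward(d_adv)  # gradient through D into the fake patch
            dz = dz + cfg.lambda_mae * np.sign(fake - y) / fake.size
            g.backward(dz.astype(np.float32))
            g_loss, terms = generator_loss_pix2pix(fake, y, p_fake, cfg.lambda_mae)
            opt_g.step()

            step += 1
            rec = LossRecord(step, epoch, weighted_d, g_loss, {"d_raw": raw_d, **terms})
            _check_finite(weighted_d + g_loss, "loss", rec)
            losses.append(rec)

        if epoch % cfg.checkpoint_interval == 0:
            ck = Checkpoint(epoch=epoch, state=g.copy_state(), spec=cfg.unet_spec)
            checkpoints.append(ck)
            if out_dir is not None:
                ck.save(Path(out_dir) / f"pix2pix_epoch{epoch:03d}.npz", seed=cfg.seed)

    return TrainResult(checkpoints=checkpoints, losses=losses, generator=g, discriminator=d)


def train_cyclegan(
    unpaired_nlm: Sequence[np.ndarray],
    unpaired_he: Sequence[np.ndarray],
    config: Optional[TrainConfig] = None,
    out_dir: Optional[Path] = None,
) -> TrainResult:
    """Unpaired training of (G1, G2, D1[, D2]) on independently drawn pools.

    Patch arrays are (C, H, W) in [-1, 1].  Each step pairs one patch from
    each pool; an epoch covers ``min(len(nlm), len(he))`` steps.
    """
    cfg = config or TrainConfig()
    if not unpaired_nlm or not unpaired_he:
        raise ValueError("both domains need at least one patch")
    w_adv, w_id, w_f, w_b = cfg.cycle_weights
    d_weight = cfg.d_loss_weight if cfg.halve_cycle_d_loss else 1.0

    g1 = ResNetGenerator(cfg.resnet_spec)  # NLM -> H&E
    g2 = ResNetGenerator(cfg.resnet_spec)  # H&E -> NLM
    d1 = PatchGANDiscriminator(cfg.disc_spec)
    d2 = PatchGANDiscriminator(cfg.disc_spec) if cfg.use_d2_adversarial else None
    init_weights(g1, cfg.init_sigma, seed=cfg.seed)
    init_weights(g2, cfg.init_sigma, seed=cfg.seed + 1)
    init_weights(d1, cfg.init_sigma, seed=cfg.seed + 2)
    if d2 is not None:
        init_weights(d2, cfg.init_sigma, seed=cfg.seed + 3)
    gen_params = g1.params() + g2.params()
    opt_g = Adam(gen_params, lr=cfg.learning_rate, beta1=cfg.beta1)
    opt_d1 = Adam(d1.params(), lr=cfg.learning_rate, beta1=cfg.beta1)
    opt_d2 = Adam(d2.params(), lr=cfg.learning_rate, beta1=cfg.beta1) if d2 is not None else None
    shuffle_rng = np.random.default_rng(cfg.seed + 4)

    losses: List[LossRecord] = []
    checkpoints: List[Checkpoint] = []
    n = min(len(unpaired_nlm), len(unpaired_he))
    step = 0
    for epoch in range(1, cfg.epochs + 1):
        order_x = shuffle_rng.permutation(len(unpaired_nlm))[:n]
        order_y = shuffle_rng.permutation(len(unpaired_he))[:n]
        for ix, iy in zip(order_x, order_y):
            x, y = unpaired_nlm[ix], unpaired_he[iy]

            # --- D1 update on (fake H&E, real H&E) ---
            fake_he = g1.forward(x, train=True)
            d1.zero_grad()
            m_fake = d1.forward(fake_he, train=True)
            p_fake = aggregate_map(m_fake)
            gf, _ = _adv_disc_grads(p_fake, 0.0, d_weight, m_fake.size, "lsq")
            d1.backward(np.full_like(m_fake, gf))
            m_real = d1.forward(y, train=True)
            p_real = aggregate_map(m_real)
            _, gr = _adv_disc_grads(0.0, p_real, d_weight, m_real.size, "lsq")
            d1.backward(np.full_like(m_real, gr))
            raw_d, weighted_d = discriminator_loss(p_fake, p_real, d_weight, "lsq")
            opt_d1.step()

            if d2 is not None:
                fake_nlm_for_d = g2.forward(y, train=True)
                d2.zero_grad()
                mf2 = d2.forward(fake_nlm_for_d, train=True)
                pf2 = aggregate_map(mf2)
                gf2, _ = _adv_disc_grads(pf2, 0.0, d_weight, mf2.size, "lsq")
                d2.backward(np.full_like(mf2, gf2))
                mr2 = d2.forward(x, train=True)
                pr2 = aggregate_map(mr2)
                _, gr2 = _adv_disc_grads(0.0, pr2, d_weight, mr2.size, "lsq")
                d2.backward(np.full_like(mr2, gr2))
                opt_d2.step()

            # --- generator update, one objective term at a time ---
            for p in gen_params:
                p.grad.fill(0.0)

            # adversarial (MSE form): weight w_adv
            fake_he = g1.forward(x, train=True)
            m_fake = d1.forward(fake_he, train=True)
            p_adv = aggregate_map(m_fake)
            dz = d1.backward(np.full_like(m_fake, w_adv * _adv_gen_grad(p_adv, m_fake.size, "lsq")))
            g1.backward(dz.astype(np.float32))
            adv = float((1.0 - p_adv) ** 2)

            if d2 is not None:
                fake_nlm = g2.forward(y, train=True)
                mf2 = d2.forward(fake_nlm, train=True)
                pa2 = aggregate_map(mf2)
                dz2 = d2.backward(np.full_like(mf2, w_adv * _adv_gen_grad(pa2, mf2.size, "lsq")))
                g2.backward(dz2.astype(np.float32))

            # identity of G1 on H&E: weight w_id
            id_out = g1.forward(y, train=True)
            identity = float(np.mean(np.abs(id_out - y)))
            g1.backward((w_id * np.sign(id_out - y) / id_out.size).astype(np.float32))

            if cfg.use_identity_g2:
                id2_out = g2.forward(x, train=True)
                g2.backward((w_id * np.sign(id2_out - x) / id2_out.size).astype(np.float32))

            # forward cycle: G2(G1(x)) ≈ x, weight w_f
            a = g1.forward(x, train=True)
            b = g2.forward(a, train=True)
            cyc_f = float(np.mean(np.abs(b - x)))
            da = g2.backward((w_f * np.sign(b - x) / b.size).astype(np.float32))
            g1.backward(da.astype(np.float32))

            # backward cycle: G1(G2(y)) ≈ y, weight w_b
            c = g2.forward(y, train=True)
            e = g1.forward(c, train=True)
            cyc_b = float(np.mean(np.abs(e - y)))
            dc = g1.backward((w_b * np.sign(e - y) / e.size).astype(np.float32))
            g2.backward(dc.astype(np.float32))

            opt_g.step()
            g_loss = w_adv * adv + w_id * identity + w_f * cyc_f + w_b * cyc_b
            step += 1
            rec = LossRecord(
                step,
                epoch,
                weighted_d,
                g_loss,
                {"d_raw": raw_d, "adv": adv, "identity": identity, "cycle_forward": cyc_f, "cycle_backward": cyc_b},
            )
            _check_finite(weighted_d + g_loss, "loss", rec)
            losses.append(rec)

        if epoch % cfg.checkpoint_interval == 0:
            ck = Checkpoint(epoch=epoch, state=g1.copy_state(), spec=cfg.resnet_spec, extra_state=g2.copy_state())
            checkpoints.append(ck)
            if out_dir is not None:
                ck.save(Path(out_dir) / f"cyclegan_epoch{epoch:03d}.npz", seed=cfg.seed)

    return TrainResult(checkpoints=checkpoints, losses=losses, generator=g1, discriminator=d1, generator2=g2)


def losses_to_csv(losses: Sequence[LossRecord], path: Path) -> None:
    keys = sorted({k for rec in losses for k in rec.terms})
    lines = ["step,epoch,d_loss,g_loss," + ",".join(keys)]
    for rec in losses:
        lines.append(
            f"{rec.step},{rec.epoch},{rec.d_loss:.6g},{rec.g_loss:.6g},"
            + ",".join(f"{rec.terms.get(k, float('nan')):.6g}" for k in keys)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def select_checkpoint(
    checkpoints: Sequence[Checkpoint],
    validation_pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    metric: str = "ssim",
    generator_factory=None,
) -> Checkpoint:
    """Pick the checkpoint whose generator scores best on validation pairs.

    ``validation_pairs`` are scaled (x, y) patches in (C, H, W); the metric
    (``ssim``, ``css`` — higher better — or ``mse`` — lower better) is
    computed on the unscaled 8-bit predictions.  Ties break toward the later
    epoch.
    """
    from .evaluation import css as _css, mse as _mse, ssim as _ssim

    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    if not validation_pairs:
        raise ValueError("empty validation set")
    if metric not in ("ssim", "css", "mse"):
        raise ValueError("metric must be one of ssim, css, mse")

    def build(ck: Checkpoint):
        if generator_factory is not None:
            net = generator_factory(ck.spec)
        elif isinstance(ck.spec, GeneratorSpecUNet):
            net = UNetGenerator(ck.spec)
        else:
            net = ResNetGenerator(ck.spec)
        net.load_state_dict(ck.state)
        return net

    best: Tuple[float, int, Optional[Checkpoint]] = (-np.inf, -1, None)
    for ck in checkpoints:
        net = build(ck)
        vals = []
        for x, y in validation_pairs:
            pred = unscale_from_model_range(net.forward(x, train=False)).transpose(1, 2, 0)
            ref = unscale_from_model_range(np.asarray(y)).transpose(1, 2, 0)
            if metric == "ssim":
                vals.append(_ssim(pred, ref))
            elif metric == "css":
                vals.append(_css(pred, ref))
            else:
                vals.append(_mse(pred, ref))
        score = float(np.mean(vals))
        if metric == "mse":
            score = -score
        if (score, ck.epoch) >= best[:2]:
            best = (score, ck.epoch, ck)
    return best[2]
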