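"""Training and evaluation of the segmentation network.

Recipe: SGD (momentum 0.9, weight decay 5e-4), cross-entropy loss on the
bilinearly upsampled main logits plus the booster-head logits plus the
point-decoder logits (all weights 1.0), polynomial(0.9) learning-rate decay
from ``lr_init`` floored at ``lr_min``.  Determinism: batch order and point
sampling derive from (seed, epoch, step), so a resumed run reproduces the
original trajectory.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import nn
from .backbone import BiSeNeXt
from .config import NetworkConfig, TrainConfig
from .data import MASK_PALETTE, Sample
from .metrics import ConfusionMatrix
from .nn import autograd as A
from .pointrefine import point_loss

log = logging.getLogger("bisenext")


def _to_batch(samples: list[Sample]) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in samples]).astype(np.float32)
    imgs = (imgs / 255.0 - 0.5) / 0.25
    return imgs.transpose(0, 3, 1, 2), np.stack([s.mask for s in samples]).astype(np.int64)


def total_loss(main_logits, aux_logits_list, truth: np.ndarray,
               point_term=None):
    """CE(main, truth) + sum CE(aux_i, truth) + optional point CE, weights 1.

    Logits at reduced resolution are bilinearly upsampled to the truth size.
    ``aux_logits_list`` must be non-empty: an empty list means the network
    ran in evaluation mode, where no training loss is defined.
    """
    if not aux_logits_list:
        raise ValueError("no booster logits: run the network in training mode")
    size = truth.shape[-2:]
    loss = A.cross_entropy(A.interpolate_bilinear(main_logits, size), truth)
    for aux in aux_logits_list:
        loss = loss + A.cross_entropy(A.interpolate_bilinear(aux, size), truth)
    if point_term is not None:
        loss = loss + point_term
    return loss


def recompute_bn_stats(net: BiSeNeXt, samples: list[Sample],
                       batch_size: int = 8, max_batches: int = 6) -> None:
    """Precise-BN: replace running statistics with a cumulative average over
    fresh forward passes.  With few optimiser steps per epoch the momentum
    running average lags the weights badly, which depresses eval-mode scores."""
    bns = [m for m in net.modules() if isinstance(m, nn.BatchNorm2d)]
    saved = [m.momentum for m in bns]
    net.train()
    with A.no_grad():
        for i in range(min(max_batches, max(1, len(samples) // batch_size))):
            for m in bns:
                m.momentum = 1.0 / (i + 1)
            x, _ = _to_batch(samples[i * batch_size:(i + 1) * batch_size])
            net(x)
    for m, mom in zip(bns, saved):
        m.momentum = mom


def save_checkpoint(path: str | Path, net: BiSeNeXt, optimizer: nn.SGD | None = None,
                    epoch: int = 0, extra: dict | None = None) -> None:
    path = Path(path)
    arrays = net.state_dict()
    if optimizer is not None:
        for i, v in enumerate(optimizer.velocity):
            arrays[f"vel:{i}"] = v
    np.savez(path, **arrays)
    meta = {"config": net.config.to_dict(), "epoch": epoch, **(extra or {})}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path, num_classes: int | None = None
                    ) -> tuple[BiSeNeXt, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig.from_dict(meta["config"])
    if num_classes is not None and cfg.num_classes != num_classes:
        raise ValueError(f"checkpoint has {cfg.num_classes} classes, "
                         f"expected {num_classes}")
    net = BiSeNeXt(cfg)
    with np.load(str(path) + (".npz" if not str(path).endswith(".npz") else "")) as data:
        state = {k: data[k] for k in data.files if not k.startswith("vel:")}
        vel = {int(k.split(":")[1]): data[k] for k in data.files if k.startswith("vel:")}
    net.load_state_dict(state)
    meta["velocity"] = vel
    return net, meta


def train(train_cfg: TrainConfig, net: BiSeNeXt, train_set: list[Sample],
          val_set: list[Sample], out_dir: str | Path | None = None,
          start_epoch: int = 0, end_epoch: int | None = None,
          velocity: dict | None = None) -> dict:
    """Train; returns {'log': per-epoch records, 'best_miou': float, ...}.

    Keeps the best-validation-mIoU checkpoint when ``out_dir`` is given; an
    optional ``train_cfg.target_miou`` stops early once validation reaches it.
    """
    if not train_set:
        raise ValueError("training split is empty")
    opt = nn.SGD(net.parameters(), lr=train_cfg.lr_init,
                 momentum=train_cfg.momentum, weight_decay=train_cfg.weight_decay)
    if velocity:
        for i, v in velocity.items():
            opt.velocity[i][...] = v
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    history: list[dict] = []
    best = {"miou": -1.0, "epoch": -1}
    bs = train_cfg.batch_size
    for epoch in range(start_epoch, end_epoch or train_cfg.epochs):
        t0 = time.time()
        opt.lr = train_cfg.lr_at(epoch)
        order = np.random.default_rng(train_cfg.seed * 100003 + epoch).permutation(len(train_set))
        net.train()
        losses = []
        for step in range(0, len(order), bs):
            batch = [train_set[i] for i in order[step:step + bs]]
            x, y = _to_batch(batch)
            res = net(x)
            pt = None
            if net.config.use_pointrefine:
                prng = np.random.default_rng((train_cfg.seed, epoch, step))
                pt, _ = point_loss(net.point_head, res.fine_features,
                                   res.main_logits, y, net.config.point_params, prng)
                pt = pt * train_cfg.point_loss_weight
            loss = total_loss(res.main_logits, res.aux_logits, y, pt)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        recompute_bn_stats(net, train_set)
        val = evaluate(net, val_set, seed=train_cfg.seed)
        rec = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses)),
               "val_miou": val["miou"], "val_mf1": val["mf1"],
               "seconds": round(time.time() - t0, 2)}
        history.append(rec)
        log.info("epoch %(epoch)d lr %(lr).2e loss %(train_loss).4f "
                 "val mIoU %(val_miou).4f (%(seconds).1fs)", rec)
        if val["miou"] > best["miou"]:
            best = {"miou": val["miou"], "epoch": epoch}
            if out_dir is not None:
                save_checkpoint(out_dir / "best.npz", net, opt, epoch,
                                {"val_miou": val["miou"]})
        if out_dir is not None:
            save_checkpoint(out_dir / "last.npz", net, opt, epoch)
            (out_dir / "log.json").write_text(json.dumps(history, indent=2))
        if (train_cfg.target_miou is not None
                and val["miou"] >= train_cfg.target_miou):
            break
    return {"log": history, "best_miou": best["miou"], "best_epoch": best["epoch"]}


def evaluate(net: BiSeNeXt, samples: list[Sample], seed: int = 0,
             batch_size: int = 8, predictor=None) -> dict:
    """Refine-enabled inference + metric suite over a dataset split.

    ``predictor(batch_images) -> (B,H,W) labels`` may replace the network
    (e.g. an oracle injector for pipeline tests).
    """
    net.eval()
    cm = ConfusionMatrix(net.config.num_classes)
    for i in range(0, len(samples), batch_size):
        batch = samples[i:i + batch_size]
        x, y = _to_batch(batch)
        if predictor is not None:
            pred = predictor(x)
        else:
            logits = net.predict_logits(x, rng=np.random.default_rng((seed, i)))
            pred = logits.argmax(axis=1)
        cm.accumulate(y, pred)
    out = cm.to_json()
    out["confusion"] = cm
    return out


def predict(net: BiSeNeXt, image: np.ndarray, seed: int = 0) -> np.ndarray:
    """Predicted label mask (H, W) for one RGB uint8 image."""
    sample = Sample(image=image, mask=np.zeros(image.shape[:2], dtype=np.uint8))
    x, _ = _to_batch([sample])
    net.eval()
    return net.predict_logits(x, rng=seed).argmax(axis=1)[0].astype(np.uint8)


def colorize_mask(mask: np.ndarray) -> np.ndarray:
    """Index mask -> RGB using the black/green/red palette."""
    out = np.zeros((*mask.shape, 3), dtype=np.uint8)
    for idx, rgb in MASK_PALETTE.items():
        out[mask == idx] = rgb
    return out


def boundary_error_rate(pred: np.ndarray, truth: np.ndarray, width: int = 2) -> float:
    """Misclassification rate restricted to pixels near class boundaries
    of the ground truth (within ``width`` pixels)."""
    from scipy import ndimage

    k = 2 * width + 1
    mx = ndimage.maximum_filter(truth, size=k)
    mn = ndimage.minimum_filter(truth, size=k)
    band = mx != mn
    if not band.any():
        return 0.0
    return float((pred[band] != truth[band]).mean())
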