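"""Training loop, identification evaluation (CIR), and the ablation runner.

Identification is closed-set and one-to-many: the test probe is
assigned the class with the highest softmax probability over scaled
cosine logits.  A probe counts as a *correct case* only when the top-1
class matches the true label **and** its probability exceeds 50%; the
correct identification rate is

    CIR = correct cases / total cases.

Plain top-1 accuracy (no probability threshold) is reported alongside,
since the two coincide once the model is confident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .data import (RoiImage, SplitSpec, SyntheticVeinConfig,
                   generate_synthetic_dataset, labels_of,
                   preprocess_batch, split_dataset)
from .loss import EMLConfig, eml_loss
from .model import ILCNN, ILCNNConfig, build_ilcnn, reparameterize_model
from .optim import AdamW


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    num_classes: int
    image_size: int = 112
    batch_size: int = 32
    epochs: int = 30            # desk default; 500 for full-scale runs
    learning_rate: float = 2e-4
    weight_decay: float = 0.01
    seed: int = 0
    eml: EMLConfig = field(default_factory=EMLConfig)
    use_eml: bool = True        # False -> plain softmax CE (ablation)
    block_style: str = "dbrb"
    dropout_rate: float = 0.2

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid batch size or learning rate")


@dataclass
class CIRReport:
    correct_cases: int
    total_cases: int
    cir: float
    top1_correct: int = 0
    top1_accuracy: float = 0.0

    def __post_init__(self):
        if self.total_cases <= 0:
            raise ValueError("evaluation needs at least one case")
        assert abs(self.cir - self.correct_cases / self.total_cases) < 1e-12


def model_config(cfg: TrainConfig) -> ILCNNConfig:
    return ILCNNConfig(num_classes=cfg.num_classes,
                       input_size=cfg.image_size,
                       dropout_rate=cfg.dropout_rate,
                       scale=cfg.eml.s,
                       block_style=cfg.block_style,
                       seed=cfg.seed)


def train(cfg: TrainConfig,
          train_images: list[RoiImage],
          val_images: list[RoiImage] | None = None,
          log: list[dict] | None = None) -> tuple[ILCNN, list[dict]]:
    """Optimize the train-structure network with the elastic-margin loss.

    Returns the model restored to its best-validation state (by CIR,
    falling back to final state when no validation split is given) and
    a per-epoch history of mean loss and validation CIR.
    """
    if not train_images:
        raise ValueError("empty training split")
    x = preprocess_batch(train_images, cfg.image_size).astype(np.float32)
    y = labels_of(train_images)
    if y.max() >= cfg.num_classes:
        raise ValueError("label outside configured class count")
    from ._memory import trim, tune_allocator
    tune_allocator()
    model = build_ilcnn(model_config(cfg))
    opt = AdamW(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 10_000)
    history: list[dict] = log if log is not None else []
    best = (-1.0, None)
    n = len(train_images)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Tensor(x[idx])
            emb = model.embed(xb)
            if cfg.use_eml:
                loss = eml_loss(emb, y[idx], model.head_weight, cfg.eml, rng)
            else:
                margin_free = EMLConfig(s=cfg.eml.s, m=0.0, sigma=0.0)
                loss = eml_loss(emb, y[idx], model.head_weight,
                                margin_free, rng)
            loss_value = float(loss.data)
            if not np.isfinite(loss_value):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward(free_graph=True)
            opt.step()
            losses.append(loss_value)
        trim()
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_images:
            report = evaluate(model, val_images)
            entry["val_cir"] = report.cir
            entry["val_top1"] = report.top1_accuracy
            if report.cir > best[0]:
                best = (report.cir, model.state_dict())
        history.append(entry)
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, history


def evaluate(model: ILCNN, images: list[RoiImage],
             batch_size: int = 64) -> CIRReport:
    """Closed-set identification on a split; the >50%-probability rule
    gates correctness on top of top-1 matching."""
    labels = labels_of(images)
    if labels.max() >= model.cfg.num_classes:
        raise ValueError("evaluation labels outside the model's class set")
    x = preprocess_batch(images, model.cfg.input_size).astype(np.float32)
    was_training = model.training
    model.eval()
    correct = top1 = 0
    for start in range(0, len(images), batch_size):
        xb = Tensor(x[start:start + batch_size])
        with no_grad():
            _, logits = model(xb)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        prob = np.exp(z)
        prob /= prob.sum(axis=1, keepdims=True)
        pred = prob.argmax(axis=1)
        yb = labels[start:start + batch_size]
        match = pred == yb
        top1 += int(match.sum())
        correct += int((match & (prob[np.arange(len(yb)), pred] > 0.5)).sum())
    if was_training:
        model.train()
    total = len(images)
    return CIRReport(correct_cases=correct, total_cases=total,
                     cir=correct / total, top1_correct=top1,
                     top1_accuracy=top1 / total)


def desk_run(n_identities: int = 50, epochs: int = 30, seed: int = 0,
             use_eml: bool = True, block_style: str = "dbrb",
             images_per_identity: int = 12,
             ratios: tuple[int, int, int] = (4, 1, 1)) -> dict:
    """End-to-end synthetic study: generate, split, train, evaluate,
    fuse, re-evaluate.  Returns a dict of the key quantities."""
    data_cfg = SyntheticVeinConfig(n_identities=n_identities,
                                   images_per_identity=images_per_identity,
                                   seed=seed)
    images = generate_synthetic_dataset(data_cfg)
    tr, va, te = split_dataset(images, SplitSpec(ratios=ratios, seed=seed))
    cfg = TrainConfig(num_classes=n_identities, epochs=epochs, seed=seed,
                      use_eml=use_eml, block_style=block_style)
    model, history = train(cfg, tr, va)
    report = evaluate(model, te)
    result = {
        "test_cir": report.cir,
        "test_top1": report.top1_accuracy,
        "history": history,
    }
    if block_style == "dbrb":
        deployed = reparameterize_model(model)
        fused = evaluate(deployed, te)
        result["deploy_cir"] = fused.cir
        result["deploy_top1"] = fused.top1_accuracy
    return result


def run_ablation(images: list[RoiImage], seeds: list[int],
                 n_classes: int, epochs: int = 10,
                 ratios: tuple[int, int, int] = (4, 1, 1)) -> list[dict]:
    """CIR of the three variants (basic residual / DBRB / DBRB+EML)
    under identical budgets and seeds; mean ± sd per variant."""
    variants = [("basic", False), ("dbrb", False), ("dbrb", True)]
    rows = []
    for block_style, use_eml in variants:
        cirs = []
        for seed in seeds:
            tr, va, te = split_dataset(images, SplitSpec(ratios=ratios,
                                                         seed=seed))
            cfg = TrainConfig(num_classes=n_classes, epochs=epochs,
                              seed=seed, use_eml=use_eml,
                              block_style=block_style)
            model, _ = train(cfg, tr, va)
            cirs.append(evaluate(model, te).cir)
        rows.append({
            "block": block_style, "eml": use_eml,
            "cir_mean": float(np.mean(cirs)),
            "cir_sd": float(np.std(cirs)),
            "cirs": cirs,
        })
    return rows
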