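"""Study protocol: data splitting, training, cross-validation, inference.

The protocol holds out a test fraction (default 20%), splits the remainder
into k=5 folds for cross-validation, trains with the class-weighted focal
loss under an AdamW-based optimizer with warm-up and cosine decay, keeps
the best-validation-Dice checkpoint, and at inference routes each image
through the LCA/RCA classifier to the corresponding segmentation model.
Splitting is by patient when patient ids are given, so all frames of one
acquisition stay in one split.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import no_grad
from .nn.optim import build_optimizer
from .architecture import SERegUNet, SideClassifier
from .losses import FocalLossParams, focal_loss
from .metrics import MetricsReport, binarize, dice_score
from .preprocess import RawAngiogram, PreprocessParams, preprocess_pipeline, model_input


@dataclass
class TrainConfig:
    epochs: int = 200                  # external-validation preset: 100
    batch_size: int = 8
    input_size: int = 512
    lr: float = 1e-3
    optimizer: str = "ranger21_style"  # or "adamw"
    folds: int = 5
    seed: int = 0
    loss: FocalLossParams = field(default_factory=FocalLossParams)
    weight_decay: float = 1e-4
    # optional extension, off by default: "hflip" mirrors images (and for the
    # side classifier swaps the LCA/RCA label, which mirroring implies)
    augment: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.folds < 2 or self.lr <= 0:
            raise ValueError("invalid training configuration")

    def to_dict(self):
        d = asdict(self)
        d["loss"] = asdict(self.loss)
        return d


EXTERNAL_VALIDATION_EPOCHS = 100


@dataclass
class FoldSplit:
    test_ids: list
    folds: list                        # k disjoint id lists over the remainder

    def validate(self):
        all_ids = list(self.test_ids) + [i for f in self.folds for i in f]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("splits overlap")
        sizes = [len(f) for f in self.folds]
        return sizes


def make_splits(image_ids, test_fraction: float = 0.2, k: int = 5, seed: int = 0,
                patient_ids=None, test_count: int | None = None) -> FoldSplit:
    """Deterministic test/cross-validation split.

    ``test_count`` overrides the fraction when a protocol prescribes exact
    counts. With ``patient_ids``, whole patients are assigned to a single
    split; otherwise each image is its own group and fold sizes differ by
    at most one.
    """
    image_ids = list(image_ids)
    n = len(image_ids)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} images, got {n}")
    rng = np.random.default_rng(seed)
    if patient_ids is None:
        groups = {i: [i] for i in image_ids}
    else:
        groups = {}
        for img, pat in zip(image_ids, patient_ids):
            groups.setdefault(pat, []).append(img)
    keys = sorted(groups)
    rng.shuffle(keys)

    n_test = int(np.floor(test_fraction * n)) if test_count is None else int(test_count)
    test_ids, i = [], 0
    while len(test_ids) < n_test and i < len(keys):
        test_ids.extend(groups[keys[i]])
        i += 1
    rest_keys = keys[i:]
    folds = [[] for _ in range(k)]
    # largest groups first onto the currently smallest fold
    for key in sorted(rest_keys, key=lambda s: (-len(groups[s]), str(s))):
        smallest = min(range(k), key=lambda j: len(folds[j]))
        folds[smallest].extend(groups[key])
    split = FoldSplit(test_ids, folds)
    split.validate()
    return split


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def evaluate_segmenter(model, data, report: MetricsReport | None = None) -> float:
    """Mean Dice of ``model`` over (x, y) pairs; optionally fills a report."""
    model.eval()
    dices = []
    with no_grad():
        for idx, (x, y) in enumerate(data):
            probs = model(nn.Tensor(x[None])).numpy()[0]
            pred = binarize(probs)
            if report is not None:
                report.add(pred, y, image_id=str(idx))
            dices.append(dice_score(pred, y))
    return float(np.mean(dices)) if dices else float("nan")


def train(model: SERegUNet, train_data, val_data, config: TrainConfig):
    """Train a segmentation model; returns (model, history).

    ``train_data``/``val_data``: sequences of (x, y) with x (3,H,W) float32
    in [0,1] and y (H,W) binary. Runs exactly ``config.epochs`` epochs,
    records train loss and validation Dice per epoch, and restores the
    best-validation-Dice weights at the end.
    """
    if len(train_data) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    steps_per_epoch = -(-len(train_data) // config.batch_size)
    opt = build_optimizer(config.optimizer, model.parameters(), config.lr,
                          total_steps=config.epochs * steps_per_epoch,
                          weight_decay=config.weight_decay)
    history = {"train_loss": [], "val_dice": []}
    best = {"dice": -1.0, "state": None}
    xs = [x for x, _ in train_data]
    ys = [y for _, y in train_data]
    for epoch in range(config.epochs):
        model.train()
        losses = []
        for bi, batch in enumerate(_batches(len(xs), config.batch_size, rng)):
            xb = np.stack([xs[i] for i in batch])
            yb = np.stack([ys[i] for i in batch])
            if config.augment == "hflip":
                flip = rng.random(len(batch)) < 0.5
                xb[flip] = xb[flip, :, :, ::-1]
                yb[flip] = yb[flip, :, ::-1]
            probs = model(nn.Tensor(xb))
            loss = focal_loss(probs, yb, config.loss)
            lval = loss.item()
            if not np.isfinite(lval):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {bi}")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)
        history["train_loss"].append(float(np.mean(losses)))
        vdice = evaluate_segmenter(model, val_data) if len(val_data) else float("nan")
        history["val_dice"].append(vdice)
        if len(val_data) and vdice > best["dice"]:
            best = {"dice": vdice, "state": copy.deepcopy(model.state_dict())}
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    return model, history


def train_classifier(model: SideClassifier, train_data, val_data, config: TrainConfig):
    """Train the LCA/RCA classifier with binary cross-entropy.

    ``train_data``: sequence of (x, label) with label 1 for LCA, 0 for RCA.
    Returns (model, history) with per-epoch loss and validation accuracy.
    """
    if len(train_data) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    steps_per_epoch = -(-len(train_data) // config.batch_size)
    opt = build_optimizer(config.optimizer, model.parameters(), config.lr,
                          total_steps=config.epochs * steps_per_epoch,
                          weight_decay=config.weight_decay)
    xs = [x for x, _ in train_data]
    ys = np.array([y for _, y in train_data], dtype=np.float32)
    history = {"train_loss": [], "val_acc": []}
    for epoch in range(config.epochs):
        model.train()
        losses = []
        for bi, batch in enumerate(_batches(len(xs), config.batch_size, rng)):
            xb = np.stack([xs[i] for i in batch])
            yb = ys[batch].reshape(-1, 1).copy()
            if config.augment == "hflip":
                flip = rng.random(len(batch)) < 0.5
                xb[flip] = xb[flip, :, :, ::-1]
                yb[flip] = 1.0 - yb[flip]
            p = model(nn.Tensor(xb))
            p = nn.clip_min(p, 1e-7)
            q = nn.clip_min(1.0 - p, 1e-7)
            loss = (nn.log(p) * nn.Tensor(-yb) + nn.log(q) * nn.Tensor(yb - 1.0)).mean()
            lval = loss.item()
            if not np.isfinite(lval):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {bi}")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)
        history["train_loss"].append(float(np.mean(losses)))
        if len(val_data):
            preds = classifier_scores(model, [x for x, _ in val_data])
            acc = float(np.mean((preds >= 0.5) == np.array([y for _, y in val_data])))
            history["val_acc"].append(acc)
    model.eval()
    return model, history


def classifier_scores(model, xs) -> np.ndarray:
    model.eval()
    with no_grad():
        return np.array([model(nn.Tensor(x[None])).numpy().item() for x in xs])


def cross_validate(dataset, config: TrainConfig, model_factory, split: FoldSplit | None = None):
    """k-fold cross-validation; returns a list of (model, MetricsReport).

    ``dataset``: list of (x, y) pairs; ``model_factory(fold_index)`` builds a
    fresh model per fold. Each fold is held out once for validation while
    the others train.
    """
    n = len(dataset)
    if split is None:
        split = make_splits(range(n), test_fraction=0.0, k=config.folds,
                            seed=config.seed)
    results = []
    for fi, fold in enumerate(split.folds):
        val_idx = set(fold)
        train_data = [dataset[i] for i in range(n)
                      if i not in val_idx and i not in set(split.test_ids)]
        val_data = [dataset[i] for i in fold]
        model = model_factory(fi)
        model, _ = train(model, train_data, val_data, config)
        report = MetricsReport()
        evaluate_segmenter(model, val_data, report)
        results.append((model, report))
    return results


# ---------------------------------------------------------------------------
# routed inference
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    side: str
    side_prob: float                   # probability of LCA
    prob_map: np.ndarray               # (2,H,W)
    mask: np.ndarray                   # (H,W) uint8
    metrics: dict | None = None


def infer(img: RawAngiogram, bundle: dict,
          params: PreprocessParams | None = None,
          truth: np.ndarray | None = None) -> SegmentationResult:
    """Preprocess, classify the side, route to that side's segmenter.

    ``bundle``: {"classifier", "lca_model", "rca_model"}; the two segmenter
    entries may alias one model.
    """
    pre = preprocess_pipeline(img, params)
    x = model_input(pre)
    clf = bundle["classifier"]
    clf.eval()
    with no_grad():
        p_lca = clf(nn.Tensor(x[None])).numpy().item()
    side = "LCA" if p_lca >= 0.5 else "RCA"
    key = "lca_model" if side == "LCA" else "rca_model"
    model = bundle.get(key)
    if model is None:
        raise ValueError(f"no segmentation model available for predicted side {side}")
    model.eval()
    with no_grad():
        probs = model(nn.Tensor(x[None])).numpy()[0]
    mask = binarize(probs)
    metrics = None
    if truth is not None:
        report = MetricsReport()
        metrics = report.add(mask, truth)
    return SegmentationResult(side, p_lca, probs, mask, metrics)
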