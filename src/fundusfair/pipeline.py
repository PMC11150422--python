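"""Training, evaluation and reporting orchestration.

The reference optimisation recipe is Adam (lr 1e-4, weight decay 1e-4,
betas (0.9, 0.999)) under a one-cycle schedule, 100 epochs at batch size
16, with random horizontal/vertical flip augmentation. The *desk preset*
keeps that recipe's shape but shrinks everything -- 64x80 images, the
compact encoder, 5 epochs, a higher peak rate suited to a small network
trained from scratch -- so the full pipeline runs in minutes on a CPU.

Two training arms share one dataset and seed: the two-branch
pathology-aware model with the full composite objective, and the
single-branch baseline trained with the asymmetric loss on disease
labels alone. `compare` reports both arms side by side; `table_metrics`
computes disparity reports straight from a published class-by-group AP
table without any model.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .fairness import (
    DisparityReport,
    GroupAPTable,
    GroupedPredictions,
    UndefinedMetricError,
    fairness_report,
)
from .losses import (
    LossBreakdown,
    LossWeights,
    asl,
    asl_grad,
    consis_grad,
    consis_loss,
    joint_grad,
    joint_loss,
    total_loss,
)
from .model import BaselineNet, ModelConfig, PathologyAwareNet
from .nn import Adam, OneCycleSchedule, sigmoid
from .screening import ScreeningReport, grouped_ap_table, screening_report
from .synthetic import SampleSet, SyntheticSpec, generate_dataset, load_dataset

__all__ = [
    "RunConfig",
    "TrainResult",
    "desk_preset",
    "train",
    "evaluate",
    "predict_scores",
    "table_metrics",
    "packaged_table_path",
    "compare",
    "compare_over_seeds",
    "save_checkpoint",
    "load_checkpoint",
]

ATTRIBUTE_COLUMNS = {"sex": "sex", "age": "age_bracket"}

PACKAGED_TABLES = {
    "sex_twobranch": "uwf_sex_ap_twobranch.tsv",
    "sex_baseline": "uwf_sex_ap_baseline.tsv",
    "age_twobranch": "uwf_age_ap_twobranch.tsv",
    "age_baseline": "uwf_age_ap_baseline.tsv",
}


@dataclass
class RunConfig:
    """One experiment: data source, model, objective, optimiser, seed."""

    n_diseases: int = 6
    n_features: int = 8
    n_samples: int = 1000
    manifest_dir: str | None = None  # load instead of simulating when set
    synthetic_overrides: dict = field(default_factory=dict)
    image_size: tuple[int, int] = (64, 80)
    channels: tuple[int, ...] = (8, 16, 16)
    kernels: tuple[int, ...] = (3, 3, 3)
    strides: tuple[int, ...] = (2, 2, 2)
    spatial_attention: bool = False
    batch_norm: bool = True
    loss: LossWeights = field(default_factory=LossWeights)
    lr: float = 1e-4  # one-cycle peak learning rate
    weight_decay: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 100
    batch_size: int = 16
    augment: bool = True  # random horizontal/vertical flips, training only
    swa_epochs: int = 0  # average weights over the final k epochs (0 = off)
    threshold: float = 0.5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            n_diseases=self.n_diseases,
            n_features=self.n_features,
            image_size=tuple(self.image_size),
            channels=tuple(self.channels),
            kernels=tuple(self.kernels),
            strides=tuple(self.strides),
            spatial_attention=self.spatial_attention,
            batch_norm=self.batch_norm,
        )

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_diseases", "n_features", "n_samples", "manifest_dir",
                "synthetic_overrides", "lr", "weight_decay", "epochs",
                "batch_size", "augment", "swa_epochs", "threshold", "seed",
                "out_dir", "spatial_attention", "batch_norm",
            )
        }
        d["image_size"] = list(self.image_size)
        d["channels"] = list(self.channels)
        d["kernels"] = list(self.kernels)
        d["strides"] = list(self.strides)
        d["betas"] = list(self.betas)
        d["loss"] = self.loss.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "loss" in d:
            d["loss"] = LossWeights.from_dict(d["loss"])
        for key in ("image_size", "channels", "kernels", "strides", "betas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def desk_preset(seed: int = 0, **overrides) -> RunConfig:
    """Minutes-scale configuration: 64x80 images, compact encoder, 5 epochs.

    Not the reference recipe -- the peak learning rate is raised to 3e-3
    and the final two epochs are weight-averaged because the compact
    encoder trains from scratch for only 5 epochs.
    """
    kwargs = dict(epochs=5, n_samples=1000, lr=3e-3, swa_epochs=2, seed=seed)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# data plumbing


def resolve_dataset(config: RunConfig) -> SampleSet:
    if config.manifest_dir is not None:
        return load_dataset(config.manifest_dir)
    overrides = {"image_size": tuple(config.image_size), **config.synthetic_overrides}
    spec = SyntheticSpec.default(seed=config.seed, **overrides)
    return generate_dataset(spec, config.n_samples)


def _to_batch_arrays(ds: SampleSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(images NCHW float, disease labels, feature labels)."""
    x = ds.images.astype(np.float64) / 255.0 - 0.5
    x = x.transpose(0, 3, 1, 2)
    return x, ds.disease_matrix(), ds.feature_matrix()


def _relation_matrix(ds: SampleSet) -> np.ndarray:
    """Feature-disease relation: simulator ground truth when available,
    otherwise empirical co-occurrence on the training split binarised at >0."""
    if ds.spec is not None:
        return ds.spec.relation_matrix()
    feats = ds.feature_matrix().astype(float)
    dis = ds.disease_matrix().astype(float)
    return (feats.T @ dis > 0).astype(float)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    model: PathologyAwareNet | BaselineNet
    arm: str
    history: list[LossBreakdown]
    config: RunConfig
    relation: np.ndarray
    disease_names: list[str]
    checkpoint_path: str | None = None


def train(config: RunConfig, dataset: SampleSet | None = None, arm: str = "two_branch") -> TrainResult:
    """Train one arm on the config's dataset.

    ``arm`` is "two_branch" (full composite objective) or "baseline"
    (asymmetric disease loss only). Runs are reproducible bit-for-bit
    under a fixed seed. A non-finite loss aborts with the batch index.
    """
    if arm not in ("two_branch", "baseline"):
        raise ValueError(f"unknown arm {arm!r}")
    ds = resolve_dataset(config) if dataset is None else dataset
    train_ds = ds.split("train")
    if len(train_ds.manifest) == 0:
        raise ValueError("empty training split")
    x, y_dis, y_feat = _to_batch_arrays(train_ds)
    if y_dis.shape[1] != config.n_diseases or y_feat.shape[1] != config.n_features:
        raise ValueError(
            f"class-count mismatch: manifest has {y_dis.shape[1]} diseases / "
            f"{y_feat.shape[1]} features, config expects "
            f"{config.n_diseases} / {config.n_features}"
        )
    relation = _relation_matrix(train_ds)
    w = config.loss

    model_seed = int(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % (2**31))
    mc = config.model_config()
    model = PathologyAwareNet(mc, seed=model_seed) if arm == "two_branch" else BaselineNet(mc, seed=model_seed)

    n = x.shape[0]
    steps_per_epoch = math.ceil(n / config.batch_size)
    sched = OneCycleSchedule(max_lr=config.lr, total_steps=config.epochs * steps_per_epoch)
    opt = Adam(model.params(), lr=sched.initial_lr, betas=config.betas,
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    history: list[LossBreakdown] = []
    step = 0
    log_lines = []
    swa_sums = None
    swa_count = 0
    model.set_mode(True)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = np.zeros(5)
        for bi in range(steps_per_epoch):
            idx = order[bi * config.batch_size : (bi + 1) * config.batch_size]
            xb = x[idx]
            if config.augment:
                xb = xb.copy()
                hflip = rng.random(len(idx)) < 0.5
                vflip = rng.random(len(idx)) < 0.5
                xb[hflip] = xb[hflip, :, :, ::-1]
                xb[vflip] = xb[vflip, :, ::-1, :]
            opt.zero_grad()
            opt.lr = sched.lr_at(step)
            if arm == "two_branch":
                breakdown = _step_two_branch(model, xb, y_dis[idx], y_feat[idx], relation, w)
            else:
                breakdown = _step_baseline(model, xb, y_dis[idx], w)
            if not math.isfinite(breakdown.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {bi}"
                )
            opt.step()
            step += 1
            if config.swa_epochs and epoch >= config.epochs - config.swa_epochs:
                if swa_sums is None:
                    swa_sums = [p.value.copy() for p in model.params()]
                else:
                    for acc, p in zip(swa_sums, model.params()):
                        acc += p.value
                swa_count += 1
            sums += [breakdown.patho, breakdown.disea, breakdown.joint,
                     breakdown.consis, breakdown.total]
        epoch_mean = LossBreakdown(*(sums / steps_per_epoch))
        history.append(epoch_mean)
        log_lines.append(json.dumps({"epoch": epoch, **epoch_mean.to_dict()}))

    if swa_count:
        for acc, p in zip(swa_sums, model.params()):
            p.value[...] = acc / swa_count

    result = TrainResult(
        model=model, arm=arm, history=history, config=config,
        relation=relation, disease_names=train_ds.disease_names,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"train_{arm}.log.jsonl", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        result.checkpoint_path = str(out / f"checkpoint_{arm}.npz")
        save_checkpoint(result, result.checkpoint_path)
    return result


def _step_two_branch(model, xb, yd, yf, relation, w: LossWeights) -> LossBreakdown:
    out = model.forward(xb)
    p_probs = sigmoid(out["patho_logits"])
    d_probs = sigmoid(out["disease_logits"])
    l_patho = asl(p_probs, yf, w)
    l_disea = asl(d_probs, yd, w)
    l_joint = joint_loss(p_probs, d_probs, relation)
    l_consis = consis_loss(out["F_p"], out["F_d"])
    breakdown = total_loss(l_patho, l_disea, l_joint, l_consis, w)

    jg_p, jg_d = joint_grad(p_probs, d_probs, relation)
    d_pp = w.lambda1 * asl_grad(p_probs, yf, w) + w.lambda3 * jg_p
    d_dp = w.lambda2 * asl_grad(d_probs, yd, w) + w.lambda3 * jg_d
    d_plog = d_pp * p_probs * (1 - p_probs)
    d_dlog = d_dp * d_probs * (1 - d_probs)
    cg_p, cg_d = consis_grad(out["F_p"], out["F_d"])
    model.backward(d_plog, d_dlog, d_f_p=w.lambda4 * cg_p, d_f_d=w.lambda4 * cg_d)
    return breakdown


def _step_baseline(model, xb, yd, w: LossWeights) -> LossBreakdown:
    out = model.forward(xb)
    d_probs = sigmoid(out["disease_logits"])
    l_disea = asl(d_probs, yd, w)
    breakdown = LossBreakdown(patho=0.0, disea=l_disea, joint=0.0, consis=0.0, total=l_disea)
    d_dp = asl_grad(d_probs, yd, w)
    model.backward(d_dp * d_probs * (1 - d_probs))
    return breakdown


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Self-describing .npz: parameters plus embedded JSON config."""
    meta = {
        "arm": result.arm,
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "disease_names": result.disease_names,
        "final_loss": result.history[-1].to_dict() if result.history else None,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        __relation__=result.relation,
        **result.model.state_arrays(),
    )


def load_checkpoint(path: str | Path) -> TrainResult:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        relation = data["__relation__"]
        arrays = {k: data[k] for k in data.files if not k.startswith("__")}
    config = RunConfig.from_dict(meta["config"])
    mc = config.model_config()
    model = PathologyAwareNet(mc) if meta["arm"] == "two_branch" else BaselineNet(mc)
    model.load_state(arrays)
    return TrainResult(
        model=model, arm=meta["arm"], history=[], config=config,
        relation=relation, disease_names=meta["disease_names"],
    )


# ---------------------------------------------------------------------------
# evaluation


def predict_scores(model, ds: SampleSet, batch_size: int = 64) -> np.ndarray:
    """Sigmoid disease scores for every sample, in manifest order."""
    x, _, _ = _to_batch_arrays(ds)
    model.set_mode(False)
    chunks = []
    for i in range(0, x.shape[0], batch_size):
        out = model.forward(x[i : i + batch_size])
        chunks.append(sigmoid(out["disease_logits"]))
    return np.concatenate(chunks)


@dataclass
class EvalResult:
    screening: ScreeningReport
    disparity: dict[str, DisparityReport | None]
    map_percent: float

    def to_dict(self) -> dict:
        return {
            "map": self.map_percent,
            "screening": self.screening.to_dict(),
            "disparity": {
                k: (v.to_dict() if v is not None else None)
                for k, v in self.disparity.items()
            },
        }


def evaluate(
    source: TrainResult | str | Path,
    dataset: SampleSet,
    attributes: tuple[str, ...] = ("sex",),
    threshold: float = 0.5,
) -> EvalResult:
    """Screening + per-attribute disparity reports on a test split.

    ``source`` is a TrainResult or a checkpoint path. Attributes with a
    single group present yield a None disparity report (undefined), the
    screening report is produced regardless.
    """
    result = load_checkpoint(source) if isinstance(source, (str, Path)) else source
    test = dataset.split("test") if "split" in dataset.manifest else dataset
    if len(test.manifest) == 0:
        raise ValueError("empty test split")
    y = test.disease_matrix()
    if y.shape[1] != result.config.n_diseases:
        raise ValueError("checkpoint and manifest disease sets differ in size")
    scores = predict_scores(result.model, test)
    names = test.disease_names
    screening = screening_report(scores, y, classes=names, threshold=threshold)
    disparity: dict[str, DisparityReport | None] = {}
    for attr in attributes:
        col = ATTRIBUTE_COLUMNS[attr]
        preds = GroupedPredictions(
            scores=scores, labels=y, group_of=test.manifest[col].tolist(),
            classes=names, threshold=threshold,
        )
        try:
            disparity[attr] = fairness_report(preds, attribute=attr)
        except UndefinedMetricError:
            disparity[attr] = None
    return EvalResult(
        screening=screening, disparity=disparity,
        map_percent=screening.macro["map"],
    )


# ---------------------------------------------------------------------------
# table-only metric path


def packaged_table_path(name: str) -> Path:
    """Path of a packaged class-by-group AP fixture table.

    Names: sex_twobranch, sex_baseline, age_twobranch, age_baseline.
    """
    try:
        fname = PACKAGED_TABLES[name]
    except KeyError:
        raise KeyError(f"unknown packaged table {name!r}; options: {sorted(PACKAGED_TABLES)}")
    return Path(str(resources.files("fundusfair").joinpath("data", fname)))


def table_metrics(table_path: str | Path, attribute: str | None = None) -> DisparityReport:
    """Disparity report straight from a class-by-group AP table file."""
    table = GroupAPTable.read(table_path)
    return fairness_report(table, attribute=attribute)


# ---------------------------------------------------------------------------
# side-by-side comparison


def _arm_summary(result: TrainResult, dataset: SampleSet, attribute: str) -> dict:
    ev = evaluate(result, dataset, attributes=(attribute,))
    rep = ev.disparity[attribute]
    return {
        "map": ev.map_percent,
        "delta_a": rep.delta_a if rep else None,
        "delta_m": rep.delta_m if rep else None,
        "pqd_mean": float(np.mean(list(rep.pqd.values()))) if rep and rep.pqd else None,
        "dpm": rep.dpm if rep else None,
        "eom": rep.eom if rep else None,
    }


def compare(config: RunConfig, dataset: SampleSet | None = None, attribute: str = "sex") -> dict:
    """Train both arms on one dataset/seed and report them side by side."""
    ds = resolve_dataset(config) if dataset is None else dataset
    two = train(config, dataset=ds, arm="two_branch")
    base = train(config, dataset=ds, arm="baseline")
    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "attribute": attribute,
        "two_branch": _arm_summary(two, ds, attribute),
        "baseline": _arm_summary(base, ds, attribute),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "compare.json", "w") as fh:
            json.dump(report, fh, indent=2)
        with open(out / "compare.md", "w") as fh:
            fh.write(compare_markdown(report))
    return report


def compare_markdown(report: dict) -> str:
    keys = ["map", "delta_a", "delta_m", "pqd_mean", "dpm", "eom"]
    head = "| arm | " + " | ".join(keys) + " |"
    sep = "|" + "---|" * (len(keys) + 1)
    rows = []
    for arm in ("baseline", "two_branch"):
        vals = [
            f"{report[arm][k]:.1f}" if report[arm][k] is not None else "-"
            for k in keys
        ]
        rows.append(f"| {arm} | " + " | ".join(vals) + " |")
    return "\n".join([head, sep, *rows]) + "\n"


def compare_over_seeds(config: RunConfig, seeds: list[int], attribute: str = "sex") -> dict:
    """Repeat the two-arm comparison over seeds; count two-branch wins.

    A seed is a *win* when the two-branch model has strictly lower
    disparity (dA) and at least as high test mAP.
    """
    runs = []
    wins = 0
    for seed in seeds:
        cfg = replace(config, seed=seed, out_dir=None)
        rep = compare(cfg, attribute=attribute)
        two, base = rep["two_branch"], rep["baseline"]
        win = (
            two["delta_a"] is not None
            and base["delta_a"] is not None
            and two["delta_a"] < base["delta_a"]
            and two["map"] >= base["map"] - 1e-9
        )
        wins += bool(win)
        runs.append({**rep, "win": bool(win)})
    return {
        "seeds": list(seeds),
        "wins": wins,
        "win_fraction": wins / len(seeds) if seeds else float("nan"),
        "runs": runs,
    }
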