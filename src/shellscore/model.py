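"""Pose-level RMSD regression model assembled from per-shell encoders.

The model follows the familiar two-object pattern: :class:`ShellScoreModel`
holds the featurized poses and the configuration; ``fit()`` runs the training
recipe (AdamW, MSE loss, learning rate halved every STEP epochs, early
stopping after STEP non-improving validation epochs, hard cap of 150 epochs)
and returns a :class:`ShellScoreResults` carrying the best checkpoint, the
epoch history and a ``summary()`` table.  ``fit_ensemble()`` splits the
complexes into four disjoint parts, trains one model per part (validating on
another randomly chosen part) and reports every evaluation metric as
mean +/- std across the four models.

A pose whose shell stack contains no protein atom at all is "dissociated":
its predicted RMSD is +infinity, it is excluded from losses and regression
metrics, and it sorts last in rankings.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import AdamW, Tensor
from .features import DEFAULT_SCHEMA, FeatureSchema
from .graphormer import GraphormerConfig, encode_shell_graph, \
    init_graphormer_params
from .shells import ShellGraph, ShellLayout, build_all_shells
from .structures import ComplexPose

__all__ = [
    "ScoringConfig", "FeaturizedPose", "featurize_pose", "mse_loss",
    "lr_at_epoch", "EarlyStopping", "ShellScoreModel", "ShellScoreResults",
    "EnsembleResults", "forward_score", "load_results",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Everything that defines a trained model, seeds included."""

    layout: ShellLayout = field(default_factory=ShellLayout)
    encoder: GraphormerConfig = field(default_factory=GraphormerConfig)
    mlp_hidden: tuple = (256, 64)
    learning_rate: float = 0.001
    step: int = 25                 # lr-halving period and early-stop patience
    max_epochs: int = 150
    batch_size: int = 32
    weight_decay: float = 0.01
    min_improvement: float = 1e-4  # absolute validation-loss improvement
    val_fraction: float = 0.25
    ensemble_parts: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.max_epochs < self.step:
            raise ValueError("max_epochs must be >= step")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "layout" in d and isinstance(d["layout"], dict):
            d["layout"] = ShellLayout(**d["layout"])
        if "encoder" in d and isinstance(d["encoder"], dict):
            d["encoder"] = GraphormerConfig(**d["encoder"])
        if "mlp_hidden" in d:
            d["mlp_hidden"] = tuple(d["mlp_hidden"])
        return cls(**d)


@dataclass
class FeaturizedPose:
    """A pose after shell-graph construction; the trainable unit."""

    graphs: list[ShellGraph]
    dissociated: bool
    pose_id: str
    complex_id: str
    label: float | None = None


def featurize_pose(cplx: ComplexPose, layout: ShellLayout,
                   schema: FeatureSchema = DEFAULT_SCHEMA,
                   hop_max: int = 5) -> FeaturizedPose:
    graphs, dissociated = build_all_shells(cplx, layout, schema, hop_max)
    return FeaturizedPose(
        graphs=graphs, dissociated=dissociated, pose_id=cplx.pose_id,
        complex_id=cplx.complex_id or cplx.pose_id, label=cplx.rmsd_label)


# --------------------------------------------------------------------------
# training-recipe primitives

def mse_loss(predictions: Sequence[float], labels: Sequence[float]) -> float:
    """Mean squared error; infinite predictions must be excluded upstream."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("need equal-length, non-empty prediction/label arrays")
    if not np.all(np.isfinite(predictions)):
        raise ValueError("infinite predictions must be excluded before the loss")
    return float(np.mean((predictions - labels) ** 2))


def lr_at_epoch(epoch: int, initial_lr: float, step: int) -> float:
    """Learning rate halved every ``step`` epochs: lr0 * 0.5**(epoch // step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return initial_lr * 0.5 ** (epoch // step)


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement.

    Improvement means the monitored (validation) loss dropping below the best
    seen so far by at least ``min_improvement``.
    """

    def __init__(self, patience: int, min_improvement: float = 1e-4):
        self.patience = patience
        self.min_improvement = min_improvement
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record one epoch's loss; return True when training should stop."""
        if loss < self.best - self.min_improvement:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


# --------------------------------------------------------------------------
# parameters and forward pass

def _init_params(config: ScoringConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    params: dict[str, Tensor] = {}
    for s in range(config.layout.n_shells):
        for key, tensor in init_graphormer_params(config.encoder, rng).items():
            params[f"s{s}.{key}"] = tensor
    widths = (config.layout.n_shells * config.encoder.out_dim,
              *config.mlp_hidden, 1)
    for i, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
        params[f"head.w{i}"] = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(w_in), size=(w_in, w_out)))
        params[f"head.b{i}"] = Tensor(np.zeros(w_out))
    return params


def _shell_params(params: dict[str, Tensor], s: int) -> dict[str, Tensor]:
    prefix = f"s{s}."
    return {k[len(prefix):]: v for k, v in params.items() if k.startswith(prefix)}


def concatenated_embedding(fp: FeaturizedPose, params: dict[str, Tensor],
                           config: ScoringConfig) -> Tensor:
    """The n_shells * out_dim vector fed to the MLP head."""
    embeddings = [encode_shell_graph(g, _shell_params(params, s), config.encoder)
                  for s, g in enumerate(fp.graphs)]
    return ad.concat(embeddings, axis=0)


def _forward(fp: FeaturizedPose, params: dict[str, Tensor],
             config: ScoringConfig) -> Tensor | None:
    """Predicted RMSD as a scalar tensor, or None for a dissociated pose."""
    if fp.dissociated:
        return None
    z = ad.reshape(concatenated_embedding(fp, params, config),
                   (1, config.layout.n_shells * config.encoder.out_dim))
    n_layers = len(config.mlp_hidden) + 1
    for i in range(n_layers):
        z = z @ params[f"head.w{i}"] + params[f"head.b{i}"]
        if i < n_layers - 1:
            z = ad.relu(z)
    return ad.softplus(ad.reshape(z, ()))  # RMSD is nonnegative


def forward_score(fp: FeaturizedPose, params: dict[str, Tensor],
                  config: ScoringConfig) -> float:
    """Predicted RMSD in Angstrom, +inf for a dissociated pose."""
    out = _forward(fp, params, config)
    return float("inf") if out is None else float(out.data)


# --------------------------------------------------------------------------
# model / results

class ShellScoreModel:
    """RMSD regression over docked poses, built from labeled complexes.

    Parameters
    ----------
    poses : sequence of ComplexPose
        Labeled poses (``rmsd_label`` set) for training; unlabeled poses are
        accepted only for prediction-time featurization.
    config : ScoringConfig
    """

    def __init__(self, poses: Sequence[ComplexPose],
                 config: ScoringConfig | None = None,
                 schema: FeatureSchema = DEFAULT_SCHEMA):
        self.config = config or ScoringConfig()
        self.schema = schema
        self.poses = list(poses)
        self.featurized = [featurize_pose(p, self.config.layout, schema,
                                          self.config.encoder.hop_max)
                           for p in self.poses]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, poses: Sequence[ComplexPose],
                       config: ScoringConfig | None = None) -> "ShellScoreModel":
        """Attach labels from a (pose_id, complex_id, rmsd) table to poses."""
        labels = {(r.complex_id, r.pose_id): r.rmsd for r in df.itertuples()}
        relabeled = []
        for p in poses:
            key = (p.complex_id, p.pose_id)
            relabeled.append(ComplexPose(p.protein, p.ligand, p.pose_id,
                                         p.complex_id, labels.get(key)))
        return cls(relabeled, config)

    # -- splitting helpers -------------------------------------------------
    def _complex_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for fp in self.featurized:
            seen.setdefault(fp.complex_id)
        return list(seen)

    def _trainable(self) -> list[FeaturizedPose]:
        return [fp for fp in self.featurized
                if fp.label is not None and not fp.dissociated]

    def fit(self, validation: Iterable[str] | None = None,
            log_path=None) -> "ShellScoreResults":
        """Train with the AdamW / halving-schedule / early-stopping recipe.

        ``validation`` may name the held-out complex ids; by default a
        complex-disjoint random fraction (``config.val_fraction``) is held out.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        pool = self._trainable()
        if not pool:
            raise ValueError("no labeled, associated poses to train on")
        ids = sorted({fp.complex_id for fp in pool})
        if validation is None:
            ids_shuffled = list(ids)
            rng.shuffle(ids_shuffled)
            n_val = max(1, int(round(cfg.val_fraction * len(ids_shuffled)))) \
                if len(ids_shuffled) > 1 else 0
            val_ids = set(ids_shuffled[:n_val])
        else:
            val_ids = set(validation)
        train = [fp for fp in pool if fp.complex_id not in val_ids]
        val = [fp for fp in pool if fp.complex_id in val_ids]
        if not train:
            raise ValueError("validation split leaves an empty training set")

        params = _init_params(cfg, rng)
        opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        stopper = EarlyStopping(cfg.step, cfg.min_improvement)
        history: list[dict] = []
        best_params = {k: p.data.copy() for k, p in params.items()}
        monitor = val if val else train

        for epoch in range(cfg.max_epochs):
            opt.lr = lr_at_epoch(epoch, cfg.learning_rate, cfg.step)
            order = rng.permutation(len(train))
            train_losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = [train[i] for i in order[start:start + cfg.batch_size]]
                sq = [ad.square(_forward(fp, params, cfg) - Tensor(fp.label))
                      for fp in batch]
                loss = ad.mean_of(sq)
                opt.zero_grad()
                loss.backward()
                opt.step()
                train_losses.append(float(loss.data))
            val_loss = self._eval_mse(monitor, params)
            history.append({"epoch": epoch, "lr": opt.lr,
                            "train_mse": float(np.mean(train_losses)),
                            "val_mse": val_loss})
            improved_best = stopper.best
            stop = stopper.update(epoch, val_loss)
            if stopper.best < improved_best:  # new best checkpoint
                best_params = {k: p.data.copy() for k, p in params.items()}
            if log_path is not None:
                pd.DataFrame(history).to_csv(log_path, sep="\t", index=False)
            if stop:
                break

        best = {k: Tensor(v) for k, v in best_params.items()}
        return ShellScoreResults(
            model=self, params=best, config=cfg,
            history=pd.DataFrame(history), best_epoch=stopper.best_epoch,
            train_complex_ids=sorted({fp.complex_id for fp in train}),
            val_complex_ids=sorted(val_ids))

    def _eval_mse(self, pool: list[FeaturizedPose],
                  params: dict[str, Tensor]) -> float:
        preds = [forward_score(fp, params, self.config) for fp in pool]
        labels = [fp.label for fp in pool]
        return mse_loss(preds, labels)

    def fit_ensemble(self) -> "EnsembleResults":
        """Four complex-disjoint parts; each trains one model and validates on
        another randomly selected part."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        ids = self._complex_ids()
        n_parts = cfg.ensemble_parts
        if len(ids) < n_parts:
            raise ValueError(
                f"need at least {n_parts} complexes for the ensemble split")
        order = list(ids)
        rng.shuffle(order)
        parts = [order[i::n_parts] for i in range(n_parts)]
        results = []
        for i, part in enumerate(parts):
            others = [j for j in range(n_parts) if j != i]
            val_part = parts[rng.choice(others)]
            sub_poses = [p for p in self.poses
                         if (p.complex_id or p.pose_id) in set(part) | set(val_part)]
            sub_cfg = ScoringConfig.from_dict({**cfg.to_dict(),
                                               "seed": cfg.seed + i + 1})
            sub_model = ShellScoreModel(sub_poses, sub_cfg, self.schema)
            results.append(sub_model.fit(validation=val_part))
        return EnsembleResults(results=results, parts=parts, config=cfg)


@dataclass
class ShellScoreResults:
    """A fitted scorer: best checkpoint, history and prediction interface."""

    params: dict[str, Tensor]
    config: ScoringConfig
    history: pd.DataFrame
    best_epoch: int
    model: ShellScoreModel | None = None
    train_complex_ids: list = field(default_factory=list)
    val_complex_ids: list = field(default_factory=list)
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def predict_featurized(self, fps: Iterable[FeaturizedPose]) -> np.ndarray:
        return np.array([forward_score(fp, self.params, self.config)
                         for fp in fps])

    def predict(self, poses: Sequence[ComplexPose]) -> np.ndarray:
        """Predicted RMSD per pose (+inf where the pose is dissociated)."""
        fps = [featurize_pose(p, self.config.layout, self.schema,
                              self.config.encoder.hop_max) for p in poses]
        return self.predict_featurized(fps)

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.model is None:
            raise ValueError("results loaded from disk carry no training data")
        return self.predict_featurized(self.model.featurized)

    def rankings(self, poses: Sequence[ComplexPose]):
        """Group predictions into per-complex PoseRanking objects."""
        from .metrics import PoseRanking

        scores = self.predict(poses)
        by_complex: dict[str, list] = {}
        for p, s in zip(poses, scores):
            cid = p.complex_id or p.pose_id
            by_complex.setdefault(cid, []).append((p.pose_id, float(s),
                                                   float(p.rmsd_label)))
        return [PoseRanking(cid, entries) for cid, entries in by_complex.items()]

    def evaluate(self, poses: Sequence[ComplexPose], k_dock: int = 1,
                 k_hit: int = 10, threshold: float = 2.0):
        from .metrics import compute_metrics

        return compute_metrics(self.rankings(poses), k_dock=k_dock,
                               k_hit=k_hit, threshold=threshold)

    def summary(self) -> str:
        buf = io.StringIO()
        h = self.history
        buf.write("Shell-graph RMSD regression results\n")
        buf.write("=" * 51 + "\n")
        rows = [
            ("shells (n, d0, d)", f"{self.config.layout.n_shells}, "
                                  f"{self.config.layout.d0}, {self.config.layout.d}"),
            ("encoder (layers/heads/d)", f"{self.config.encoder.n_layers}/"
                                         f"{self.config.encoder.n_heads}/"
                                         f"{self.config.encoder.d_hidden}"),
            ("embedding per shell", str(self.config.encoder.out_dim)),
            ("epochs run", str(len(h))),
            ("best epoch", str(self.best_epoch)),
            ("best val MSE", f"{h['val_mse'].min():.4f}" if len(h) else "n/a"),
            ("final train MSE", f"{h['train_mse'].iloc[-1]:.4f}" if len(h) else "n/a"),
            ("train complexes", str(len(self.train_complex_ids))),
            ("val complexes", str(len(self.val_complex_ids))),
        ]
        for k, v in rows:
            buf.write(f"{k:<28}{v:>23}\n")
        buf.write("=" * 51 + "\n")
        return buf.getvalue()

    def save(self, path) -> None:
        """Self-describing checkpoint: parameters + full configuration."""
        arrays = {f"param::{k}": p.data for k, p in self.params.items()}
        meta = {
            "config": self.config.to_dict(),
            "best_epoch": self.best_epoch,
            "schema": json.loads(self.schema.to_json()),
            "train_complex_ids": self.train_complex_ids,
            "val_complex_ids": self.val_complex_ids,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        arrays["history_json"] = np.frombuffer(
            self.history.to_json().encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)


def load_results(path) -> ShellScoreResults:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        history = pd.read_json(io.StringIO(bytes(data["history_json"]).decode()))
        params = {k[len("param::"):]: Tensor(data[k])
                  for k in data.files if k.startswith("param::")}
    return ShellScoreResults(
        params=params, config=ScoringConfig.from_dict(meta["config"]),
        history=history, best_epoch=meta["best_epoch"],
        train_complex_ids=meta["train_complex_ids"],
        val_complex_ids=meta["val_complex_ids"])


@dataclass
class EnsembleResults:
    """Four fitted models plus mean +/- std reporting across them."""

    results: list[ShellScoreResults]
    parts: list[list[str]]
    config: ScoringConfig

    def evaluate(self, poses: Sequence[ComplexPose], k_dock: int = 1,
                 k_hit: int = 10, threshold: float = 2.0) -> pd.DataFrame:
        """Per-metric mean and std across the ensemble members."""
        reports = [r.evaluate(poses, k_dock, k_hit, threshold).as_dict()
                   for r in self.results]
        return summarize_metric_reports(reports)

    def summary(self) -> str:
        lines = ["Ensemble of %d shell-graph scorers" % len(self.results),
                 "parts (complex ids): " + "; ".join(
                     ",".join(p) for p in self.parts)]
        for i, r in enumerate(self.results):
            h = r.history
            lines.append(f"model {i}: epochs={len(h)} "
                         f"best_val_mse={h['val_mse'].min():.4f}")
        return "\n".join(lines)


def summarize_metric_reports(reports: list[dict]) -> pd.DataFrame:
    """mean +/- std table over per-model metric dicts (numeric keys only)."""
    keys = [k for k, v in reports[0].items() if isinstance(v, (int, float))]
    rows = {}
    for k in keys:
        vals = np.array([r[k] for r in reports], dtype=float)
        rows[k] = {"mean": float(np.nanmean(vals)), "std": float(np.nanstd(vals))}
    return pd.DataFrame(rows).T
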