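"""The synergy model and its fitted results.

:class:`SynergyModel` binds a :class:`~combosyn.datasets.DatasetBundle`
to a :class:`~combosyn.config.ModelConfig`; :meth:`SynergyModel.fit`
trains the full multitask network on a set of training samples and
returns a :class:`SynergyResults` carrying the loss trace, the held-out
metrics and a ``summary()`` table.

Training minimises the weighted multitask loss with Adam on mini-batches
(both drugs of every pair pass through the one shared encoder), early
stops on the synergy loss of a validation slice carved from the training
samples, and restores the best-validation weights.  Everything — weight
initialisation, batch order, dropout, the validation carve-out, the walk
and embedding stages — derives from the single ``seed`` argument, so a
fit is bit-reproducible single-threaded.

Ablation variants reuse the identical architecture and differ only in
the loss-weight mask (``variant`` argument): ``transformer`` keeps the
synergy loss alone, ``transformer_toxic`` adds the toxic penalty,
``transformer_dti`` adds the one-class interaction losses, ``full`` uses
all terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cpi, losses, nn, patching, ppi
from .autodiff import Tensor, concat, no_grad
from .config import ModelConfig
from .datasets import DatasetBundle, SynergySample
from .evaluation import MetricReport, SplitPlan, evaluate_predictions
from .head import HeadConfig, SynergyHead
from .losses import LossReport, LossWeights
from .patching import PatchConfig, PatchSequence
from .ppi import ClusteredProteinSpace
from .transformer import DrugTransformer, TransformerConfig

logger = logging.getLogger(__name__)


class NonFiniteLossError(RuntimeError):
    """Raised when a training batch produces a non-finite loss."""

    def __init__(self, epoch: int, batch_indices: np.ndarray, report: LossReport):
        self.epoch = epoch
        self.batch_indices = batch_indices
        self.report = report
        super().__init__(
            f"non-finite loss at epoch {epoch} on batch {batch_indices.tolist()}: "
            f"{report.as_dict()}"
        )


@dataclass
class _Network:
    """The trainable parts plus the frozen per-fit preprocessing artefacts."""

    encoder: DrugTransformer
    mapper: cpi.ProteinMapper
    head: SynergyHead
    vocab: dict[str, int]
    patch_cfg: PatchConfig
    sequences: dict[str, PatchSequence]
    space: ClusteredProteinSpace
    active_clusters: dict[str, set[int]]

    def modules(self) -> list[nn.Module]:
        return [self.encoder, self.mapper, self.head]

    def parameters(self):
        for m in self.modules():
            yield from m.parameters()

    def train(self, mode: bool = True) -> None:
        for m in self.modules():
            m.train(mode)


class SynergyModel:
    """Drug-pair synergy model over a validated dataset bundle."""

    def __init__(self, bundle: DatasetBundle, config: ModelConfig | None = None):
        self.bundle = bundle
        self.config = config or ModelConfig()
        self._space_cache: dict[int, ClusteredProteinSpace] = {}

    @classmethod
    def from_files(cls, paths: dict, config: ModelConfig | None = None,
                   score_column: str = "score", threshold: float = 10.0) -> "SynergyModel":
        from .datasets import load_bundle_from_config

        bundle = load_bundle_from_config(paths, score_column=score_column,
                                         threshold=threshold)
        return cls(bundle, config)

    # -- preprocessing --------------------------------------------------------

    def protein_space(self, seed: int) -> ClusteredProteinSpace:
        """Walk + embed + cluster the PPI graph (cached per seed).

        Uses only the graph and the Cpc matrix, never the synergy labels,
        so the artefact is shared across folds of one evaluation run.
        """
        if seed not in self._space_cache:
            p = self.config.ppi
            corpus = ppi.generate_walks(
                self.bundle.ppi, walk_length=p.walk_length, num_walks=p.num_walks,
                p=p.p, q=p.q, seed=seed,
            )
            emb = ppi.embed_nodes(corpus, n=p.n, window=p.window,
                                  epochs=p.epochs, seed=seed)
            self._space_cache[seed] = ppi.cluster_proteins(
                emb, self.bundle.cpc, Pc=p.Pc, seed=seed
            )
        return self._space_cache[seed]

    def _build_network(self, train_idx: np.ndarray, seed: int) -> _Network:
        cfgp = self.config.patching
        train_drugs = sorted(
            {self.bundle.samples[i].drug1_id for i in train_idx}
            | {self.bundle.samples[i].drug2_id for i in train_idx}
        )
        vocab = patching.build_vocab(
            [self.bundle.catalog[d] for d in train_drugs]
        )
        patch_cfg = PatchConfig(
            patch_size=cfgp.patch_size, overlap_ratio=cfgp.overlap_ratio,
            max_patches=cfgp.max_patches, vocab=vocab,
        )
        sequences = patching.encode_catalog(self.bundle.catalog.entries, patch_cfg)

        space = self.protein_space(seed)
        active = cpi.lift_active_pairs(self.bundle.dti, space)

        rng = np.random.default_rng(seed)
        enc_cfg = self.config.encoder
        encoder = DrugTransformer(
            TransformerConfig(
                d_model=enc_cfg.d_model, num_heads=enc_cfg.num_heads,
                depth_L=enc_cfg.depth_L, mlp_hidden=enc_cfg.mlp_hidden,
                dropout=enc_cfg.dropout, pooling=enc_cfg.pooling,
                vocab_size=len(vocab), max_patches=cfgp.max_patches,
            ),
            rng,
        )
        mapper = cpi.ProteinMapper(
            n_in=self.config.ppi.n, d_model=enc_cfg.d_model,
            num_heads=1, rng=rng,
        )
        fus = self.config.fusion
        head = SynergyHead(
            HeadConfig(
                d_model=enc_cfg.d_model, Pc=space.Pc,
                branch_hidden=tuple(fus.branch_hidden),
                head_hidden=tuple(fus.head_hidden),
                cell_branch=fus.cell_branch, dropout=enc_cfg.dropout,
            ),
            rng,
            dropout=encoder.dropout,
        )
        return _Network(
            encoder=encoder, mapper=mapper, head=head, vocab=vocab,
            patch_cfg=patch_cfg, sequences=sequences, space=space,
            active_clusters=active,
        )

    # -- forward pass ---------------------------------------------------------

    def _batch_arrays(self, net: _Network, idx: np.ndarray):
        samples = [self.bundle.samples[i] for i in idx]
        seqs = [net.sequences[s.drug1_id] for s in samples] + [
            net.sequences[s.drug2_id] for s in samples
        ]
        patches = np.stack([s.patches for s in seqs])
        pad_mask = np.stack([s.pad_mask for s in seqs])
        cell_cols = [self.bundle.cpc.cell_index.index(s.cell_id) for s in samples]
        cell_vec = net.space.cpc_clustered[:, cell_cols].T          # (B, Pc)
        labels = np.array([s.label for s in samples], dtype=float)
        return samples, patches, pad_mask, cell_vec, labels

    def _forward(self, net: _Network, idx: np.ndarray, weights: LossWeights,
                 symmetrize: bool = False):
        samples, patches, pad_mask, cell_vec, labels = self._batch_arrays(net, idx)
        B = len(samples)
        oF_all = net.encoder(patches, pad_mask)           # (2B, d) shared weights
        opm = net.mapper(net.space.op)                    # (Pc, d)
        oB_all, _ = cpi.binding_affinity(oF_all, opm)     # (2B, Pc)
        oF1, oF2 = oF_all[:B], oF_all[B:]
        oB1, oB2 = oB_all[:B], oB_all[B:]
        o = net.head(oF1, oF2, oB1, oB2, opm, Tensor(cell_vec),
                     symmetrize=symmetrize)

        l_syn = losses.synergy_loss(labels, o)
        l_tox = losses.toxic_loss(oB1, oB2)
        l_cmp = cpi.compactness_loss(oF_all)
        active_pairs = []
        for row, s in enumerate(samples):
            for drug, offset in ((s.drug1_id, 0), (s.drug2_id, B)):
                for cluster in net.active_clusters.get(drug, ()):
                    active_pairs.append((row + offset, cluster))
        l_dsc = cpi.descriptiveness_loss(oB_all, active_pairs)
        total, report = losses.total_loss(l_syn, l_tox, l_cmp, l_dsc, weights)
        return o, total, report

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        train_idx: np.ndarray | None = None,
        test_idx: np.ndarray | None = None,
        seed: int = 0,
        variant: str = "full",
    ) -> "SynergyResults":
        """Train the network and score it on the held-out samples.

        ``variant`` selects the ablation weight mask.  A validation slice
        (``training.val_fraction`` of the training samples) drives early
        stopping; test samples are never used for selection.
        """
        if variant not in losses.ABLATION_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        n = len(self.bundle.samples)
        train_idx = np.arange(n) if train_idx is None else np.asarray(train_idx)
        cfg_t = self.config.training
        weights = self.config.weights.masked(variant)

        rng = np.random.default_rng(seed + 1)
        order = rng.permutation(len(train_idx))
        n_val = max(1, int(round(cfg_t.val_fraction * len(train_idx))))
        val_idx = train_idx[order[:n_val]]
        fit_idx = train_idx[order[n_val:]]

        net = self._build_network(fit_idx, seed)
        opt = nn.Adam(list(net.parameters()), lr=cfg_t.learning_rate)

        trace: list[LossReport] = []
        val_trace: list[float] = []
        best_val = np.inf
        best_state = None
        best_epoch = -1
        patience_left = cfg_t.patience

        for epoch in range(cfg_t.max_epochs):
            net.train(True)
            perm = rng.permutation(len(fit_idx))
            epoch_reports = []
            for lo in range(0, len(fit_idx), cfg_t.batch_size):
                batch = fit_idx[perm[lo : lo + cfg_t.batch_size]]
                opt.zero_grad()
                _, total, report = self._forward(net, batch, weights)
                if not np.isfinite(report.total):
                    raise NonFiniteLossError(epoch, batch, report)
                total.backward()
                opt.step()
                epoch_reports.append(report)
            trace.append(
                LossReport(
                    synergy=float(np.mean([r.synergy for r in epoch_reports])),
                    toxic=float(np.mean([r.toxic for r in epoch_reports])),
                    compactness=float(np.mean([r.compactness for r in epoch_reports])),
                    descriptive=float(np.mean([r.descriptive for r in epoch_reports])),
                    total=float(np.mean([r.total for r in epoch_reports])),
                )
            )

            val_loss = self._validation_loss(net, val_idx, weights)
            val_trace.append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = [p.data.copy() for p in net.parameters()]
                best_epoch = epoch
                patience_left = cfg_t.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

        if best_state is not None:
            for p, data in zip(net.parameters(), best_state):
                p.data = data

        test_metrics = None
        test_scores = None
        test_labels = None
        if test_idx is not None and len(test_idx):
            test_idx = np.asarray(test_idx)
            test_scores = self.predict_with(net, test_idx)
            test_labels = np.array(
                [self.bundle.samples[i].label for i in test_idx], dtype=int
            )
            test_metrics = evaluate_predictions(
                test_labels, test_scores, threshold=cfg_t.threshold
            )

        return SynergyResults(
            model=self, network=net, variant=variant, seed=seed,
            loss_trace=trace, val_trace=val_trace, best_epoch=best_epoch,
            train_idx=train_idx, test_idx=test_idx,
            test_scores=test_scores, test_labels=test_labels,
            metrics=test_metrics,
        )

    def _validation_loss(self, net: _Network, val_idx: np.ndarray,
                         weights: LossWeights) -> float:
        net.train(False)
        with no_grad():
            _, _, report = self._forward(net, val_idx, weights)
        return report.synergy

    def predict_with(self, net: _Network, idx: np.ndarray) -> np.ndarray:
        """Predicted synergy probabilities for samples (inference mode)."""
        net.train(False)
        scores = []
        bs = self.config.training.batch_size * 4
        with no_grad():
            for lo in range(0, len(idx), bs):
                o, _, _ = self._forward(
                    net, np.asarray(idx)[lo : lo + bs], LossWeights(0, 0, 0),
                    symmetrize=self.config.fusion.symmetrize,
                )
                scores.append(o.data)
        return np.concatenate(scores)

    # -- protocols ------------------------------------------------------------

    def cross_validate(self, plan: SplitPlan, seed: int = 0,
                       variant: str = "full") -> "CrossValidationResults":
        """Fit one model per fold of a split plan and pool the metrics."""
        fold_results = [
            self.fit(train_idx=tr, test_idx=te, seed=seed + i, variant=variant)
            for i, (tr, te) in enumerate(plan.folds)
        ]
        return CrossValidationResults(plan=plan, fold_results=fold_results,
                                      variant=variant)


@dataclass
class SynergyResults:
    """Fitted synergy model: loss trace, held-out metrics, summary table."""

    model: SynergyModel
    network: _Network
    variant: str
    seed: int
    loss_trace: list[LossReport]
    val_trace: list[float]
    best_epoch: int
    train_idx: np.ndarray
    test_idx: np.ndarray | None
    test_scores: np.ndarray | None
    test_labels: np.ndarray | None
    metrics: MetricReport | None

    @property
    def n_epochs(self) -> int:
        return len(self.loss_trace)

    def predict(self, idx: np.ndarray) -> np.ndarray:
        return self.model.predict_with(self.network, idx)

    def loss_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.as_dict() for r in self.loss_trace])
        df["val_synergy"] = self.val_trace
        df.index.name = "epoch"
        return df

    def save_training_log(self, path) -> None:
        self.loss_frame().to_csv(path, sep="\t")

    def summary(self) -> str:
        lines = [
            "Synergy model fit",
            "=================",
            f"variant:        {self.variant}",
            f"seed:           {self.seed}",
            f"train samples:  {len(self.train_idx)}",
            f"epochs run:     {self.n_epochs} (best at {self.best_epoch})",
            f"final train loss: {self.loss_trace[-1].total:.4f}",
            f"best val synergy loss: {min(self.val_trace):.4f}",
        ]
        if self.metrics is not None:
            m = self.metrics
            lines += [
                f"test samples:   {len(self.test_idx)}",
                f"  ACC     {m.acc:.4f}",
                f"  Recall  {m.recall:.4f}",
                f"  F1      {m.f1:.4f}",
                f"  AUC-ROC {m.auc_roc if m.auc_roc is None else format(m.auc_roc, '.4f')}",
                f"  AUC-PR  {m.auc_pr if m.auc_pr is None else format(m.auc_pr, '.4f')}",
            ]
        return "\n".join(lines)


@dataclass
class CrossValidationResults:
    plan: SplitPlan
    fold_results: list[SynergyResults]
    variant: str

    def metric_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in zip(self.plan.fold_names or range(len(self.fold_results)),
                             self.fold_results):
            rows.append({"fold": name, **res.metrics.as_dict()})
        return pd.DataFrame(rows).set_index("fold")

    def mean_metrics(self) -> dict[str, float]:
        df = self.metric_frame()
        return {k: float(df[k].mean()) for k in df.columns}

    def metric_vector(self, metric: str) -> np.ndarray:
        return self.metric_frame()[metric].to_numpy(dtype=float)

    def summary(self) -> str:
        df = self.metric_frame()
        mean = df.mean(numeric_only=True)
        lines = [
            f"{self.plan.mode} cross-validation ({len(self.fold_results)} folds, "
            f"variant={self.variant})",
            df.round(4).to_string(),
            "mean: " + "  ".join(f"{k}={v:.4f}" for k, v in mean.items()),
        ]
        return "\n".join(lines)


def run_ablation(
    bundle: DatasetBundle,
    config: ModelConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seeds: list[int],
    variants: tuple[str, ...] = losses.ABLATION_VARIANTS,
) -> pd.DataFrame:
    """Fit every ablation variant for every seed on one split.

    Returns a tidy frame with one row per (variant, seed) and the test
    metrics as columns.
    """
    rows = []
    for seed in seeds:
        model = SynergyModel(bundle, config)  # protein space shared across variants
        for variant in variants:
            res = model.fit(train_idx=train_idx, test_idx=test_idx,
                            seed=seed, variant=variant)
            rows.append({"variant": variant, "seed": seed,
                         **res.metrics.as_dict()})
    return pd.DataFrame(rows)
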