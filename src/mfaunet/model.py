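"""High-level modelling interface.

``VesselSegmenter`` binds a dataset to the architecture and training
configuration; ``fit()`` runs the patch-based optimisation and returns a
``SegmentationResults`` object carrying the fitted network, the learning
curves, held-out diagnostics and a ``summary()`` table, with
``predict()`` / ``evaluate()`` for downstream use.

    >>> seg = VesselSegmenter.from_directory("data/synth",
    ...                                      model_config=slim_config(7))
    >>> res = seg.fit()
    >>> print(res.summary())
    >>> prob = res.predict(image)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine
from .network import MFAUNet, ModelConfig
from .preprocess import PreprocessConfig


class VesselSegmenter:
    """MFA-UNet bound to a training dataset.

    Parameters
    ----------
    data
        A dataset directory (images/ + masks/ [+ fov/]), a list of sample
        dicts, or a prepared ``(X, Y, groups)`` patch triple.
    model_config, train_config, preprocess_config
        Architecture, optimisation and enhancement settings; defaults are
        the reference configuration.
    """

    def __init__(self, data, model_config: ModelConfig | None = None,
                 train_config: engine.TrainConfig | None = None,
                 preprocess_config: PreprocessConfig | None = None):
        self.data = data
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or engine.TrainConfig()
        self.preprocess_config = preprocess_config or PreprocessConfig()

    @classmethod
    def from_directory(cls, path, **kwargs) -> "VesselSegmenter":
        return cls(engine.load_dataset(path), **kwargs)

    def fit(self, checkpoint_path=None, val_images=None) -> "SegmentationResults":
        model, record = engine.train(
            self.model_config, self.train_config, self.data,
            pre_cfg=self.preprocess_config, checkpoint_path=checkpoint_path,
            val_images=val_images)
        return SegmentationResults(model, record, self)


@dataclass
class SegmentationResults:
    """Fitted network plus its training history and diagnostics."""

    model: MFAUNet
    record: engine.RunRecord
    parent: VesselSegmenter | None = None

    @property
    def learning_curve(self) -> list[engine.EpochStats]:
        return self.record.epochs

    @property
    def best_epoch(self) -> int:
        return self.record.best_epoch

    @property
    def n_parameters(self) -> int:
        return self.model.count_parameters()

    def predict(self, image: np.ndarray, window: int = 64,
                stride: int = 32) -> np.ndarray:
        pre = self.parent.preprocess_config if self.parent else None
        return engine.predict_image(self.model, image, pre, window, stride)

    def evaluate(self, data, threshold: float = 0.5, **kwargs) -> dict:
        pre = self.parent.preprocess_config if self.parent else None
        return engine.evaluate_dataset(self.model, data, threshold,
                                       pre_cfg=pre, **kwargs)

    def save(self, path) -> None:
        engine.save_checkpoint(self.model, path, self.record)

    def summary(self) -> str:
        cfg = self.model.cfg
        toggles = "+".join(t for t, on in [("MSAM", cfg.use_msam),
                                           ("PAM", cfg.use_pam),
                                           ("MBDM", cfg.use_mbdm)] if on)
        lines = [
            "MFA-UNet segmentation results",
            "=" * 64,
            f"encoder channels : {cfg.encoder_channels}",
            f"modules enabled  : {toggles or 'none (baseline)'}",
            f"parameters       : {self.n_parameters:,}",
            f"epochs trained   : {len(self.record.epochs)}",
            f"best epoch (AUC) : {self.best_epoch}"
            f"  val AUC {self.record.best_val_auc:.4f}",
            "-" * 64,
            f"{'epoch':>5} {'lr':>9} {'train loss':>11} {'val loss':>9}"
            f" {'val acc':>8} {'val AUC':>8} {'val DSC':>8}",
        ]
        for e in self.record.epochs:
            lines.append(f"{e.epoch:>5} {e.lr:>9.2e} {e.train_loss:>11.4f}"
                         f" {e.val_loss:>9.4f} {e.val_acc:>8.4f}"
                         f" {e.val_auc:>8.4f} {e.val_dsc:>8.4f}")
        lines.append("=" * 64)
        return "\n".join(lines)
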