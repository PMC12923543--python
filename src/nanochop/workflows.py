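"""End-to-end simulate -> train -> evaluate pipelines.

These runners wire the generator, classifier and metrics together at a scale
a single CPU handles in minutes: the small model preset and the short
desk-scale training schedule. They back both the command line and the
reproduction script.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional

import numpy as np

from . import model as M
from . import simulate as S

logger = logging.getLogger(__name__)


def benchmark_classifier(
    n_reads: int = 20000,
    seed: int = 0,
    model_config: Optional[M.ModelConfig] = None,
    train_config: Optional[M.TrainConfig] = None,
) -> Dict[str, float]:
    """Simulate a default dataset, train the small model, evaluate the test split.

    Reads are generated at the standard study conditions (9:1 positive:negative,
    1:1 internal:3'-end, default corruption and quality models), split 8:1:1
    stratified, and pooled per-base precision/recall/F1 are computed on the
    held-out test split.
    """
    splits = S.generate_dataset(n_reads, seed=seed)
    model_config = model_config or M.ModelConfig.small(seed=seed)
    train_config = train_config or M.TrainConfig.desk_scale(shuffle_seed=seed)
    trained, history = M.train(splits.train, splits.val, model_config, train_config)
    report = evaluate_on_reads(trained, splits.test)
    return dict(
        f1=report.f1,
        precision=report.precision,
        recall=report.recall,
        accuracy=report.accuracy,
        n_train=len(splits.train),
        n_test=len(splits.test),
        best_val_f1=max((h["val_f1"] for h in history), default=0.0),
    )


def benchmark_quality_ablation(
    n_reads: int = 10000,
    seed: int = 0,
    model_config: Optional[M.ModelConfig] = None,
    train_config: Optional[M.TrainConfig] = None,
) -> Dict[str, float]:
    """Train with and without the quality block on a quality-separable dataset.

    The dataset uses per-read randomized adapter templates (adapter base
    composition matches the transcript bodies) with a low adapter quality
    mean, so per-base quality is the discriminative signal the quality block
    can exploit. Both variants share data and hyperparameters.
    """
    splits = S.generate_dataset(n_reads, seed=seed, adapters=S.ablation_adapter_model())
    base_config = model_config or M.ModelConfig.small(seed=seed)
    train_config = train_config or M.TrainConfig.desk_scale(shuffle_seed=seed)

    results = {}
    for label, use_quality in (("ablated", False), ("full", True)):
        cfg_kwargs = {
            k: getattr(base_config, k)
            for k in (
                "embed_dim",
                "quality_hidden_dim",
                "backbone_layers",
                "kernel_width",
                "dilation_base",
                "max_input_length",
                "seed",
            )
        }
        cfg = M.ModelConfig(use_quality=use_quality, **cfg_kwargs)
        trained, _ = M.train(splits.train, splits.val, cfg, train_config)
        report = evaluate_on_reads(trained, splits.test)
        results[f"f1_{label}"] = report.f1
        logger.info("%s model test F1: %.4f", label, report.f1)
    results["n_test"] = len(splits.test)
    return results


def evaluate_on_reads(model: M.AdapterClassifier, reads) -> M.EvalReport:
    """Pooled per-base metrics of a model's raw predictions on labeled reads."""
    records = [r.record for r in reads]
    tracks = model.predict(records)
    truths = [np.asarray(r.labels) for r in reads]
    return M.evaluate(tracks, truths)
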