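"""Experiment naming, grid enumeration and runners.

Attention settings are named by a compact grammar:

* ``wo_attention`` — plain backbone;
* ``w_CHatt3(8)`` — channel attention after conv layer 3, reduction 8;
* ``w_CHatt(8)`` — channel attention after all four conv layers;
* ``w_SPatt1(5)`` — spatial attention after conv layer 1, kernel 5;
* ``w_CHSPatt4(2)(7)`` — channel-then-spatial after layer 4, r=2, k=7.

The full study grid crosses reduction ratios {1, 2, 4, 8, 16} and kernel
sizes {3, 5, 7} with placements {1, 2, 3, 4, all}: 25 channel + 15
spatial + 75 combined = 115 attention configurations next to the one
baseline.
"""

from __future__ import annotations

import re
import time
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .attention import (
    AttentionSpec,
    CANONICAL_KERNEL_SIZES,
    CANONICAL_REDUCTION_RATIOS,
    PLACEMENTS,
    attention_param_count,
)
from .data import WindowedDataset, kfold
from .evaluation import evaluate, fold_summary
from .model import ModelConfig, TrainConfig, build_model, count_trainable_params, train
from .synthetic import PRESETS, make_benchmark

__all__ = [
    "format_name",
    "parse_name",
    "enumerate_grid",
    "report_param_table",
    "run_experiment",
    "run_grid",
    "relative_overhead_percent",
    "PUBLISHED_BASE_PARAMS",
]

#: published total parameter counts of the attention-free models, used to
#: express attention overheads as percentages of the deployed model size
PUBLISHED_BASE_PARAMS = {"opportunity": 822_098, "pamap2": 1_415_244}

_NAME_RE = re.compile(r"^w_(CHSP|CH|SP)att([1-4]?)\((\d+)\)(?:\((\d+)\))?$")

_GRAMMAR = (
    "wo_attention | w_CHattx(r) | w_CHatt(r) | w_SPattx(k) | w_SPatt(k) | "
    "w_CHSPattx(r)(k) | w_CHSPatt(r)(k), with x in {1,2,3,4}"
)


def format_name(spec: Optional[AttentionSpec]) -> str:
    """Canonical experiment name for an attention spec (None = baseline)."""
    if spec is None:
        return "wo_attention"
    x = "" if spec.placement == "all" else str(spec.placement)
    if spec.mode == "CH":
        return f"w_CHatt{x}({spec.r})"
    if spec.mode == "SP":
        return f"w_SPatt{x}({spec.k})"
    return f"w_CHSPatt{x}({spec.r})({spec.k})"


def parse_name(name: str) -> Optional[AttentionSpec]:
    """Inverse of :func:`format_name`; raises on anything off-grammar."""
    if name == "wo_attention":
        return None
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse experiment name {name!r}; grammar: {_GRAMMAR}")
    mode, x, first, second = m.groups()
    placement: Union[int, str] = int(x) if x else "all"
    if mode == "CH":
        if second is not None:
            raise ValueError(f"{name!r}: channel attention takes a single (r)")
        return AttentionSpec(mode="CH", r=int(first), placement=placement)
    if mode == "SP":
        if second is not None:
            raise ValueError(f"{name!r}: spatial attention takes a single (k)")
        return AttentionSpec(mode="SP", k=int(first), placement=placement)
    if second is None:
        raise ValueError(f"{name!r}: combined attention needs both (r)(k)")
    return AttentionSpec(mode="CHSP", r=int(first), k=int(second),
                         placement=placement)


def enumerate_grid() -> list[tuple[str, AttentionSpec]]:
    """All 115 attention configurations of the study, canonically ordered.

    Channel first (25), then spatial (15), then combined (75); within
    each family the parameter values ascend and placements run 1-4 then
    ``all``.
    """
    grid: list[tuple[str, AttentionSpec]] = []
    for r in CANONICAL_REDUCTION_RATIOS:
        for placement in PLACEMENTS:
            spec = AttentionSpec(mode="CH", r=r, placement=placement)
            grid.append((format_name(spec), spec))
    for k in CANONICAL_KERNEL_SIZES:
        for placement in PLACEMENTS:
            spec = AttentionSpec(mode="SP", k=k, placement=placement)
            grid.append((format_name(spec), spec))
    for r in CANONICAL_REDUCTION_RATIOS:
        for k in CANONICAL_KERNEL_SIZES:
            for placement in PLACEMENTS:
                spec = AttentionSpec(mode="CHSP", r=r, k=k, placement=placement)
                grid.append((format_name(spec), spec))
    return grid


def report_param_table(n_channels: int = 64) -> pd.DataFrame:
    """Additional-parameter counts for the single-placement grid settings.

    One row per channel (5), spatial (3) and combined (15) setting; the
    ``all``-layers variants cost four times the listed figure.
    """
    rows = []
    for r in CANONICAL_REDUCTION_RATIOS:
        spec = AttentionSpec(mode="CH", r=r, placement=1)
        rows.append(("w_CHattx(r)", r, None,
                     attention_param_count(spec, n_channels)))
    for k in CANONICAL_KERNEL_SIZES:
        spec = AttentionSpec(mode="SP", k=k, placement=1)
        rows.append(("w_SPattx(k)", None, k,
                     attention_param_count(spec, n_channels)))
    for r in CANONICAL_REDUCTION_RATIOS:
        for k in CANONICAL_KERNEL_SIZES:
            spec = AttentionSpec(mode="CHSP", r=r, k=k, placement=1)
            rows.append(("w_CHSPattx(r)(k)", r, k,
                         attention_param_count(spec, n_channels)))
    return pd.DataFrame(rows, columns=["setting", "r", "k", "additional_params"])


def relative_overhead_percent(additional: int, base_params: int,
                              ndigits: int = 3) -> float:
    """Attention overhead as a percentage of the base model size."""
    return round(100.0 * additional / base_params, ndigits)


def _resolve_dataset(dataset, seed: int, folds: Optional[int]) -> WindowedDataset:
    if isinstance(dataset, str):
        if dataset not in PRESETS:
            raise ValueError(f"unknown preset {dataset!r}; choose from "
                             f"{sorted(PRESETS)}")
        return make_benchmark(dataset, seed=seed, folds=folds)
    ds = dataset
    if folds is not None and ds.fold is None:
        ds = kfold(ds, k=folds, seed=seed)
    return ds


def run_experiment(name: str, dataset, eval_mode: str = "holdout",
                   seed: int = 0, epochs: int = 10, folds: int = 5,
                   lstm_dropout: float = 0.0, patience: Optional[int] = None,
                   model_overrides: Optional[dict] = None) -> dict:
    """Train and evaluate one named attention setting; returns a result row.

    *dataset* is a preset name or a :class:`WindowedDataset` (already
    split; a fold assignment is added when needed).  ``eval_mode`` is
    ``"holdout"`` (train split -> test split, validation checkpointing)
    or ``"5fold"`` (one model per fold, mean and sample std reported).
    """
    if eval_mode not in ("holdout", "5fold"):
        raise ValueError("eval_mode must be 'holdout' or '5fold'")
    spec = parse_name(name)
    ds = _resolve_dataset(dataset, seed,
                          folds if eval_mode == "5fold" else None)
    h, d = ds.window_shape
    overrides = dict(model_overrides or {})
    cfg = ModelConfig(
        window_length=h, n_signals=d, n_classes=ds.n_classes,
        attention=(spec,) if spec is not None else (),
        lstm_dropout=lstm_dropout, seed=seed, **overrides,
    )
    base_cfg = ModelConfig(
        window_length=h, n_signals=d, n_classes=ds.n_classes,
        lstm_dropout=lstm_dropout, seed=seed, **overrides,
    )
    delta = count_trainable_params(build_model(cfg)) - count_trainable_params(
        build_model(base_cfg))
    tc = TrainConfig(max_epochs=epochs, seed=seed, patience=patience)

    t0 = time.perf_counter()
    if eval_mode == "holdout":
        model, _ = train(build_model(cfg), ds, tc)
        test = ds.subset(split="test")
        report = evaluate(test.labels, model.predict(test.windows), ds.class_names)
        f1_mean, f1_sstd = report.macro_f1, None
        per_class = report.per_class_f1
    else:
        fold_scores = []
        per_class = np.zeros(ds.n_classes)
        n_folds = int(ds.fold.max()) + 1
        for f in range(n_folds):
            tr = ds.subset(exclude_fold=f)
            tr.split = None  # train on everything outside the held-out fold
            model, _ = train(build_model(cfg), tr, tc)
            held = ds.subset(fold=f)
            rep = evaluate(held.labels, model.predict(held.windows), ds.class_names)
            fold_scores.append(rep.macro_f1)
            per_class += rep.per_class_f1 / n_folds
        f1_mean, f1_sstd = fold_summary(fold_scores)
    runtime = time.perf_counter() - t0

    return dict(
        name=name,
        mode=spec.mode if spec else "none",
        r=spec.r if spec else None,
        k=spec.k if spec else None,
        placement=str(spec.placement) if spec else None,
        eval_mode=eval_mode,
        macro_f1=float(f1_mean),
        sstd=None if f1_sstd is None else float(f1_sstd),
        per_class_f1=[round(float(v), 4) for v in per_class],
        attention_param_delta=int(delta),
        seed=seed,
        epochs=epochs,
        runtime_s=round(runtime, 2),
    )


def run_grid(dataset, eval_mode: str = "holdout", seed: int = 0,
             epochs: int = 10, folds: int = 5, lstm_dropout: float = 0.0,
             model_overrides: Optional[dict] = None,
             out_csv=None, names: Optional[Sequence[str]] = None
             ) -> pd.DataFrame:
    """Run the baseline plus the (possibly restricted) grid; 1 + 115 rows
    by default."""
    ds = _resolve_dataset(dataset, seed, folds if eval_mode == "5fold" else None)
    todo = ["wo_attention"] + (list(names) if names is not None
                               else [n for n, _ in enumerate_grid()])
    rows = []
    for name in todo:
        rows.append(run_experiment(name, ds, eval_mode=eval_mode, seed=seed,
                                   epochs=epochs, folds=folds,
                                   lstm_dropout=lstm_dropout,
                                   model_overrides=model_overrides))
        if out_csv is not None:
            pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)
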