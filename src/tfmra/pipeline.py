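"""End-to-end orchestration: data -> TFD -> 2D MRA -> features -> CV report.

A :class:`RunConfig` captures every stage knob and serializes losslessly to
a single JSON document that is embedded in each report for provenance.  The
grid runner shares TF images across MRA methods and feature tables across
classifiers, so method-comparison sweeps do not recompute common stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, features, mra2d, preprocess, synth, tfd

logger = logging.getLogger("tfmra")

FEATURE_METHODS = ("curvelet", "wavelet2d", "dwt1d")


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    # input: either a recording file or the synthetic generator
    input_path: str | None = None
    input_format: str | None = None
    channel: str | int = "Fpz"
    use_synth: bool = True
    synth: dict = field(default_factory=dict)   # SynthConfig overrides
    # preprocessing
    highpass_hz: float = 0.5
    window_s: float = 1.0
    # TFD
    tfd_kernel: str = "swvd"
    tfd_sigma: float = 0.8
    tfd_mbd_beta: float = 0.02
    tfd_window_kind: str = "hanning"
    tfd_window_len: int | None = None
    # 2D MRA
    mra_method: str = "curvelet"
    tf_image_size: int = 256
    wavelet_levels: int = 4
    wavelet_name: str = "haar"
    curvelet_scales: int = 5
    curvelet_angles: int = 8
    # features
    n_gray_levels: int = 8
    # classification
    model: str = "svm_rbf"
    svm_c: float = 10.0
    tree_max_splits: int = 100
    k_folds: int = 10
    pca_components: int = 0             # 0 disables PCA
    seed: int = 0
    out_dir: str = "tfmra_out"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def kernel_spec(self) -> tfd.TfdKernelSpec:
        return tfd.TfdKernelSpec(
            kind=self.tfd_kernel, sigma=self.tfd_sigma,
            mbd_beta=self.tfd_mbd_beta, window_kind=self.tfd_window_kind,
            window_len=self.tfd_window_len)

    def model_spec(self) -> classify.ModelSpec:
        return classify.ModelSpec(
            kind=self.model, svm_c=self.svm_c,
            tree_max_splits=self.tree_max_splits, seed=self.seed)

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(seed=self.seed, **self.synth)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def load_segments(cfg: RunConfig) -> tuple[list[preprocess.Segment], list[str]]:
    """Resolve the configured input into labeled (or unlabeled) segments."""
    if cfg.use_synth:
        ds = synth.synth_dataset(cfg.synth_config())
        return ds.segments, [s.label for s in ds.segments]
    rec = preprocess.read_signal(cfg.input_path, cfg.input_format, cfg.channel)
    rec = preprocess.highpass_filter(rec, cfg.highpass_hz)
    segs = preprocess.make_segments(rec, cfg.channel, cfg.window_s)
    return segs, [s.label for s in segs]


def tf_images(segments: list[preprocess.Segment],
              spec: tfd.TfdKernelSpec, tf_image_size: int) -> list[np.ndarray]:
    """TFD of each segment, resized to the square MRA input grid."""
    shape = (tf_image_size, tf_image_size)
    return [mra2d.resize_tf_image(tfd.compute_tfd(s, spec).values, shape)
            for s in segments]


def features_from_images(images: list[np.ndarray], method: str,
                         cfg: RunConfig,
                         segments: list[preprocess.Segment] | None = None,
                         ) -> pd.DataFrame:
    """Feature table for one MRA method from precomputed TF images."""
    rows = []
    if method == "curvelet":
        for img in images:
            dec = mra2d.fdct_wrapping(img, cfg.curvelet_scales,
                                      cfg.curvelet_angles)
            fv = features.curvelet_feature_vector(
                mra2d.select_subbands(dec), cfg.n_gray_levels)
            rows.append(fv)
    elif method == "wavelet2d":
        for img in images:
            dec = mra2d.dwt2(img, cfg.wavelet_levels, cfg.wavelet_name)
            fv = features.wavelet_feature_vector(dec, cfg.n_gray_levels)
            rows.append(fv)
    elif method == "dwt1d":
        if segments is None:
            raise ValueError("dwt1d features need the raw segments")
        rows = [features.dwt1d_baseline_features(s) for s in segments]
    else:
        raise ValueError(f"unknown feature method {method!r}; "
                         f"choose from {FEATURE_METHODS}")
    return pd.DataFrame([fv.values for fv in rows], columns=rows[0].names)


def extract_features(cfg: RunConfig,
                     segments: list[preprocess.Segment]) -> pd.DataFrame:
    images = (tf_images(segments, cfg.kernel_spec(), cfg.tf_image_size)
              if cfg.mra_method != "dwt1d" else [])
    return features_from_images(images, cfg.mra_method, cfg, segments)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and persist a report.

    Writes ``features.csv``, ``confusion.csv``, and ``metrics.json`` (with
    the full config embedded) under ``cfg.out_dir``.  Any stage failure is
    re-raised with the failing stage named; artifacts written so far remain.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "ingest"
    try:
        t0 = time.perf_counter()
        segments, labels = load_segments(cfg)
        timings[stage] = time.perf_counter() - t0
        logger.info("ingest: %d segments", len(segments))

        stage = "features"
        t0 = time.perf_counter()
        table = extract_features(cfg, segments)
        timings[stage] = time.perf_counter() - t0
        table_out = table.copy()
        table_out["label"] = labels
        table_out.to_csv(out / "features.csv", index=False)

        stage = "classify"
        t0 = time.perf_counter()
        X = table.to_numpy()
        feature_names = list(table.columns)
        pca_info = None
        if cfg.pca_components:
            model, X = classify.pca_reduce(X, cfg.pca_components,
                                           feature_names)
            pca_info = {
                "n_kept": model.n_kept,
                "explained_variance_ratio":
                    model.explained_variance_ratio.tolist(),
            }
        cv = classify.run_cv(X, labels, cfg.model_spec(),
                             k_folds=cfg.k_folds, seed=cfg.seed)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    pd.DataFrame(cv.confusion, index=cv.class_names,
                 columns=cv.class_names).to_csv(out / "confusion.csv")
    report = {
        "config": dataclasses.asdict(cfg),
        "n_segments": len(segments),
        "n_features": int(X.shape[1]),
        "total_accuracy_pct": cv.total_accuracy,
        "per_class_sensitivity_pct": {
            c: (None if np.isnan(v) else float(v))
            for c, v in zip(cv.class_names, cv.per_class_sensitivity)},
        "per_class_specificity_pct": {
            c: (None if np.isnan(v) else float(v))
            for c, v in zip(cv.class_names, cv.per_class_specificity)},
        "pca": pca_info,
        "timings_s": timings,
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("classify: accuracy %.2f%%", cv.total_accuracy)
    return report


def run_grid(base: RunConfig,
             kernels: tuple[str, ...] = ("wvd", "swvd", "spec", "gkd", "mbd", "sepk"),
             methods: tuple[str, ...] = ("curvelet", "wavelet2d", "dwt1d"),
             models: tuple[str, ...] = ("svm_rbf", "complex_tree", "knn1"),
             window_lengths: tuple[float, ...] = (1.0,)) -> pd.DataFrame:
    """Accuracy over {kernel} x {MRA method} x {model} x {window length}.

    TF images are computed once per (kernel, window) and feature tables once
    per (kernel, window, method), then reused across classifiers.
    """
    records = []
    for window_s in window_lengths:
        cfg_w = dataclasses.replace(base, window_s=window_s)
        if cfg_w.use_synth:
            cfg_w.synth = {**cfg_w.synth, "trial_s": window_s}
        segments, labels = load_segments(cfg_w)
        for kernel in kernels:
            cfg_k = dataclasses.replace(cfg_w, tfd_kernel=kernel)
            needs_images = any(m != "dwt1d" for m in methods)
            images = (tf_images(segments, cfg_k.kernel_spec(),
                                cfg_k.tf_image_size) if needs_images else [])
            for method in methods:
                table = features_from_images(images, method, cfg_k, segments)
                for model in models:
                    cfg_m = dataclasses.replace(cfg_k, mra_method=method,
                                                model=model)
                    cv = classify.run_cv(table.to_numpy(), labels,
                                         cfg_m.model_spec(),
                                         k_folds=cfg_m.k_folds,
                                         seed=cfg_m.seed)
                    records.append({
                        "window_s": window_s, "kernel": kernel,
                        "method": method, "model": model,
                        "accuracy_pct": cv.total_accuracy,
                    })
                    logger.info("grid %s/%s/%s/%ss: %.2f%%", kernel, method,
                                model, window_s, cv.total_accuracy)
    return pd.DataFrame.from_records(records)
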