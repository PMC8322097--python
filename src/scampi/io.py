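"""Pipeline orchestration: load class folders, fit image models, train/test
split, discriminate, estimate probabilities, and write reports.

All randomness flows from ``RunConfig.seed``; identical configs produce
byte-identical CSV output (floats fixed to 12 significant digits).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .baselines import signal_lognormal, spreading_area, kullback_mdi
from .discriminate import (
    ClassParameterMatrix,
    FLDModel,
    fld_classify,
    fld_fit,
    fld_project,
)
from .errors import InvalidImageError, ScampiError
from .image_model import GrayscaleImage, ImageModelFit, select_lag_order
from .probability import LogisticModel, logistic_fit, logistic_predict

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Configuration for one two-class discrimination run."""

    class_dirs: dict[str, str]
    train_count: int = 80
    seed: int = 0
    alpha_t: float = 0.05
    alpha_chi: float = 0.01
    max_lag: int = 3
    output_dir: str | None = None
    r2_flavor: str = "uncentered"
    decision_rule: str = "midpoint"
    spreading_threshold: float | None = None
    lr_on: str = "test"  # which projections feed the logistic fit

    def __post_init__(self):
        if len(self.class_dirs) != 2:
            raise ValueError(
                f"exactly two classes required, got {len(self.class_dirs)}"
            )
        if self.lr_on not in ("test", "train"):
            raise ValueError("lr_on must be 'test' or 'train'")


@dataclass
class RunReport:
    """Everything produced by :func:`run_pipeline`."""

    config: RunConfig
    fits: pd.DataFrame
    fld_model: FLDModel
    projections: pd.DataFrame
    probabilities: pd.DataFrame
    baselines: pd.DataFrame
    logistic_model: LogisticModel
    accuracy: float
    confusion: dict
    split: dict[str, dict[str, list[str]]]
    timings: dict[str, float]
    kullback: dict


def load_image(path) -> GrayscaleImage:
    """Read a single-channel TIFF as a float64 image.

    Multi-page or multi-channel files are rejected.  A sidecar
    ``metadata.json`` in the same folder may provide ``pixel_size_nm``.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) != 1:
                raise InvalidImageError(
                    f"{path}: multi-page TIFF ({len(tf.pages)} pages) not supported"
                )
            arr = tf.pages[0].asarray()
    except InvalidImageError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface the offending file
        raise InvalidImageError(f"{path}: unreadable TIFF ({exc})") from exc
    if arr.ndim != 2:
        raise InvalidImageError(
            f"{path}: expected single-channel 2-D image, got shape {arr.shape}"
        )
    pixel_size = 73.0
    meta = path.parent / "metadata.json"
    if meta.exists():
        try:
            pixel_size = float(json.loads(meta.read_text()).get("pixel_size_nm", 73.0))
        except (ValueError, json.JSONDecodeError):
            pass
    try:
        return GrayscaleImage(pixels=arr.astype(np.float64), pixel_size=pixel_size)
    except InvalidImageError as exc:
        raise InvalidImageError(f"{path}: {exc}") from exc


def load_class_images(
    directory, label: str
) -> tuple[list[GrayscaleImage], list[str]]:
    """Load every TIFF in a folder in deterministic filename-sorted order."""
    directory = Path(directory)
    if not directory.is_dir():
        raise ScampiError(f"class {label!r}: directory not found: {directory}")
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    if not paths:
        raise ScampiError(f"class {label!r}: no TIFF files in {directory}")
    images = [load_image(p) for p in paths]
    return images, [p.name for p in paths]


def split_train_test(
    ids: Sequence[str], train_count: int, seed: int
) -> tuple[list[str], list[str]]:
    """Uniform random train subset without replacement; complement is test."""
    ids = list(ids)
    if train_count <= 0:
        raise ValueError("train_count must be positive")
    if train_count >= len(ids):
        raise ValueError(
            f"train_count {train_count} must be < number of images {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ids), size=train_count, replace=False)
    train_set = set(int(i) for i in idx)
    train = [ids[i] for i in sorted(train_set)]
    test = [ids[i] for i in range(len(ids)) if i not in train_set]
    return train, test


def fit_all_images(
    images: Sequence[GrayscaleImage],
    ids: Sequence[str],
    label: str,
    alpha_t: float = 0.05,
    alpha_chi: float = 0.01,
    max_lag: int = 3,
) -> pd.DataFrame:
    """Fit the lag model for each image; one CSV-ready row per image."""
    rows = []
    for img, iid in zip(images, ids):
        fit = select_lag_order(
            img, alpha_t=alpha_t, alpha_chi=alpha_chi, max_order=max_lag
        )
        row = {"file": iid, "label": label, "lag_order": fit.lag_order}
        offsets = fit.lags.offsets
        for h, (di, dj) in enumerate(offsets):
            tag = f"{di}{dj}"
            row[f"beta_{tag}"] = fit.beta[h]
            row[f"se_{tag}"] = fit.std_errors[h]
            row[f"t_{tag}"] = fit.t_stats[h]
            row[f"p_{tag}"] = fit.p_values[h]
        row.update(
            r_squared=fit.r_squared,
            r_squared_centered=fit.r_squared_centered,
            n_samples=fit.n_samples,
            wald_chi2=fit.wald_chi2,
            wald_p=fit.wald_p,
            significant=fit.significant,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _beta_matrix(fits: pd.DataFrame, files: Sequence[str], label: str):
    sub = fits[fits["label"] == label].set_index("file").loc[list(files)]
    beta_cols = [c for c in fits.columns if c.startswith("beta_")]
    # pairwise discrimination requires a common k; the selection search on
    # homogeneous data returns the same order for every image
    orders = sub["lag_order"].unique()
    if len(orders) != 1:
        min_order = int(orders.min())
        beta_cols = [c for c in beta_cols if c in _order_cols(min_order)]
    rows = sub[beta_cols].to_numpy(dtype=np.float64)
    return ClassParameterMatrix(label=label, rows=rows, image_ids=tuple(files))


def _order_cols(order: int) -> list[str]:
    from .image_model import LagStructure

    return [f"beta_{di}{dj}" for di, dj in LagStructure(order).offsets]


def run_pipeline(
    config: RunConfig,
    preloaded: dict[str, tuple[list[GrayscaleImage], list[str]]] | None = None,
) -> RunReport:
    """Execute the full discrimination pipeline.

    ``preloaded`` maps a class label to ``(images, ids)`` and bypasses TIFF
    loading (used by the simulators and tests); otherwise images are read
    from ``config.class_dirs``.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    labels = list(config.class_dirs)
    data: dict[str, tuple[list[GrayscaleImage], list[str]]] = {}
    for label in labels:
        if preloaded and label in preloaded:
            data[label] = preloaded[label]
        else:
            data[label] = load_class_images(config.class_dirs[label], label)
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits = pd.concat(
        [
            fit_all_images(
                *data[label],
                label=label,
                alpha_t=config.alpha_t,
                alpha_chi=config.alpha_chi,
                max_lag=config.max_lag,
            )
            for label in labels
        ],
        ignore_index=True,
    )
    timings["fit_models"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lab_A, lab_B = labels
    split: dict[str, dict[str, list[str]]] = {}
    for c, label in enumerate(labels):
        ids = data[label][1]
        tr, te = split_train_test(ids, config.train_count, seed=config.seed + c)
        split[label] = {"train": tr, "test": te}

    train_A = _beta_matrix(fits, split[lab_A]["train"], lab_A)
    train_B = _beta_matrix(fits, split[lab_B]["train"], lab_B)
    model = fld_fit(train_A, train_B)

    test_A = _beta_matrix(fits, split[lab_A]["test"], lab_A)
    test_B = _beta_matrix(fits, split[lab_B]["test"], lab_B)
    proj_A = fld_project(model, test_A)
    proj_B = fld_project(model, test_B)
    test_proj = np.concatenate([proj_A, proj_B])
    test_truth = [lab_A] * len(proj_A) + [lab_B] * len(proj_B)
    test_ids = list(split[lab_A]["test"]) + list(split[lab_B]["test"])

    result = fld_classify(model, test_proj, test_truth, rule=config.decision_rule)

    proj_train_A = fld_project(model, train_A)
    proj_train_B = fld_project(model, train_B)
    train_result = fld_classify(
        model,
        np.concatenate([proj_train_A, proj_train_B]),
        [lab_A] * len(proj_train_A) + [lab_B] * len(proj_train_B),
        rule=config.decision_rule,
    )

    projections = pd.DataFrame(
        {
            "image_id": test_ids,
            "label": test_truth,
            "projection": test_proj,
            "predicted": list(result.labels),
        }
    )
    timings["discriminate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.lr_on == "test":
        lr_x, lr_y = test_proj, np.array([t == lab_B for t in test_truth], dtype=float)
    else:
        lr_x = np.concatenate([proj_train_A, proj_train_B])
        lr_y = np.concatenate(
            [np.zeros(len(proj_train_A)), np.ones(len(proj_train_B))]
        )
    lr = logistic_fit(lr_x, lr_y)
    probs = logistic_predict(lr, test_proj)
    probabilities = pd.DataFrame(
        {
            "image_id": test_ids,
            "projection": test_proj,
            "probability": probs,
            "label_if_known": test_truth,
        }
    )
    timings["logistic"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    base_rows = []
    for label in labels:
        for img, iid in zip(*data[label]):
            summ = signal_lognormal(img)
            row = {
                "file": iid,
                "label": label,
                "mean_intensity": summ.mean_intensity,
                "total_intensity": summ.total_intensity,
                "background_median": summ.background_median,
                "signal_threshold": summ.signal_threshold,
                "lognormal_mu": summ.lognormal_mu,
                "lognormal_sigma": summ.lognormal_sigma,
                "n_signal_pixels": summ.n_signal_pixels,
                "insufficient_signal": summ.insufficient_signal,
            }
            if config.spreading_threshold is not None:
                sa = spreading_area(img, config.spreading_threshold)
                row["spreading_pixels"] = sa.pixel_count
                row["spreading_area_um2"] = sa.area_um2
            base_rows.append(row)
    baselines_df = pd.DataFrame(base_rows)

    try:
        kb_stat, kb_p = kullback_mdi(proj_A, proj_B)
    except (ValueError, ScampiError):
        kb_stat, kb_p = None, None
    kullback = {
        "statistic": kb_stat,
        "p_value": kb_p,
        "note": (
            "(n_harmonic/2)*J with J the symmetric KL divergence between "
            "normals fitted to each test projection set; chi-square df=2 "
            "reference (documented interpretation)"
        ),
    }
    timings["baselines"] = time.perf_counter() - t0

    confusion = {
        "hits_A": result.hits_A,
        "hits_B": result.hits_B,
        "n_A": result.n_A,
        "n_B": result.n_B,
        "labels": [lab_A, lab_B],
        "train_accuracy": train_result.accuracy,
    }
    report = RunReport(
        config=config,
        fits=fits,
        fld_model=model,
        projections=projections,
        probabilities=probabilities,
        baselines=baselines_df,
        logistic_model=lr,
        accuracy=result.accuracy,
        confusion=confusion,
        split=split,
        timings=timings,
        kullback=kullback,
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def write_report(report: RunReport, output_dir) -> list[Path]:
    """Write the CSV/JSON artefacts with stable column order and formatting."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for name, df in (
        ("fits.csv", report.fits),
        ("projections.csv", report.projections),
        ("probabilities.csv", report.probabilities),
        ("baselines.csv", report.baselines),
    ):
        path = out / name
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        written.append(path)

    model_path = out / "fld_model.json"
    report.fld_model.to_json(model_path)
    written.append(model_path)

    lr_path = out / "logistic_model.json"
    report.logistic_model.to_json(lr_path)
    written.append(lr_path)

    run_path = out / "run.json"
    run_path.write_text(
        json.dumps(
            {
                "config": asdict(report.config),
                "split": report.split,
                "accuracy": report.accuracy,
                "confusion": report.confusion,
                "kullback": report.kullback,
                "timings_s": report.timings,
                "version": __version__,
            },
            indent=2,
        )
    )
    written.append(run_path)
    return written
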