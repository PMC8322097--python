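"""Two-class Fisher linear discriminant on per-image model parameters.

Each image contributes one row of lag-model coefficients; the discriminant
direction maximises between-class over within-class scatter of those rows.
Projections onto the direction are scalars, classified against a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateClassesError

#: Ridge fraction applied to a singular within-class scatter matrix.
RIDGE_EPS = 1e-8


@dataclass(frozen=True)
class ClassParameterMatrix:
    """Stack of per-image parameter vectors for one class."""

    label: str
    rows: np.ndarray
    image_ids: tuple[str, ...] = ()

    def __post_init__(self):
        arr = np.atleast_2d(np.asarray(self.rows, dtype=np.float64))
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"class {self.label!r}: non-finite parameter rows")
        object.__setattr__(self, "rows", arr)
        if self.image_ids and len(self.image_ids) != arr.shape[0]:
            raise ValueError("image_ids length does not match rows")
        object.__setattr__(self, "image_ids", tuple(self.image_ids))

    @property
    def n_images(self) -> int:
        return self.rows.shape[0]

    @property
    def n_params(self) -> int:
        return self.rows.shape[1]


@dataclass(frozen=True)
class FLDModel:
    """Fitted two-class Fisher discriminant.

    ``v_c`` is unit-norm and oriented so class B projects higher
    (``proj_mean_B > proj_mean_A``); ``threshold`` is the midpoint of the two
    training projection means unless the Gaussian-likelihood rule is used.
    """

    v_c: np.ndarray
    class_labels: tuple[str, str]
    proj_mean_A: float
    proj_mean_B: float
    proj_sd_A: float
    proj_sd_B: float
    threshold: float
    orientation: str = "B-high"
    ridge_applied: bool = False

    def to_json(self, path) -> None:
        payload = {
            "v_c": self.v_c.tolist(),
            "class_labels": list(self.class_labels),
            "proj_mean_A": self.proj_mean_A,
            "proj_mean_B": self.proj_mean_B,
            "proj_sd_A": self.proj_sd_A,
            "proj_sd_B": self.proj_sd_B,
            "threshold": self.threshold,
            "orientation": self.orientation,
            "ridge_applied": self.ridge_applied,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "FLDModel":
        d = json.loads(Path(path).read_text())
        return cls(
            v_c=np.asarray(d["v_c"], dtype=np.float64),
            class_labels=tuple(d["class_labels"]),
            proj_mean_A=d["proj_mean_A"],
            proj_mean_B=d["proj_mean_B"],
            proj_sd_A=d["proj_sd_A"],
            proj_sd_B=d["proj_sd_B"],
            threshold=d["threshold"],
            orientation=d.get("orientation", "B-high"),
            ridge_applied=d.get("ridge_applied", False),
        )


@dataclass(frozen=True)
class ClassificationResult:
    labels: tuple[str, ...]
    accuracy: float | None = None
    hits_A: int | None = None
    hits_B: int | None = None
    n_A: int | None = None
    n_B: int | None = None


def _scatter(rows: np.ndarray) -> np.ndarray:
    centered = rows - rows.mean(axis=0)
    return centered.T @ centered


def fld_fit(
    train_A: ClassParameterMatrix, train_B: ClassParameterMatrix
) -> FLDModel:
    """Fit the two-class Fisher discriminant.

    The direction is the leading eigenvector of ``S_w^-1 S_b``, which for two
    classes is proportional to ``S_w^-1 (m_B - m_A)``.  ``S_w`` is the pooled
    within-class scatter (sum of outer products, no normalisation).  Stored
    unit-norm, oriented so class B projects higher; threshold at the midpoint
    of the training projection means.
    """
    if train_A.n_images < 2 or train_B.n_images < 2:
        raise ValueError("each class needs at least 2 training rows")
    if train_A.n_params != train_B.n_params:
        raise ValueError(
            f"parameter dimension mismatch: {train_A.n_params} vs {train_B.n_params}"
        )
    m_A = train_A.rows.mean(axis=0)
    m_B = train_B.rows.mean(axis=0)
    diff = m_B - m_A
    if np.allclose(diff, 0.0):
        raise DegenerateClassesError(
            f"classes {train_A.label!r} and {train_B.label!r} share the same mean"
        )

    S_w = _scatter(train_A.rows) + _scatter(train_B.rows)
    k = S_w.shape[0]
    ridge_applied = False
    try:
        cond = np.linalg.cond(S_w)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        S_w = S_w + RIDGE_EPS * (np.trace(S_w) / k + 1.0) * np.eye(k)
        ridge_applied = True

    v = np.linalg.solve(S_w, diff)
    v = v / np.linalg.norm(v)

    pa = train_A.rows @ v
    pb = train_B.rows @ v
    if pb.mean() < pa.mean():
        v = -v
        pa, pb = -pa, -pb

    return FLDModel(
        v_c=v,
        class_labels=(train_A.label, train_B.label),
        proj_mean_A=float(pa.mean()),
        proj_mean_B=float(pb.mean()),
        proj_sd_A=float(pa.std(ddof=1)),
        proj_sd_B=float(pb.std(ddof=1)),
        threshold=float(0.5 * (pa.mean() + pb.mean())),
        ridge_applied=ridge_applied,
    )


def fld_project(model: FLDModel, params: ClassParameterMatrix) -> np.ndarray:
    """Project parameter rows onto the discriminant direction."""
    if params.n_params != model.v_c.shape[0]:
        raise ValueError(
            f"dimension mismatch: model k={model.v_c.shape[0]}, "
            f"rows k={params.n_params}"
        )
    return params.rows @ model.v_c


def fld_classify(
    model: FLDModel,
    projections: np.ndarray,
    true_labels: Sequence[str] | None = None,
    rule: str = "midpoint",
) -> ClassificationResult:
    """Assign class labels from projections.

    ``rule='midpoint'`` labels B iff projection > threshold (ties go to B);
    ``rule='gaussian'`` compares per-class normal likelihoods using the
    training means and SDs.
    """
    proj = np.asarray(projections, dtype=np.float64)
    lab_A, lab_B = model.class_labels
    if rule == "midpoint":
        is_B = proj >= model.threshold
    elif rule == "gaussian":
        from scipy import stats

        ll_A = stats.norm.logpdf(proj, model.proj_mean_A, model.proj_sd_A)
        ll_B = stats.norm.logpdf(proj, model.proj_mean_B, model.proj_sd_B)
        is_B = ll_B >= ll_A
    else:
        raise ValueError(f"unknown decision rule {rule!r}")

    labels = tuple(lab_B if b else lab_A for b in is_B)
    if true_labels is None:
        return ClassificationResult(labels=labels)

    truth = list(true_labels)
    if len(truth) != len(labels):
        raise ValueError("true_labels length does not match projections")
    hits_A = sum(1 for t, p in zip(truth, labels) if t == lab_A and p == lab_A)
    hits_B = sum(1 for t, p in zip(truth, labels) if t == lab_B and p == lab_B)
    n_A = truth.count(lab_A)
    n_B = truth.count(lab_B)
    accuracy = (hits_A + hits_B) / len(truth)
    return ClassificationResult(
        labels=labels,
        accuracy=accuracy,
        hits_A=hits_A,
        hits_B=hits_B,
        n_A=n_A,
        n_B=n_B,
    )
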