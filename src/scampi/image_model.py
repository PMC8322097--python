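"""Spatial-lag image model estimated by OLS with White robust covariance.

A grayscale image is treated as a two-dimensional autoregressive field: each
interior pixel is regressed on copies of the image shifted by small integer
offsets ("spatial lags").  The per-image coefficient vector is the feature
used downstream for class discrimination.

Conventions
-----------
* 0-based (row i, column j) indexing; offset ``(0, 1)`` is the left
  neighbour ``v[i, j-1]`` (horizontal lag), ``(1, 0)`` the upper neighbour
  ``v[i-1, j]`` (vertical lag).
* No intercept: the model is ``v[i,j] = sum_h beta_h * v[i-di_h, j-dj_h] + e``.
* Only the fully interior valid region ``{(i, j): L <= i < m, L <= j < n}``
  is modelled; no padding or wraparound, so an m x n image yields an
  (m-L) x (n-L) model image.
* Vectors are built in column-major order (columns stacked top to bottom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    EmptyDesignError,
    InsufficientSamplesError,
    InvalidImageError,
)

#: Relative condition-number threshold above which a design is declared
#: rank deficient.
RANK_COND_THRESHOLD = 1e10


@dataclass(frozen=True)
class GrayscaleImage:
    """Single-channel intensity image with pixel-size metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D real-valued array indexed ``(row, column)``.
    pixel_size : float
        Physical pixel edge length in nanometres (metadata only).
    """

    pixels: np.ndarray
    pixel_size: float = 73.0

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise InvalidImageError(
                f"expected a non-empty 2-D array, got shape {np.shape(self.pixels)}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidImageError("image contains non-finite intensities")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LagStructure:
    """Set of spatial-lag offsets for a given order.

    For order ``L`` the offsets are all integer pairs ``(di, dj)`` with
    ``0 <= di, dj <= L`` except ``(0, 0)``, in lexicographic order, giving
    ``k = (L+1)**2 - 1`` regressors.  For ``L = 1`` the order is exactly
    ``[(0, 1), (1, 0), (1, 1)]``.
    """

    order: int
    offsets: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self):
        if self.order < 1:
            raise ValueError(f"lag order must be >= 1, got {self.order}")
        offs = tuple(
            (di, dj)
            for di in range(self.order + 1)
            for dj in range(self.order + 1)
            if (di, dj) != (0, 0)
        )
        object.__setattr__(self, "offsets", offs)

    @property
    def n_params(self) -> int:
        return (self.order + 1) ** 2 - 1


@dataclass(frozen=True)
class RegressionDataset:
    """Response vector and lagged design matrix for one image.

    ``response[r]`` and row ``r`` of ``design`` correspond to the valid-region
    pixel enumerated in column-major order; ``design[:, h]`` holds the image
    shifted by ``offsets[h]``.
    """

    response: np.ndarray
    design: np.ndarray
    lags: LagStructure
    image_shape: tuple[int, int]

    @property
    def n_samples(self) -> int:
        return self.response.shape[0]

    @property
    def n_params(self) -> int:
        return self.design.shape[1]

    @property
    def valid_shape(self) -> tuple[int, int]:
        m, n = self.image_shape
        L = self.lags.order
        return (m - L, n - L)


@dataclass(frozen=True)
class ImageModelFit:
    """OLS fit of the spatial-lag model for one image.

    Attributes
    ----------
    beta : ndarray
        Coefficient estimates in :class:`LagStructure` offset order.
    white_cov : ndarray
        HC0 heteroskedasticity-robust (sandwich) parameter covariance.
    t_stats, p_values : ndarray
        Per-parameter Student-t statistics and two-sided p-values
        (``N - k`` degrees of freedom).
    r_squared : float
        Uncentered goodness of fit, ``1 - sum(e^2) / sum(y^2)``.
    r_squared_centered : float
        Centered R^2 of fitted vs observed response (diagnostic).
    wald_chi2, wald_p : float
        Joint Wald statistic ``beta' W^-1 beta`` with the robust covariance
        and its chi-square (df = k) p-value.
    significant : bool
        True when every individual t-test rejects at the selection level.
    """

    beta: np.ndarray
    residuals: np.ndarray
    white_cov: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    r_squared: float
    r_squared_centered: float
    lag_order: int
    n_samples: int
    wald_chi2: float = np.nan
    wald_p: float = np.nan
    significant: bool = True
    wald_significant: bool = True
    lags: LagStructure | None = None

    @property
    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.white_cov))


def vectorize_image(img: GrayscaleImage) -> np.ndarray:
    """Flatten an image to a 1-D vector in column-major order.

    ``out[j*m + i] == pixels[i, j]``: columns are stacked top-to-bottom,
    left-to-right.
    """
    return img.pixels.flatten(order="F")


def build_lagged_design(img: GrayscaleImage, lags: LagStructure) -> RegressionDataset:
    """Assemble the response vector and lagged design matrix.

    The response is the image restricted to the valid region
    ``L <= i < m, L <= j < n``; each design column is the image shifted by
    one lag offset onto that same region.  Both are flattened column-major,
    so ``N = (m-L)(n-L)`` and ``k = (L+1)^2 - 1``.
    """
    m, n = img.shape
    L = lags.order
    if L >= min(m, n):
        raise EmptyDesignError(
            f"lag order {L} leaves no valid region in a {m}x{n} image"
        )
    px = img.pixels
    response = px[L:, L:].flatten(order="F")
    cols = [
        px[L - di : m - di, L - dj : n - dj].flatten(order="F")
        for di, dj in lags.offsets
    ]
    design = np.column_stack(cols)
    return RegressionDataset(
        response=response, design=design, lags=lags, image_shape=(m, n)
    )


def _check_rank(design: np.ndarray, lags: LagStructure) -> None:
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[0] == 0 or sv[-1] == 0 or sv[0] / sv[-1] > RANK_COND_THRESHOLD:
        # name the columns loading on the (near-)null space
        _, _, vt = np.linalg.svd(design)
        null_vec = np.abs(vt[-1])
        cols = [
            lags.offsets[h]
            for h in range(len(null_vec))
            if null_vec[h] > 0.1 * null_vec.max()
        ]
        raise CollinearityError(
            "design matrix is rank deficient (condition number "
            f"{sv[0] / max(sv[-1], np.finfo(float).tiny):.3g}); "
            f"collinear lag columns: {cols}",
            columns=cols,
        )


def fit_ols(data: RegressionDataset) -> ImageModelFit:
    """Estimate the spatial-lag coefficients by OLS with HC0 covariance.

    Minimises ``||y - X b||^2`` (no intercept).  The robust covariance is the
    White sandwich ``(X'X)^-1 X' diag(e^2) X (X'X)^-1``; t-statistics use its
    diagonal with ``N - k`` degrees of freedom.  Also computes the joint Wald
    chi-square of all coefficients.
    """
    y, X = data.response, data.design
    N, k = X.shape
    if N <= k:
        raise InsufficientSamplesError(
            f"need more observations than parameters: N={N}, k={k}"
        )
    _check_rank(X, data.lags)

    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    fitted = X @ beta
    resid = y - fitted

    # HC0 sandwich; meat assembled without materialising diag(e^2)
    Xe = X * resid[:, None]
    white_cov = xtx_inv @ (Xe.T @ Xe) @ xtx_inv
    white_cov = 0.5 * (white_cov + white_cov.T)

    se = np.sqrt(np.diag(white_cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = beta / se
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), df=N - k)

    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if np.std(y) > 0 and np.std(fitted) > 0:
        r2c = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2c = np.nan

    wald = float(beta @ np.linalg.solve(white_cov, beta))
    wald_p = float(stats.chi2.sf(wald, df=k))

    return ImageModelFit(
        beta=beta,
        residuals=resid,
        white_cov=white_cov,
        t_stats=t_stats,
        p_values=p_values,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        r_squared_centered=r2c,
        lag_order=data.lags.order,
        n_samples=N,
        wald_chi2=wald,
        wald_p=wald_p,
        lags=data.lags,
    )


def select_lag_order(
    img: GrayscaleImage,
    alpha_t: float = 0.05,
    alpha_chi: float = 0.01,
    max_order: int = 3,
) -> ImageModelFit:
    """Forward search over lag orders driven by per-parameter t-tests.

    Fits ``L = 1``; while every coefficient is individually significant
    (``p < alpha_t``) and ``L < max_order``, tries ``L + 1``.  Returns the
    largest model whose coefficients are all significant.  If even the
    ``L = 1`` model has an insignificant coefficient the L=1 fit is returned
    flagged ``significant=False`` (no exception).  The joint Wald chi-square
    is reported on the returned fit and contributes to the flag at
    ``alpha_chi``.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")

    def _fit(L: int) -> ImageModelFit:
        return fit_ols(build_lagged_design(img, LagStructure(L)))

    def _all_sig(f: ImageModelFit) -> bool:
        return bool(np.all(f.p_values < alpha_t))

    current = _fit(1)
    if _all_sig(current):
        L = 1
        m, n = img.shape
        while L < max_order and (L + 1) < min(m, n):
            try:
                candidate = _fit(L + 1)
            except (CollinearityError, InsufficientSamplesError):
                break
            if not _all_sig(candidate):
                break
            current, L = candidate, L + 1

    return _flagged(
        current,
        significant=_all_sig(current),
        wald_significant=bool(current.wald_p < alpha_chi),
    )


def _flagged(
    fit: ImageModelFit, significant: bool, wald_significant: bool
) -> ImageModelFit:
    return ImageModelFit(
        beta=fit.beta,
        residuals=fit.residuals,
        white_cov=fit.white_cov,
        t_stats=fit.t_stats,
        p_values=fit.p_values,
        r_squared=fit.r_squared,
        r_squared_centered=fit.r_squared_centered,
        lag_order=fit.lag_order,
        n_samples=fit.n_samples,
        wald_chi2=fit.wald_chi2,
        wald_p=fit.wald_p,
        significant=significant,
        wald_significant=wald_significant,
        lags=fit.lags,
    )


def reconstruct_model_image(img: GrayscaleImage, fit: ImageModelFit) -> GrayscaleImage:
    """Rebuild the model image ``X @ beta`` on the valid region.

    Output shape is ``(m - L, n - L)``; adding the residual image recovers the
    observed valid region exactly.
    """
    lags = fit.lags if fit.lags is not None else LagStructure(fit.lag_order)
    data = build_lagged_design(img, lags)
    if data.n_samples != fit.n_samples or data.n_params != fit.beta.shape[0]:
        raise InvalidImageError(
            "fit does not match image: "
            f"expected N={fit.n_samples}, k={fit.beta.shape[0]}, "
            f"got N={data.n_samples}, k={data.n_params}"
        )
    fitted = data.design @ fit.beta
    model = fitted.reshape(data.valid_shape, order="F")
    return GrayscaleImage(pixels=model, pixel_size=img.pixel_size)


def fit_image(
    img: GrayscaleImage, lags: LagStructure | None = None
) -> ImageModelFit:
    """Convenience: build the design for ``lags`` (default L=1) and fit."""
    if lags is None:
        lags = LagStructure(1)
    return fit_ols(build_lagged_design(img, lags))
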