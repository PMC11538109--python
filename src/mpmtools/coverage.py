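"""Cell coverage area from Z-projections.

Pixel intensities of a fluorescence projection are modelled as a
two-component 1D Gaussian mixture: a dark background component and a
bright foreground (cell) component.  The cutoff intensity is

    cutoff = mu_foreground + lambda * sigma_foreground

where ``lambda`` tunes stringency: negative values admit more pixels,
positive values fewer.  Coverage is the thresholded cell area divided by
the well interior area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from mpmtools.errors import DegenerateInputError, EmptyWellError, ShapeMismatchError
from mpmtools.imaging_io import WellBoundary


@dataclass
class GmmFit:
    """Parameters of a fitted two-component intensity mixture.

    Component 0/1 ordering is arbitrary; ``foreground_index`` marks the
    component with the larger mean (bright pixels = cells).
    """

    means: np.ndarray     # shape (2,)
    sigmas: np.ndarray    # shape (2,)
    weights: np.ndarray   # shape (2,), sums to 1
    foreground_index: int

    @property
    def mu_foreground(self) -> float:
        return float(self.means[self.foreground_index])

    @property
    def sigma_foreground(self) -> float:
        return float(self.sigmas[self.foreground_index])


@dataclass
class CoverageResult:
    cell_area_px: int
    well_area_px: int
    fraction: float
    lambda_used: float


def fit_bimodal_gmm(pixels: np.ndarray, seed: int = 0, max_iter: int = 200, tol: float = 1e-4) -> GmmFit:
    """EM-fit a two-component Gaussian mixture to an intensity sample.

    ``pixels`` is flattened; at least 100 samples with nonzero variance
    are required.  Initialisation is k-means with a fixed seed so the fit
    is deterministic.
    """
    x = np.asarray(pixels, dtype=np.float64).ravel()
    if x.size < 100:
        raise DegenerateInputError(f"need at least 100 pixels to fit a mixture, got {x.size}")
    if np.std(x) < 1e-12:
        raise DegenerateInputError("constant intensity sample: mixture fit is degenerate")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        max_iter=max_iter,
        tol=tol,
        init_params="kmeans",
        random_state=seed,
    )
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    return GmmFit(means=means, sigmas=sigmas, weights=weights, foreground_index=int(np.argmax(means)))


def threshold_foreground(image: np.ndarray, fit: GmmFit, lam: float = 0.0) -> np.ndarray:
    """Binary foreground mask: pixels with intensity >= mu_fg + lam * sigma_fg.

    The comparison is inclusive; for continuous intensities the choice is
    immaterial and it keeps the lambda = 0 cutoff exactly at the
    foreground mean.
    """
    cutoff = fit.mu_foreground + lam * fit.sigma_foreground
    return np.asarray(image, dtype=np.float64) >= cutoff


def compute_coverage(mask: np.ndarray, boundary: WellBoundary, lambda_used: float = 0.0) -> CoverageResult:
    """Cell area within the well divided by total well area."""
    well_mask = boundary.mask
    if mask.shape != well_mask.shape:
        raise ShapeMismatchError(f"mask shape {mask.shape} != boundary mask shape {well_mask.shape}")
    well_area = int(np.count_nonzero(well_mask))
    if well_area == 0:
        raise EmptyWellError("well boundary has zero interior area")
    cell_area = int(np.count_nonzero(np.logical_and(mask, well_mask)))
    return CoverageResult(
        cell_area_px=cell_area,
        well_area_px=well_area,
        fraction=cell_area / well_area,
        lambda_used=lambda_used,
    )


def bimodality_index(fit: GmmFit) -> float:
    """Ashman's D: separation of the two components in pooled-sigma units.

    Values above ~2 indicate genuinely bimodal data; a unimodal sample
    force-split into two components scores lower.
    """
    mu1, mu2 = fit.means
    s1, s2 = fit.sigmas
    return float(np.sqrt(2.0) * abs(mu1 - mu2) / np.sqrt(s1**2 + s2**2 + 1e-300))


def coverage_from_image(
    image: np.ndarray,
    boundary: WellBoundary,
    lam: float = 0.0,
    seed: int = 0,
    bimodality_min: float = 4.0,
) -> tuple[CoverageResult, GmmFit | None, np.ndarray]:
    """Full coverage pipeline for one projection.

    The mixture is fitted to well-interior pixels only, so out-of-well
    plastic and vignetting do not perturb the background component.

    Wells that are empty or fully covered have no bimodal intensity
    structure, and a forced two-component fit would split a single mode
    and threshold inside it.  When Ashman's D of the fit falls below
    ``bimodality_min`` the well is therefore called entirely empty or
    entirely covered by comparing the interior intensity level with the
    out-of-well background (a relative comparison, so affine intensity
    rescaling does not change the call).

    Returns the result, the fit (None when the unimodal path was taken),
    and the thresholded mask.
    """
    img = np.asarray(image, dtype=np.float64)
    inside = boundary.mask.astype(bool)
    interior = img[inside]
    fit = fit_bimodal_gmm(interior, seed=seed)
    if bimodality_index(fit) >= bimodality_min:
        mask = threshold_foreground(img, fit, lam)
        return compute_coverage(mask, boundary, lambda_used=lam), fit, mask

    # unimodal well: empty or full, decided by contrast with the exterior
    outside = img[~inside]
    if outside.size == 0:
        full = False        # no reference: conservative empty call
    else:
        out_med = np.median(outside)
        out_sigma = max(1.4826 * np.median(np.abs(outside - out_med)), 1e-12)
        full = np.median(interior) > out_med + 10.0 * out_sigma
    mask = np.ones_like(img, dtype=bool) if full else np.zeros_like(img, dtype=bool)
    return compute_coverage(mask, boundary, lambda_used=lam), None, mask
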