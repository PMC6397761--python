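"""Band filtering, label dropping, and background statistics / whitening.

The ACE detector operates in a *whitened* coordinate system in which the
background distribution is isotropic: with background mean ``mu_b`` and
covariance ``Sigma_b = U diag(D) U^T``, an instance ``x`` maps to

    x_hat = D^{-1/2} U^T (x - mu_b)

Airborne reflectance data carry wavelength intervals where atmospheric
water absorption makes the signal unusable (the provider stores a sentinel
value there); those bands are sliced out before any statistics are
computed, never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import Bag, BagSet, BandAxis, check_level

logger = logging.getLogger(__name__)

__all__ = [
    "WATER_BAND_RANGES",
    "DEFAULT_REGULARIZATION",
    "BandMask",
    "BackgroundModel",
    "band_mask",
    "remove_water_bands",
    "drop_label",
    "fit_background",
    "whiten",
]

#: Water-absorption wavelength intervals (nm), inclusive at both ends.
WATER_BAND_RANGES: tuple[tuple[float, float], ...] = (
    (1345.0, 1430.0),
    (1800.0, 1956.0),
    (2482.0, 2512.0),
)

#: Ridge added to the sample covariance, as a fraction of its mean eigenvalue
#: (trace/d). Rare classes contribute very few pixels, so the sample
#: covariance is frequently rank-deficient; the ridge is applied always.
DEFAULT_REGULARIZATION = 1e-6


@dataclass(frozen=True)
class BandMask:
    """Which ordinal band indices survived an exclusion-interval pass."""

    excluded_ranges: tuple[tuple[float, float], ...]
    kept_indices: np.ndarray
    excluded_indices: np.ndarray

    @property
    def n_kept(self) -> int:
        return int(self.kept_indices.size)

    @property
    def n_excluded(self) -> int:
        return int(self.excluded_indices.size)


def band_mask(axis: BandAxis, ranges: Sequence[Sequence[float]]) -> BandMask:
    """Partition a band axis into kept and excluded indices.

    Intervals are closed: a band centre equal to either endpoint is
    excluded. Intervals may lie partly or wholly outside the axis span.
    """
    w = axis.wavelengths
    excluded = np.zeros(len(axis), dtype=bool)
    norm_ranges = []
    for lo, hi in ranges:
        lo, hi = float(lo), float(hi)
        if hi < lo:
            raise ValueError(f"exclusion interval [{lo}, {hi}] has hi < lo")
        norm_ranges.append((lo, hi))
        excluded |= (w >= lo) & (w <= hi)
    return BandMask(
        excluded_ranges=tuple(norm_ranges),
        kept_indices=np.flatnonzero(~excluded),
        excluded_indices=np.flatnonzero(excluded),
    )


def remove_water_bands(
    bagset: BagSet, ranges: Sequence[Sequence[float]] = WATER_BAND_RANGES
) -> tuple[BagSet, BandMask]:
    """Slice out bands whose centres fall inside any exclusion interval.

    Returns the reduced :class:`BagSet` (d' = d - n_excluded bands, band
    axis updated, all spectra sliced consistently) and the
    :class:`BandMask` applied. Removing every band is a hard error.
    """
    mask = band_mask(bagset.band_axis, ranges)
    if mask.n_kept == 0:
        raise ValueError("exclusion ranges remove every band")
    if mask.n_excluded == 0:
        return bagset, mask
    keep = mask.kept_indices
    bags = [
        Bag(b.bag_id, b.instances[:, keep], b.genus_label, b.species_label)
        for b in bagset.bags
    ]
    return BagSet(bags, bagset.band_axis.subset(keep)), mask


def drop_label(bagset: BagSet, label: str, level: str) -> BagSet:
    """Remove every bag carrying ``label`` at ``level`` (e.g. the OTHERS
    class, which has no training mechanism here). Dropping an absent label
    is a no-op; dropping the last label leaves an empty set with a warning."""
    check_level(level)
    kept = [b for b in bagset.bags if b.label(level) != label]
    if len(kept) == len(bagset.bags):
        return bagset
    if not kept:
        warnings.warn(f"dropping label {label!r} left an empty BagSet", stacklevel=2)
    logger.info("dropped %d bag(s) labelled %r at %s level", len(bagset.bags) - len(kept), label, level)
    return BagSet(kept, bagset.band_axis)


@dataclass(frozen=True, eq=False)
class BackgroundModel:
    """Background mean, regularized covariance, and its eigensystem.

    ``covariance`` already includes the ridge; ``eigenvalues`` are strictly
    positive and descending, ``eigenvectors`` columns orthonormal, and
    ``U diag(D) U^T`` reconstructs the regularized covariance.
    """

    mean: np.ndarray
    covariance: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    regularization: float

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues <= 0):
            raise ValueError("background eigenvalues must be positive after regularization")

    @property
    def n_bands(self) -> int:
        return int(self.mean.size)

    @property
    def whitener(self) -> np.ndarray:
        """Matrix W with whiten(x) = (x - mean) @ W, i.e. W = U D^{-1/2}."""
        return self.eigenvectors / np.sqrt(self.eigenvalues)

    @classmethod
    def from_moments(
        cls, mean: np.ndarray, covariance: np.ndarray, regularization: float = 0.0
    ) -> "BackgroundModel":
        """Build the model from a given mean and (symmetric) covariance,
        adding ``regularization * (trace/d) * I`` before decomposing."""
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(covariance, dtype=float)
        d = mean.size
        if cov.shape != (d, d):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        scale = np.trace(cov) / d
        if scale <= 0:
            scale = 1.0  # rank-0 sample covariance: ridge alone defines the model
        reg = float(regularization) * scale
        cov_reg = cov + reg * np.eye(d)
        evals, evecs = np.linalg.eigh(cov_reg)
        order = np.argsort(evals)[::-1]
        return cls(
            mean=mean,
            covariance=cov_reg,
            eigenvectors=evecs[:, order],
            eigenvalues=evals[order],
            regularization=reg,
        )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "regularization": float(self.regularization),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BackgroundModel":
        U = np.asarray(payload["eigenvectors"], dtype=float)
        D = np.asarray(payload["eigenvalues"], dtype=float)
        return cls(
            mean=np.asarray(payload["mean"], dtype=float),
            covariance=(U * D) @ U.T,
            eigenvectors=U,
            eigenvalues=D,
            regularization=float(payload["regularization"]),
        )


def fit_background(
    instances: np.ndarray, regularization: float = DEFAULT_REGULARIZATION
) -> BackgroundModel:
    """Fit background mean and covariance from an (N, d) instance block.

    The covariance is the sample covariance (ddof=1) plus a ridge of
    ``regularization`` times its mean eigenvalue. At least two instances
    are required; non-finite values are rejected.
    """
    X = np.asarray(instances, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("background fit needs at least 2 instances (N, d array)")
    if not np.all(np.isfinite(X)):
        raise ValueError("background instances contain non-finite values")
    mean = X.mean(axis=0)
    centred = X - mean
    cov = (centred.T @ centred) / (X.shape[0] - 1)
    return BackgroundModel.from_moments(mean, cov, regularization=regularization)


def whiten(x: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """Map instance(s) into whitened coordinates ``D^{-1/2} U^T (x - mu_b)``.

    Accepts a single spectrum (1-D) or a block of spectra (2-D rows);
    returns the same shape. Whitening the background-generating
    distribution yields identity covariance.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != bg.n_bands:
        raise ValueError(f"instance has {x.shape[-1]} bands, background has {bg.n_bands}")
    return (x - bg.mean) @ bg.whitener
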