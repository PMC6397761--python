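"""Synthetic multiple-instance hyperspectral bags.

Bags follow the additive-target Gaussian model underlying the ACE
detector: a target-bearing pixel of class ``c`` is drawn from

    x ~ N(alpha * s_c + mu_b, sigma2 * Sigma_b),   alpha != 0,

and a background pixel from ``N(mu_b, sigma2 * Sigma_b)``. Each positive
bag contains at least one target-bearing instance; the remainder emulate
the background pixels (sand, grass, neighbouring canopy) that crown
polygons inevitably include. *Contamination* additionally replaces some
instances with draws from a different class's target model, emulating
mislabeled crown pixels.

The default band count is 50 for fast experimentation;
:func:`paper_band_axis` provides the airborne-sensor geometry (426 bands,
383-2512 nm) used for full-scale runs. The background covariance defaults
to a first-order autoregressive structure (exponentially decaying
band-to-band correlation), the simplest model of the strong correlation
between neighbouring wavelengths in reflectance spectra. The abundance
``alpha`` is drawn uniformly from a strictly positive interval, and
``sigma2`` is a free noise-scale parameter of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import Bag, BagSet, BandAxis

__all__ = [
    "SyntheticConfig",
    "make_config",
    "generate",
    "two_level_config",
    "make_two_level",
    "paper_band_axis",
    "default_band_axis",
]


def paper_band_axis() -> BandAxis:
    """426 uniformly spaced bands spanning 383-2512 nm."""
    return BandAxis(np.linspace(383.0, 2512.0, 426))


def default_band_axis(n_bands: int = 50) -> BandAxis:
    """A reduced visible-to-SWIR axis for fast tests."""
    return BandAxis(np.linspace(400.0, 2450.0, n_bands))


def _ar1_covariance(d: int, sd: float, rho: float) -> np.ndarray:
    idx = np.arange(d)
    return sd**2 * rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic study.

    Parameters
    ----------
    class_signatures
        (C, d) target signatures s_c, one row per species-level class.
    class_names
        C class codes (species level).
    background_mean, background_covariance
        mu_b (reflectance units) and symmetric positive-definite Sigma_b.
    sigma2
        Scalar noise scale multiplying Sigma_b in both pixel models.
    abundance_range
        (low, high) for the uniform target abundance alpha; must exclude
        zero (a zero-abundance "target" pixel is just background).
    bags_per_class, instances_per_bag
        Crown counts and the inclusive (min, max) pixel count per crown.
    target_fraction
        Fraction of each positive bag's pixels carrying the target term;
        every bag gets at least one (ceil), so any value in (0, 1] is valid.
    contamination_fraction
        Fraction of the remaining pixels replaced by draws from a
        uniformly chosen *other* class's target model (mislabeled pixels).
    genus_map
        Optional species code -> genus code map for two-level labels.
    """

    class_signatures: np.ndarray
    class_names: tuple[str, ...]
    background_mean: np.ndarray
    background_covariance: np.ndarray
    sigma2: float = 1.0
    abundance_range: tuple[float, float] = (0.5, 1.5)
    bags_per_class: int = 20
    instances_per_bag: tuple[int, int] = (10, 30)
    target_fraction: float = 0.7
    contamination_fraction: float = 0.0
    genus_map: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        S = np.atleast_2d(np.asarray(self.class_signatures, dtype=float))
        object.__setattr__(self, "class_signatures", S)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        object.__setattr__(self, "background_mean", np.asarray(self.background_mean, dtype=float))
        object.__setattr__(
            self, "background_covariance", np.asarray(self.background_covariance, dtype=float)
        )
        if S.shape[0] != len(self.class_names):
            raise ValueError("class_signatures and class_names disagree on C")
        d = self.background_mean.size
        if S.shape[1] != d or self.background_covariance.shape != (d, d):
            raise ValueError("signature / background dimensionalities disagree")
        try:
            np.linalg.cholesky(self.background_covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError("background covariance must be positive definite") from exc
        lo, hi = self.abundance_range
        if lo > hi or lo <= 0 <= hi or (lo == 0 and hi == 0):
            raise ValueError(
                "abundance_range must be an interval excluding zero (alpha != 0)"
            )
        if not 0.0 < self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in (0, 1]")
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError("contamination_fraction must lie in [0, 1)")
        n_lo, n_hi = self.instances_per_bag
        if n_lo < 1 or n_hi < n_lo:
            raise ValueError("instances_per_bag must be a valid (min, max) with min >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_bands(self) -> int:
        return int(self.background_mean.size)

    def genus_of(self, species: str) -> str:
        if self.genus_map is None:
            return species
        return self.genus_map[species]


def make_config(
    n_classes: int = 4,
    n_bands: int = 50,
    *,
    seed: int = 0,
    signature_scale: float = 0.5,
    background_sd: float = 0.02,
    background_rho: float = 0.9,
    class_names: Sequence[str] | None = None,
    band_axis: BandAxis | None = None,
    **overrides,
) -> SyntheticConfig:
    """Convenience constructor with realistic reflectance-scale defaults.

    The background mean is a smooth positive spectrum around 0.3
    reflectance; class signatures are random unit directions scaled to
    ``signature_scale`` (near-orthogonal in moderate dimension, i.e. the
    well-separated regime); the background covariance is AR(1) with
    per-band standard deviation ``background_sd``.
    """
    rng = np.random.default_rng(seed)
    axis = band_axis if band_axis is not None else default_band_axis(n_bands)
    d = len(axis)
    t = np.linspace(0.0, 1.0, d)
    mean = 0.3 + 0.1 * np.sin(2 * np.pi * t) + 0.05 * t
    cov = _ar1_covariance(d, background_sd, background_rho)
    S = rng.standard_normal((n_classes, d))
    S *= signature_scale / np.linalg.norm(S, axis=1, keepdims=True)
    names = (
        tuple(class_names)
        if class_names is not None
        else tuple(f"C{i+1:02d}" for i in range(n_classes))
    )
    cfg = SyntheticConfig(
        class_signatures=S,
        class_names=names,
        background_mean=mean,
        background_covariance=cov,
        seed=seed,
        **overrides,
    )
    return cfg


def _draw_bag(
    cfg: SyntheticConfig,
    class_idx: int,
    bag_id: str,
    rng: np.random.Generator,
    chol: np.ndarray,
) -> tuple[Bag, pd.DataFrame]:
    n_lo, n_hi = cfg.instances_per_bag
    n = int(rng.integers(n_lo, n_hi + 1))
    n_target = max(1, int(np.ceil(cfg.target_fraction * n)))
    n_target = min(n_target, n)
    noise = rng.standard_normal((n, cfg.n_bands)) @ (np.sqrt(cfg.sigma2) * chol).T
    X = cfg.background_mean + noise
    lo, hi = cfg.abundance_range
    alphas = np.zeros(n)
    source = np.full(n, "", dtype=object)
    is_target = np.zeros(n, dtype=bool)

    target_rows = np.arange(n_target)  # leading rows carry the target term
    alphas[target_rows] = rng.uniform(lo, hi, size=n_target)
    X[target_rows] += alphas[target_rows, None] * cfg.class_signatures[class_idx]
    is_target[target_rows] = True
    source[target_rows] = cfg.class_names[class_idx]

    # Contaminate some of the pure-background remainder with other-class
    # target pixels; never touch the guaranteed target instances.
    background_rows = np.arange(n_target, n)
    if cfg.contamination_fraction > 0 and background_rows.size and cfg.n_classes > 1:
        n_cont = int(round(cfg.contamination_fraction * background_rows.size))
        cont_rows = rng.choice(background_rows, size=n_cont, replace=False)
        others = [k for k in range(cfg.n_classes) if k != class_idx]
        for r in cont_rows:
            k = int(rng.choice(others))
            a = rng.uniform(lo, hi)
            X[r] += a * cfg.class_signatures[k]
            alphas[r] = a
            source[r] = cfg.class_names[k]

    species = cfg.class_names[class_idx]
    bag = Bag(
        bag_id=bag_id,
        instances=X,
        genus_label=cfg.genus_of(species),
        species_label=species,
    )
    record = pd.DataFrame(
        {
            "bag_id": bag_id,
            "instance_index": np.arange(n),
            "class": species,
            "is_target": is_target,
            "alpha": alphas,
            "source_class": source,
        }
    )
    return bag, record


def generate(
    cfg: SyntheticConfig, band_axis: BandAxis | None = None
) -> tuple[BagSet, pd.DataFrame]:
    """Draw the full bag collection described by ``cfg``.

    Returns the :class:`BagSet` and a per-instance ground-truth record
    (which instances carry the target term, their abundance, and the class
    whose signature they actually contain). Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    axis = band_axis if band_axis is not None else default_band_axis(cfg.n_bands)
    if len(axis) != cfg.n_bands:
        raise ValueError("band axis length does not match configured band count")
    chol = np.linalg.cholesky(cfg.background_covariance)
    bags: list[Bag] = []
    records: list[pd.DataFrame] = []
    for k, name in enumerate(cfg.class_names):
        for j in range(cfg.bags_per_class):
            bag, rec = _draw_bag(cfg, k, f"{name}_{j:03d}", rng, chol)
            bags.append(bag)
            records.append(rec)
    truth = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(
            columns=["bag_id", "instance_index", "class", "is_target", "alpha", "source_class"]
        )
    )
    return BagSet(bags, axis), truth


def two_level_config(
    cfg: SyntheticConfig,
    genus_map: Mapping[str, Sequence[str]],
    *,
    within_genus_similarity: float = 0.8,
) -> SyntheticConfig:
    """Resolve a two-level (genus -> species) configuration.

    ``genus_map`` maps each genus code to its species codes (a genus must
    have at least one species). Each genus gets a base direction drawn
    from ``cfg.seed``; a species signature is the unit blend

        normalize( w * genus_dir + (1 - w) * species_dir ) * scale,

    with ``w = within_genus_similarity``, so species within a genus grow
    arbitrarily similar as w -> 1 while genera stay separated. The number
    of rows of ``cfg.class_signatures`` sets the signature scale and
    dimensionality but the per-species signatures are rebuilt here.
    Signatures depend only on ``cfg.seed`` and the map, so replacing the
    seed on the returned config draws new noise over the same classes
    (held-out replicates).
    """
    if not genus_map:
        raise ValueError("genus_map is empty")
    for genus, species in genus_map.items():
        if len(species) == 0:
            raise ValueError(f"genus {genus!r} has zero species")
    if not 0.0 <= within_genus_similarity <= 1.0:
        raise ValueError("within_genus_similarity must lie in [0, 1]")
    rng = np.random.default_rng([cfg.seed, 7])
    d = cfg.n_bands
    scale = float(np.mean(np.linalg.norm(cfg.class_signatures, axis=1)))
    w = within_genus_similarity

    species_names: list[str] = []
    species_to_genus: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for genus in sorted(genus_map):
        g_dir = rng.standard_normal(d)
        g_dir /= np.linalg.norm(g_dir)
        for sp in genus_map[genus]:
            s_dir = rng.standard_normal(d)
            s_dir /= np.linalg.norm(s_dir)
            blend = w * g_dir + (1.0 - w) * s_dir
            blend /= np.linalg.norm(blend)
            rows.append(scale * blend)
            species_names.append(sp)
            species_to_genus[sp] = genus
    return replace(
        cfg,
        class_signatures=np.vstack(rows),
        class_names=tuple(species_names),
        genus_map=species_to_genus,
    )


def make_two_level(
    cfg: SyntheticConfig,
    genus_map: Mapping[str, Sequence[str]],
    *,
    within_genus_similarity: float = 0.8,
    band_axis: BandAxis | None = None,
) -> tuple[BagSet, pd.DataFrame]:
    """Generate bags labelled with both genus and species (see
    :func:`two_level_config`). A single genus reduces to :func:`generate`
    over its species."""
    resolved = two_level_config(
        cfg, genus_map, within_genus_similarity=within_genus_similarity
    )
    return generate(resolved, band_axis=band_axis)
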