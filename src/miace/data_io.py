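"""Containers and delimited-text I/O for bag-structured hyperspectral data.

A *bag* is a tree crown: the set of pixel reflectance spectra extracted
from one crown polygon, carrying crown-level genus and species labels.
Pixel-level labels are unknown (multiple-instance labelling), so the bag
is the atomic labelled unit throughout the package.

An individual spectrum instance is a plain 1-D float array with one
reflectance value per band of the shared :class:`BandAxis`; a :class:`Bag`
stores its instances as rows of a 2-D array.

On-disk format
--------------
One CSV per dataset, one row per pixel::

    crown_id,genus,species,b383.0,b388.0,...

Band columns are named ``b<wavelength_nm>`` so the band axis is
self-describing and no side-car file is needed. Reflectance is stored as
floats as-is (no integer scaling). A missing species label is recorded as
the empty string (genus-only bags are permitted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BandAxis",
    "Bag",
    "BagSet",
    "read_instance_table",
    "write_instance_table",
    "ID_COLUMN",
    "LEVELS",
]

ID_COLUMN = "crown_id"
BAND_PREFIX = "b"
LEVELS = ("genus", "species")


def check_level(level: str) -> str:
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    return level


@dataclass(frozen=True, eq=False)
class BandAxis:
    """Band-centre wavelengths in nm, strictly increasing."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("band axis must be a non-empty 1-D wavelength array")
        if not np.all(np.isfinite(w)):
            raise ValueError("band axis wavelengths must be finite")
        if not np.all(np.diff(w) > 0):
            raise ValueError("band axis wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", w)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def band_ids(self) -> np.ndarray:
        """Ordinal indices 0..d-1."""
        return np.arange(len(self))

    def subset(self, indices: Sequence[int]) -> "BandAxis":
        idx = np.asarray(indices, dtype=int)
        return BandAxis(self.wavelengths[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandAxis):
            return NotImplemented
        return np.array_equal(self.wavelengths, other.wavelengths)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        w = self.wavelengths
        return f"BandAxis({len(self)} bands, {w[0]:g}-{w[-1]:g} nm)"


@dataclass
class Bag:
    """One tree crown: a 2-D (n_instances, n_bands) block of pixel spectra.

    The genus/species labels apply at the crown level only; any individual
    pixel may belong to background (sand, grass, a neighbouring tree).
    """

    bag_id: str
    instances: np.ndarray
    genus_label: str
    species_label: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.instances, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError(f"bag {self.bag_id!r} needs a non-empty 2-D instance array")
        if not np.all(np.isfinite(X)):
            raise ValueError(f"bag {self.bag_id!r} contains non-finite reflectance values")
        self.instances = X
        self.bag_id = str(self.bag_id)

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def n_bands(self) -> int:
        return self.instances.shape[1]

    def label(self, level: str) -> str:
        check_level(level)
        return self.genus_label if level == "genus" else self.species_label


@dataclass
class BagSet:
    """A collection of bags sharing one band axis (one training or test set)."""

    bags: list[Bag]
    band_axis: BandAxis

    def __post_init__(self) -> None:
        d = len(self.band_axis)
        for bag in self.bags:
            if bag.n_bands != d:
                raise ValueError(
                    f"bag {bag.bag_id!r} has {bag.n_bands} bands, band axis has {d}"
                )
        ids = [b.bag_id for b in self.bags]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate bag ids in BagSet")

    def __len__(self) -> int:
        return len(self.bags)

    def __iter__(self) -> Iterator[Bag]:
        return iter(self.bags)

    @property
    def n_bags(self) -> int:
        return len(self.bags)

    @property
    def n_instances(self) -> int:
        return sum(b.n_instances for b in self.bags)

    @property
    def n_bands(self) -> int:
        return len(self.band_axis)

    def vocabulary(self, level: str) -> tuple[str, ...]:
        """Sorted distinct non-empty labels present at ``level``."""
        check_level(level)
        return tuple(sorted({b.label(level) for b in self.bags if b.label(level)}))

    @property
    def genus_vocabulary(self) -> tuple[str, ...]:
        return self.vocabulary("genus")

    @property
    def species_vocabulary(self) -> tuple[str, ...]:
        return self.vocabulary("species")

    def bags_with_label(self, label: str, level: str) -> list[Bag]:
        check_level(level)
        return [b for b in self.bags if b.label(level) == label]

    def subset(self, bags: Iterable[Bag]) -> "BagSet":
        return BagSet(list(bags), self.band_axis)

    def stack(self) -> np.ndarray:
        """All instances of all bags as one (N, d) array, bag order preserved."""
        return np.vstack([b.instances for b in self.bags])

    def equals(self, other: "BagSet", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        """Field-level equality within floating round-trip tolerance."""
        if self.n_bags != other.n_bags:
            return False
        if not np.allclose(
            self.band_axis.wavelengths, other.band_axis.wavelengths, rtol=rtol, atol=atol
        ):
            return False
        for a, b in zip(self.bags, other.bags):
            if (a.bag_id, a.genus_label, a.species_label) != (
                b.bag_id,
                b.genus_label,
                b.species_label,
            ):
                return False
            if a.instances.shape != b.instances.shape:
                return False
            if not np.allclose(a.instances, b.instances, rtol=rtol, atol=atol):
                return False
        return True


def _band_columns(columns: Sequence[str]) -> tuple[list[str], np.ndarray]:
    names, waves = [], []
    for c in columns:
        if c.startswith(BAND_PREFIX):
            try:
                waves.append(float(c[len(BAND_PREFIX) :]))
            except ValueError:
                continue
            names.append(c)
    return names, np.asarray(waves, dtype=float)


def read_instance_table(
    path: str | Path, label_columns: Sequence[str] = ("genus", "species")
) -> BagSet:
    """Read a per-pixel CSV instance table into a :class:`BagSet`.

    Parameters
    ----------
    path
        CSV file with a ``crown_id`` column, label columns, and band columns
        named ``b<wavelength_nm>`` in wavelength order.
    label_columns
        One or two column names: the genus column and, optionally, the
        species column.

    Rows with a missing crown id are rejected with a logged warning; a
    missing or empty file and inconsistent band values are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={ID_COLUMN: str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty instance table: {path}") from exc
    if df.empty:
        raise ValueError(f"instance table has a header but no rows: {path}")
    if ID_COLUMN not in df.columns:
        raise ValueError(f"instance table missing {ID_COLUMN!r} column: {path}")
    if not 1 <= len(label_columns) <= 2:
        raise ValueError("label_columns must name one or two columns")
    for c in label_columns:
        if c not in df.columns:
            raise ValueError(f"instance table missing label column {c!r}: {path}")

    band_names, wavelengths = _band_columns(df.columns)
    axis = BandAxis(wavelengths)  # validates non-empty, increasing

    bad = df[ID_COLUMN].isna() | (df[ID_COLUMN].astype(str).str.strip() == "")
    if bad.any():
        logger.warning("rejecting %d row(s) with missing crown id in %s", int(bad.sum()), path)
        df = df[~bad]
    if df.empty:
        raise ValueError(f"no rows with a valid crown id in {path}")

    values = df[band_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"missing or non-finite band values in {path} (inconsistent band count?)")

    genus_col = label_columns[0]
    species_col = label_columns[1] if len(label_columns) == 2 else None
    genus = df[genus_col].fillna("").astype(str).to_numpy()
    species = (
        df[species_col].fillna("").astype(str).to_numpy()
        if species_col is not None
        else np.full(len(df), "", dtype=object)
    )

    bags: list[Bag] = []
    crown_ids = df[ID_COLUMN].to_numpy()
    # groupby(sort=False) preserves first-appearance crown order and row order.
    order = pd.Series(range(len(df)))
    for cid, idx in pd.Series(order.values, index=crown_ids).groupby(level=0, sort=False):
        rows = idx.to_numpy()
        labels_g = set(genus[rows])
        labels_s = set(species[rows])
        if len(labels_g) > 1 or len(labels_s) > 1:
            logger.warning("crown %r has inconsistent labels; using first row's", cid)
        bags.append(
            Bag(
                bag_id=str(cid),
                instances=values[rows],
                genus_label=genus[rows[0]],
                species_label=species[rows[0]],
            )
        )
    return BagSet(bags, axis)


def write_instance_table(bagset: BagSet, path: str | Path) -> Path:
    """Write a :class:`BagSet` as a per-pixel CSV re-readable by
    :func:`read_instance_table`. Deterministic, so write/read/write is
    byte-identical."""
    if bagset.n_bags == 0:
        raise ValueError("refusing to write an empty BagSet")
    path = Path(path)
    band_names = [f"{BAND_PREFIX}{float(w)!r}" for w in bagset.band_axis.wavelengths]
    frames = []
    for bag in bagset.bags:
        block = pd.DataFrame(bag.instances, columns=band_names)
        block.insert(0, ID_COLUMN, bag.bag_id)
        block.insert(1, "genus", bag.genus_label)
        block.insert(2, "species", bag.species_label)
        frames.append(block)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False)
    return path
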