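"""One-vs-one MI-ACE training, bag-level voting, and hierarchical prediction.

For every pair of classes a binary MI-ACE classifier is trained: one class
plays target, the other supplies the background statistics and the
negative bags. Each classifier carries a decision threshold chosen by
scanning the midpoints between consecutive sorted training-bag confidence
values (a bag's confidence is the mean ACE statistic over its pixels) and
keeping the midpoint that maximizes training classification accuracy.

At test time every classifier casts one vote per bag (target class if the
bag confidence strictly exceeds the threshold, otherwise the background
class); the class with the most votes wins. Ties are broken by a seeded
uniform draw among the tied classes (a deterministic signed-margin rule is
available behind a flag). Hierarchical prediction classifies a crown at
genus level first; a genus with a single species maps to it directly,
while multi-species genera route the crown through that genus's own
species-level one-vs-one model.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .core import (
    DEFAULT_MAX_ITERATIONS,
    TargetSignature,
    ace_statistics,
    train_miace,
)
from .data_io import Bag, BagSet, check_level
from .preprocess import DEFAULT_REGULARIZATION, fit_background

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryClassifier",
    "OvoModel",
    "BagPrediction",
    "PredictionSet",
    "ThresholdResult",
    "bag_confidence",
    "train_threshold",
    "train_ovo",
    "train_hierarchical",
    "predict",
    "predict_hierarchical",
    "save_model",
    "load_model",
]

PAIRS_MODES = ("one", "two")
TIE_BREAKS = ("random", "margin")


@dataclass
class BinaryClassifier:
    """One trained target signature plus threshold for an ordered pair
    (target_class vs background_class)."""

    target_class: str
    background_class: str
    signature: TargetSignature
    threshold: float
    training_accuracy: float
    threshold_degenerate: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.target_class, self.background_class)

    def confidence(self, bag: Bag) -> float:
        return bag_confidence(bag, self)

    def to_dict(self) -> dict:
        return {
            "target_class": self.target_class,
            "background_class": self.background_class,
            "threshold": float(self.threshold),
            "training_accuracy": float(self.training_accuracy),
            "threshold_degenerate": bool(self.threshold_degenerate),
            "signature": self.signature.to_dict(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BinaryClassifier":
        return cls(
            target_class=payload["target_class"],
            background_class=payload["background_class"],
            signature=TargetSignature.from_dict(payload["signature"]),
            threshold=float(payload["threshold"]),
            training_accuracy=float(payload["training_accuracy"]),
            threshold_degenerate=bool(payload.get("threshold_degenerate", False)),
        )


@dataclass
class OvoModel:
    """A complete set of pairwise classifiers at one taxonomic level.

    ``pairs_mode='one'`` trains C(C-1)/2 classifiers (the lexicographically
    first class of each unordered pair is the target); ``'two'`` trains
    C(C-1), one per ordered pair, each casting an independent vote.
    ``hierarchy`` optionally maps each genus either to its single species
    code or to a species-level :class:`OvoModel`.
    """

    classifiers: list[BinaryClassifier]
    classes: tuple[str, ...]
    pairs_mode: str
    level: str
    hierarchy: dict[str, "OvoModel | str"] | None = None

    def __post_init__(self) -> None:
        C = len(self.classes)
        expected = C * (C - 1) // 2 if self.pairs_mode == "one" else C * (C - 1)
        if len(self.classifiers) != expected:
            raise ValueError(
                f"pairs_mode={self.pairs_mode!r} with {C} classes requires "
                f"{expected} classifiers, got {len(self.classifiers)}"
            )

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    def species_classes(self) -> tuple[str, ...]:
        """Union of species labels reachable through the hierarchy."""
        if self.hierarchy is None:
            raise ValueError("model has no genus->species hierarchy")
        out: set[str] = set()
        for entry in self.hierarchy.values():
            if isinstance(entry, OvoModel):
                out.update(entry.classes)
            elif entry:
                out.add(entry)
        return tuple(sorted(out))


@dataclass
class BagPrediction:
    """Votes, winner, and class probabilities for one bag."""

    bag_id: str
    predicted: str
    votes: dict[str, int]
    probabilities: dict[str, float]
    tie: bool = False
    truth: str | None = None
    predicted_genus: str | None = None
    confidences: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class PredictionSet:
    """Per-bag predictions over a fixed class vocabulary."""

    classes: tuple[str, ...]
    predictions: list[BagPrediction]
    level: str = "genus"

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self) -> Iterator[BagPrediction]:
        return iter(self.predictions)

    def probability_matrix(self) -> np.ndarray:
        return np.array(
            [[p.probabilities.get(c, 0.0) for c in self.classes] for p in self.predictions]
        )

    def predicted_labels(self) -> list[str]:
        return [p.predicted for p in self.predictions]

    def truth_labels(self) -> list[str]:
        truths = [p.truth for p in self.predictions]
        if any(t is None for t in truths):
            raise ValueError("ground truth missing for at least one bag")
        return truths  # type: ignore[return-value]


def bag_confidence(bag: Bag, clf: BinaryClassifier) -> float:
    """Arithmetic mean of the ACE statistic over all pixels in the bag."""
    if bag.n_instances == 0:
        raise ValueError("empty bag")
    return float(np.mean(ace_statistics(bag.instances, clf.signature)))


class ThresholdResult(NamedTuple):
    threshold: float
    accuracy: float
    degenerate: bool = False


def train_threshold(
    confidences: Sequence[float], is_target: Sequence[bool]
) -> ThresholdResult:
    """Pick the decision threshold maximizing training accuracy.

    Candidates are the midpoints between consecutive distinct sorted
    confidence values, plus one candidate below the minimum (everything
    predicted target) and the maximum itself (with the strict ``>`` rule,
    nothing predicted target). A bag is predicted target iff its
    confidence strictly exceeds the threshold. Accuracy ties are broken by
    the largest margin to the nearest confidence, then by the smallest
    threshold.
    """
    c = np.asarray(confidences, dtype=float)
    y = np.asarray(is_target, dtype=bool)
    if c.size != y.size or c.size == 0:
        raise ValueError("confidences and is_target must be equal-length and non-empty")
    if not (y.any() and (~y).any()):
        raise ValueError("need at least one target and one non-target bag")
    u = np.unique(c)
    if u.size == 1:
        warnings.warn("all training confidences identical; threshold is degenerate", stacklevel=2)
        majority = max(y.mean(), 1 - y.mean())
        return ThresholdResult(float(u[0]), float(majority), True)
    candidates = np.concatenate(([u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1]]))
    pred = c[None, :] > candidates[:, None]  # (n_cand, n_bags)
    acc = (pred == y[None, :]).mean(axis=1)
    best = acc == acc.max()
    margins = np.min(np.abs(c[None, :] - candidates[:, None]), axis=1)
    margins = np.where(best, margins, -np.inf)
    widest = margins == margins.max()
    tau = candidates[widest].min()
    return ThresholdResult(float(tau), float(acc.max()), False)


def _ordered_pairs(classes: Sequence[str], pairs_mode: str) -> list[tuple[str, str]]:
    if pairs_mode == "one":
        return list(combinations(classes, 2))
    if pairs_mode == "two":
        return list(permutations(classes, 2))
    raise ValueError(f"pairs_mode must be one of {PAIRS_MODES}, got {pairs_mode!r}")


def _train_pair(
    pos: Sequence[Bag],
    neg: Sequence[Bag],
    c1: str,
    c2: str,
    *,
    background_instances: np.ndarray | None,
    regularization: float,
    max_iterations: int,
) -> BinaryClassifier:
    if background_instances is None:
        background = None  # train_miace fits it from the negative pixels
    else:
        background = fit_background(background_instances, regularization=regularization)
    sig = train_miace(
        pos,
        neg,
        background=background,
        regularization=regularization,
        max_iterations=max_iterations,
    )
    confs = [float(np.mean(ace_statistics(b.instances, sig))) for b in [*pos, *neg]]
    flags = [True] * len(pos) + [False] * len(neg)
    thr = train_threshold(confs, flags)
    logger.debug(
        "pair %s vs %s: objective=%.4f threshold=%.4f train-acc=%.3f",
        c1, c2, sig.objective_value, thr.threshold, thr.accuracy,
    )
    return BinaryClassifier(
        target_class=c1,
        background_class=c2,
        signature=sig,
        threshold=thr.threshold,
        training_accuracy=thr.accuracy,
        threshold_degenerate=thr.degenerate,
    )


def train_ovo(
    bagset: BagSet,
    level: str,
    *,
    pairs_mode: str = "one",
    regularization: float = DEFAULT_REGULARIZATION,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    global_background: bool = False,
) -> OvoModel:
    """Train the full set of pairwise MI-ACE classifiers at one level.

    For each pair, bags of the target class are the positive bags and bags
    of the other class the negative bags; the whitening background is fit
    from the negative class's pixels (or from all training pixels when
    ``global_background`` is set).
    """
    check_level(level)
    classes = bagset.vocabulary(level)
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes at {level} level, found {classes}")
    by_class = {c: bagset.bags_with_label(c, level) for c in classes}
    for c, bags in by_class.items():
        if not bags:  # pragma: no cover - vocabulary derives from bags
            raise ValueError(f"class {c!r} has zero bags")
    shared_bg = bagset.stack() if global_background else None
    classifiers = [
        _train_pair(
            by_class[c1],
            by_class[c2],
            c1,
            c2,
            background_instances=shared_bg
            if global_background
            else np.vstack([b.instances for b in by_class[c2]]),
            regularization=regularization,
            max_iterations=max_iterations,
        )
        for c1, c2 in _ordered_pairs(classes, pairs_mode)
    ]
    return OvoModel(classifiers=classifiers, classes=classes, pairs_mode=pairs_mode, level=level)


def train_hierarchical(
    bagset: BagSet,
    *,
    pairs_mode: str = "one",
    regularization: float = DEFAULT_REGULARIZATION,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    global_background: bool = False,
) -> OvoModel:
    """Genus-level model plus per-genus species sub-models.

    A genus with a single species maps to that species directly; species
    sub-models are trained only where a genus has at least two species.
    """
    kwargs = dict(
        pairs_mode=pairs_mode,
        regularization=regularization,
        max_iterations=max_iterations,
        global_background=global_background,
    )
    genus_model = train_ovo(bagset, "genus", **kwargs)
    hierarchy: dict[str, OvoModel | str] = {}
    for genus in genus_model.classes:
        sub = bagset.subset(
            b for b in bagset.bags_with_label(genus, "genus") if b.species_label
        )
        species = sub.species_vocabulary
        if len(species) == 0:
            hierarchy[genus] = ""
        elif len(species) == 1:
            hierarchy[genus] = species[0]
        else:
            hierarchy[genus] = train_ovo(sub, "species", **kwargs)
    genus_model.hierarchy = hierarchy
    return genus_model


def _bag_rng(seed: int, bag_id: str) -> np.random.Generator:
    # Per-bag stream keyed on the bag id so tie resolution is invariant to
    # the order bags are presented in.
    return np.random.default_rng([int(seed), zlib.crc32(bag_id.encode("utf-8"))])


def _resolve_tie(
    tied: list[str],
    confidences: dict[tuple[str, str], float],
    model: OvoModel,
    rng: np.random.Generator,
    tie_break: str,
) -> str:
    if tie_break == "random":
        return str(rng.choice(sorted(tied)))
    if tie_break == "margin":
        # Mean signed margin toward the class over every classifier it
        # participates in; largest wins, remaining ties lexicographic.
        scores = {}
        for c in tied:
            margins = []
            for clf in model.classifiers:
                z = confidences[clf.pair]
                if clf.target_class == c:
                    margins.append(z - clf.threshold)
                elif clf.background_class == c:
                    margins.append(clf.threshold - z)
            scores[c] = np.mean(margins) if margins else -np.inf
        return min(sorted(tied), key=lambda c: (-scores[c], c))
    raise ValueError(f"tie_break must be one of {TIE_BREAKS}, got {tie_break!r}")


def predict(
    bagset: BagSet,
    model: OvoModel,
    *,
    seed: int = 0,
    tie_break: str = "random",
) -> PredictionSet:
    """Vote every pairwise classifier on every bag.

    Each classifier compares the bag's mean ACE confidence to its
    threshold (strict ``>`` awards the target class's vote). The bag is
    assigned the class with the most votes, with ``tie`` flagged and
    resolved per ``tie_break``. Probabilities are crisp: 1 for the
    predicted class, 0 elsewhere (soften afterwards via
    :func:`miace.metrics.soften` if a calibrated cross entropy is wanted).
    """
    if bagset.n_bags and bagset.n_bands != model.classifiers[0].signature.background.n_bands:
        raise ValueError("band axis of bags does not match the model")
    predictions = []
    for bag in bagset.bags:
        votes = {c: 0 for c in model.classes}
        confidences: dict[tuple[str, str], float] = {}
        for clf in model.classifiers:
            z = clf.confidence(bag)
            confidences[clf.pair] = z
            winner = clf.target_class if z > clf.threshold else clf.background_class
            votes[winner] += 1
        top = max(votes.values())
        tied = [c for c, v in votes.items() if v == top]
        tie = len(tied) > 1
        if tie:
            label = _resolve_tie(tied, confidences, model, _bag_rng(seed, bag.bag_id), tie_break)
            logger.info("bag %r: %d-way vote tie among %s -> %s", bag.bag_id, len(tied), tied, label)
        else:
            label = tied[0]
        predictions.append(
            BagPrediction(
                bag_id=bag.bag_id,
                predicted=label,
                votes=votes,
                probabilities={c: 1.0 if c == label else 0.0 for c in model.classes},
                tie=tie,
                truth=bag.label(model.level) or None,
                confidences=confidences,
            )
        )
    return PredictionSet(classes=model.classes, predictions=predictions, level=model.level)


def predict_hierarchical(
    bagset: BagSet,
    genus_model: OvoModel,
    *,
    seed: int = 0,
    tie_break: str = "random",
) -> PredictionSet:
    """Two-stage genus -> species prediction.

    The crown is first classified at genus level. A genus mapping to a
    single species assigns that species directly with no species-level
    model consulted; otherwise the crown is routed through the predicted
    genus's species-level one-vs-one model. The returned predictions are
    at species level, with the genus decision recorded on each bag.
    """
    if genus_model.hierarchy is None:
        raise ValueError("genus model has no hierarchy; train with train_hierarchical")
    species_classes = genus_model.species_classes()
    genus_preds = predict(bagset, genus_model, seed=seed, tie_break=tie_break)
    by_id = {b.bag_id: b for b in bagset.bags}

    results: dict[str, BagPrediction] = {}
    routed: dict[str, list[str]] = {}
    for gp in genus_preds:
        genus = gp.predicted
        if genus not in genus_model.hierarchy:
            raise ValueError(f"predicted genus {genus!r} missing from hierarchy")
        entry = genus_model.hierarchy[genus]
        if isinstance(entry, OvoModel):
            routed.setdefault(genus, []).append(gp.bag_id)
        else:
            results[gp.bag_id] = BagPrediction(
                bag_id=gp.bag_id,
                predicted=entry,
                votes={},
                probabilities={c: 1.0 if c == entry else 0.0 for c in species_classes},
                tie=gp.tie,
                truth=by_id[gp.bag_id].species_label or None,
                predicted_genus=genus,
            )
    for genus, ids in routed.items():
        sub_model = genus_model.hierarchy[genus]
        assert isinstance(sub_model, OvoModel)
        sub_set = bagset.subset(by_id[i] for i in ids)
        for sp in predict(sub_set, sub_model, seed=seed, tie_break=tie_break):
            results[sp.bag_id] = BagPrediction(
                bag_id=sp.bag_id,
                predicted=sp.predicted,
                votes=sp.votes,
                probabilities={
                    c: 1.0 if c == sp.predicted else 0.0 for c in species_classes
                },
                tie=sp.tie,
                truth=by_id[sp.bag_id].species_label or None,
                predicted_genus=genus,
                confidences=sp.confidences,
            )
    ordered = [results[b.bag_id] for b in bagset.bags]
    return PredictionSet(classes=species_classes, predictions=ordered, level="species")


# ---------------------------------------------------------------------------
# Model persistence: a directory of JSON classifier files plus a manifest.
# Schema: manifest.json holds classes, level, pairs_mode, optional band axis
# wavelengths and water ranges, classifier file names, and the hierarchy
# (either {"species": code} or {"submodel": subdirectory}).
# ---------------------------------------------------------------------------


def save_model(model: OvoModel, path: str | Path, metadata: dict | None = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    clf_files = []
    for clf in model.classifiers:
        name = f"clf_{clf.target_class}_vs_{clf.background_class}.json"
        (path / name).write_text(json.dumps(clf.to_dict()))
        clf_files.append(name)
    hierarchy_entry = None
    if model.hierarchy is not None:
        hierarchy_entry = {}
        for genus, entry in model.hierarchy.items():
            if isinstance(entry, OvoModel):
                sub = f"species_{genus}"
                save_model(entry, path / sub)
                hierarchy_entry[genus] = {"submodel": sub}
            else:
                hierarchy_entry[genus] = {"species": entry}
    manifest = {
        "classes": list(model.classes),
        "pairs_mode": model.pairs_mode,
        "level": model.level,
        "classifiers": clf_files,
        "hierarchy": hierarchy_entry,
        "metadata": metadata or {},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def load_model(path: str | Path) -> tuple[OvoModel, dict]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    classifiers = [
        BinaryClassifier.from_dict(json.loads((path / name).read_text()))
        for name in manifest["classifiers"]
    ]
    hierarchy = None
    if manifest["hierarchy"] is not None:
        hierarchy = {}
        for genus, entry in manifest["hierarchy"].items():
            if "submodel" in entry:
                hierarchy[genus], _ = load_model(path / entry["submodel"])
            else:
                hierarchy[genus] = entry["species"]
    model = OvoModel(
        classifiers=classifiers,
        classes=tuple(manifest["classes"]),
        pairs_mode=manifest["pairs_mode"],
        level=manifest["level"],
        hierarchy=hierarchy,
    )
    return model, manifest.get("metadata", {})
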