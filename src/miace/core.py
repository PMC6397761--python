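"""ACE detection statistic and MI-ACE discriminative signature estimation.

The adaptive cosine estimator (ACE) scores an instance ``x`` against a
target signature ``s`` as the cosine between their whitened,
mean-subtracted representations:

    D_ACE(x, s) = <s_hh, x_hh>,   s_hh = s_hat/||s_hat||, x_hh = x_hat/||x_hat||

with the hat denoting the background whitening of :mod:`miace.preprocess`.

MI-ACE estimates a *discriminative* signature from weakly labelled bags by
maximizing

    (1/N+) sum_{pos bags j} D_ACE(x*_j, s)
  - (1/N-) sum_{neg bags j} (1/N-_j) sum_{i in bag j} D_ACE(x_ji, s)

where ``x*_j`` is the instance of positive bag ``j`` with the largest
detection statistic under the current ``s`` (the instance most likely to
actually be target, making the estimate robust to mislabeled pixels).
Optimization alternates between this instance selection and a closed-form
signature update: with selections fixed the objective is linear in the
unit vector ``s_hh``, so its maximizer is the normalized difference
between the mean selected positive direction and the mean negative
direction. Initialization evaluates every positive instance as a
candidate signature and starts from the best, so no random seed is
involved and the objective is non-decreasing by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import Bag
from .preprocess import DEFAULT_REGULARIZATION, BackgroundModel, fit_background, whiten

logger = logging.getLogger(__name__)

__all__ = [
    "TargetSignature",
    "whiten_unit",
    "ace_statistic",
    "ace_statistics",
    "select_instance",
    "miace_objective",
    "train_miace",
    "DEFAULT_MAX_ITERATIONS",
]

#: Iteration cap for the alternating optimization. The discrete selection
#: state almost always stabilizes within a handful of iterations; the cap
#: only guards pathological cycling.
DEFAULT_MAX_ITERATIONS = 1000


@dataclass
class TargetSignature:
    """A trained discriminative target signature in whitened coordinates.

    ``s_whitened`` is the unit vector ``s_hh``; ``selected_ids`` maps each
    positive bag id to the instance index chosen as that bag's most
    target-like pixel at convergence.
    """

    s_whitened: np.ndarray
    background: BackgroundModel
    objective_value: float
    n_iterations: int
    selected_ids: dict[str, int]
    converged: bool = True
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        s = np.asarray(self.s_whitened, dtype=float)
        n = np.linalg.norm(s)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError("s_whitened must be a unit vector")
        self.s_whitened = s

    @classmethod
    def from_target(
        cls, s: np.ndarray, background: BackgroundModel
    ) -> "TargetSignature":
        """Wrap a known (un-whitened) target spectrum as a signature."""
        s_hat = whiten(np.asarray(s, dtype=float), background)
        n = np.linalg.norm(s_hat)
        if n == 0:
            raise ValueError("target signature whitens to the zero vector")
        return cls(
            s_whitened=s_hat / n,
            background=background,
            objective_value=float("nan"),
            n_iterations=0,
            selected_ids={},
        )

    def to_dict(self) -> dict:
        return {
            "s_whitened": self.s_whitened.tolist(),
            "background": self.background.to_dict(),
            "objective_value": float(self.objective_value),
            "n_iterations": int(self.n_iterations),
            "selected_ids": dict(self.selected_ids),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TargetSignature":
        return cls(
            s_whitened=np.asarray(payload["s_whitened"], dtype=float),
            background=BackgroundModel.from_dict(payload["background"]),
            objective_value=float(payload["objective_value"]),
            n_iterations=int(payload["n_iterations"]),
            selected_ids={str(k): int(v) for k, v in payload["selected_ids"].items()},
            converged=bool(payload["converged"]),
        )


def whiten_unit(X: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """Whiten and unit-normalize instance rows; a row exactly at the
    background mean (zero whitened norm) maps to the zero vector with a
    warning, so its ACE statistic is 0 by convention."""
    Xw = np.atleast_2d(whiten(X, bg))
    norms = np.linalg.norm(Xw, axis=1)
    zero = norms == 0
    if np.any(zero):
        warnings.warn(
            "instance equals the background mean; ACE statistic defined as 0",
            stacklevel=2,
        )
        norms = np.where(zero, 1.0, norms)
    out = Xw / norms[:, None]
    return out[0] if np.asarray(X).ndim == 1 else out


def ace_statistics(X: np.ndarray, sig: TargetSignature) -> np.ndarray:
    """ACE detection statistics for instance rows; values in [-1, 1]."""
    Xhh = np.atleast_2d(whiten_unit(X, sig.background))
    return Xhh @ sig.s_whitened


def ace_statistic(x: np.ndarray, sig: TargetSignature) -> float:
    """ACE detection statistic for a single spectrum."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("ace_statistic takes a single 1-D spectrum; use ace_statistics")
    return float(ace_statistics(x[None, :], sig)[0])


def select_instance(bag: Bag, sig: TargetSignature) -> tuple[int, float]:
    """Index and statistic of the bag instance with the maximum ACE
    response (ties broken by lowest instance index)."""
    stats = ace_statistics(bag.instances, sig)
    idx = int(np.argmax(stats))  # argmax returns the first maximum
    return idx, float(stats[idx])


def miace_objective(
    sig: TargetSignature, pos_bags: Sequence[Bag], neg_bags: Sequence[Bag]
) -> float:
    """Mean max-statistic over positive bags minus the mean per-bag mean
    statistic over negative bags; value in [-2, 2]."""
    if not pos_bags or not neg_bags:
        raise ValueError("need at least one positive and one negative bag")
    pos_term = float(np.mean([select_instance(b, sig)[1] for b in pos_bags]))
    neg_term = float(np.mean([np.mean(ace_statistics(b.instances, sig)) for b in neg_bags]))
    return pos_term - neg_term


def _segment_max(values: np.ndarray, starts: np.ndarray, stops: np.ndarray) -> np.ndarray:
    return np.array([values[a:b].max(axis=0) for a, b in zip(starts, stops)])


def train_miace(
    pos_bags: Sequence[Bag],
    neg_bags: Sequence[Bag],
    *,
    background: BackgroundModel | None = None,
    regularization: float = DEFAULT_REGULARIZATION,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> TargetSignature:
    """Estimate a discriminative target signature from positive and
    negative bags by alternating optimization.

    Parameters
    ----------
    pos_bags, neg_bags
        Bags on a common band axis; positives are assumed to contain at
        least one target-like instance each.
    background
        Background model for whitening. When omitted it is fit from all
        negative-bag pixels, i.e. the non-target class defines the
        background statistics.
    regularization
        Ridge fraction passed to :func:`fit_background` when fitting.
    max_iterations
        Cap on alternating iterations; optimization normally stops when
        the selected-instance set repeats. Hitting the cap returns the
        best iterate with ``converged=False`` and a warning.
    """
    if not pos_bags or not neg_bags:
        raise ValueError("need at least one positive and one negative bag")
    if background is None:
        background = fit_background(
            np.vstack([b.instances for b in neg_bags]), regularization=regularization
        )

    # Whitened unit-normalized instances, positives stacked with bag slices.
    P = np.atleast_2d(whiten_unit(np.vstack([b.instances for b in pos_bags]), background))
    sizes = np.array([b.n_instances for b in pos_bags])
    stops = np.cumsum(sizes)
    starts = stops - sizes

    # Negative term is a fixed vector: mean over bags of per-bag mean direction.
    neg_means = [
        np.atleast_2d(whiten_unit(b.instances, background)).mean(axis=0) for b in neg_bags
    ]
    b_hat = np.mean(neg_means, axis=0)

    def objective(s: np.ndarray) -> tuple[float, np.ndarray]:
        scores = P @ s
        sel = np.array([a + int(np.argmax(scores[a:b])) for a, b in zip(starts, stops)])
        return float(np.mean(scores[sel]) - s @ b_hat), sel

    # Deterministic initialization: best positive instance as candidate s.
    G = P @ P.T  # (N+, N+) candidate-vs-instance cosines
    per_bag_max = _segment_max(G, starts, stops)  # (n_pos_bags, N+)
    init_obj = per_bag_max.mean(axis=0) - P @ b_hat
    s = P[int(np.argmax(init_obj))].copy()

    obj, sel = objective(s)
    history = [obj]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        direction = P[sel].mean(axis=0) - b_hat
        norm = np.linalg.norm(direction)
        if norm == 0:
            warnings.warn("degenerate signature update (zero direction); stopping", stacklevel=2)
            converged = True
            break
        s_new = direction / norm
        obj_new, sel_new = objective(s_new)
        # Both half-steps maximize the objective, so it cannot decrease.
        s, obj = s_new, obj_new
        history.append(obj)
        if np.array_equal(sel_new, sel):
            converged = True
            sel = sel_new
            break
        sel = sel_new
    if not converged:
        warnings.warn(
            f"MI-ACE did not converge within {max_iterations} iterations; "
            "returning best iterate",
            stacklevel=2,
        )

    selected = {
        bag.bag_id: int(sel[j] - starts[j]) for j, bag in enumerate(pos_bags)
    }
    return TargetSignature(
        s_whitened=s,
        background=background,
        objective_value=obj,
        n_iterations=n_iter,
        selected_ids=selected,
        converged=converged,
        objective_history=history,
    )
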