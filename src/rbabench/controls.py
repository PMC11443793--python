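"""Negative-control ranking methods: mutual information and random shuffle.

Mutual information is a univariate filter — it sees single-feature
associations but is blind to pure interactions, which makes it a useful
contrast for interaction-sensitive scorers.  The random shuffle is the
no-information floor: any method whose power curve matches it has learned
nothing about the predictive features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import mutual_info_score

from .errors import DegenerateClassError, InvalidParameterError

__all__ = ["ControlResult", "mutual_info_scores", "shuffle_ranking"]


@dataclass
class ControlResult:
    """Output of a control method: per-feature scores or a permutation."""

    method: str  # mutual_information | random_shuffle
    scores: np.ndarray = None  # MI per feature, nats (mutual_information)
    permutation: np.ndarray = None  # feature ordering, best first (random_shuffle)
    seed: int = None


def mutual_info_scores(dataset) -> ControlResult:
    """Plug-in mutual information between each genotype column and the class.

    I(G; Y) = sum_{g,y} p(g,y) ln[p(g,y) / (p(g) p(y))] in nats, with empty
    cells contributing 0 (the discrete plug-in estimator; negatives are
    impossible, but any estimator swapped in here is clipped at 0).
    """
    X = np.asarray(dataset.genotypes)
    y = np.asarray(dataset.labels)
    if X.shape[0] < 2:
        raise InvalidParameterError("need at least 2 instances")
    if np.unique(y).size < 2:
        raise DegenerateClassError("mutual information needs both classes present")
    scores = np.array([mutual_info_score(X[:, j], y) for j in range(X.shape[1])])
    return ControlResult(method="mutual_information", scores=np.maximum(scores, 0.0))


def shuffle_ranking(dataset, rng: np.random.Generator) -> ControlResult:
    """Uniformly random feature ordering, reproducible from the generator."""
    n = np.asarray(dataset.genotypes).shape[1]
    if n < 1:
        raise InvalidParameterError("need at least 1 feature")
    return ControlResult(method="random_shuffle", permutation=rng.permutation(n))
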