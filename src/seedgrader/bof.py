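"""Per-modality visual dictionaries and bag-of-features encoding.

Local features of one modality (5-d spatial color patches, or 64-d SURF
descriptors) are clustered with k-means; the cluster centers are the
visual words.  An image is then encoded as the L1-normalized histogram of
nearest-word assignments of its features, and the two modality histograms
are concatenated (color first) into the joint descriptor that the
low-rank fusion stage consumes.

Dictionaries are fit on training images only; test images are encoded
against the frozen vocabulary.  The default vocabulary size is 800 words
per modality (joint length 1600).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

__all__ = [
    "VisualDictionary",
    "BofHistogram",
    "build_dictionary",
    "encode_histogram",
    "join_descriptors",
    "save_dictionary",
    "load_dictionary",
]

DEFAULT_DICT_SIZE = 800

MODALITY_DIMS = {"color": 5, "surf": 64}


@dataclass
class VisualDictionary:
    """k-means cluster centers ("visual words") for one feature modality."""

    modality: str
    words: np.ndarray  # (k, d)
    seed: int

    @property
    def k(self) -> int:
        return self.words.shape[0]


@dataclass
class BofHistogram:
    """L1-normalized visual-word histogram of one image, one modality."""

    modality: str
    counts: np.ndarray  # (k,) non-negative, summing to 1 (or all zero)

    @property
    def k(self) -> int:
        return self.counts.shape[0]


def build_dictionary(
    features: np.ndarray,
    k: int = DEFAULT_DICT_SIZE,
    seed: int = 0,
    modality: str = "color",
) -> VisualDictionary:
    """Cluster an (n, d) feature matrix into k visual words.

    Uses seeded k-means++ initialization run to convergence; the result is
    deterministic for a fixed seed.  Empty clusters are re-seeded by the
    solver to the points farthest from their centers.

    Raises
    ------
    ValueError
        If fewer features than words are supplied (lower ``k``).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("expected an (n, d) feature matrix")
    n = features.shape[0]
    if k < 2:
        raise ValueError("dictionary size k must be at least 2")
    if n < k:
        raise ValueError(
            f"only {n} features for k={k} words; lower k to at most {n}"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-10,
        random_state=seed,
    )
    km.fit(features)
    return VisualDictionary(
        modality=modality, words=km.cluster_centers_.copy(), seed=seed
    )


def encode_histogram(
    features: np.ndarray, dictionary: VisualDictionary
) -> BofHistogram:
    """Nearest-word (Euclidean) quantization, L1-normalized.

    An image with no features encodes to the all-zero histogram (with a
    warning) so that downstream concatenation still lines up.
    """
    features = np.asarray(features, dtype=float)
    k, d = dictionary.words.shape
    if features.size == 0:
        warnings.warn(
            f"no {dictionary.modality} features to encode; zero histogram",
            stacklevel=2,
        )
        return BofHistogram(dictionary.modality, np.zeros(k))
    if features.ndim != 2 or features.shape[1] != d:
        raise ValueError(
            f"feature dimension {features.shape} does not match dictionary "
            f"(k={k}, d={d})"
        )
    idx = pairwise_distances_argmin(features, dictionary.words)
    counts = np.bincount(idx, minlength=k).astype(float)
    return BofHistogram(dictionary.modality, counts / counts.sum())


def join_descriptors(
    color_hist: BofHistogram, surf_hist: BofHistogram
) -> np.ndarray:
    """Concatenate the two modality histograms, color first.

    The order is a fixed convention regardless of extraction order; either
    half may be all-zero (featureless image in that modality).
    """
    if color_hist.modality != "color" or surf_hist.modality != "surf":
        raise ValueError(
            f"expected (color, surf) histograms, got "
            f"({color_hist.modality!r}, {surf_hist.modality!r})"
        )
    return np.concatenate([color_hist.counts, surf_hist.counts])


def save_dictionary(dictionary: VisualDictionary, path) -> None:
    """Serialize a dictionary to an ``.npz`` container with metadata."""
    np.savez(
        path,
        words=dictionary.words,
        modality=np.array(dictionary.modality),
        seed=np.array(dictionary.seed),
    )


def load_dictionary(path) -> VisualDictionary:
    with np.load(path, allow_pickle=False) as z:
        return VisualDictionary(
            modality=str(z["modality"]),
            words=z["words"],
            seed=int(z["seed"]),
        )
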