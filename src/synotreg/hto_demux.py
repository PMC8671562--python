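"""Hashtag-oligo demultiplexing.

Each cell is classified singlet / doublet / negative from its hashtag counts.
For every tag a background negative binomial is fitted by the method of
moments to cells outside that tag's high cluster, and the tag-positive
threshold is the 99th quantile of that distribution; a cell positive for
exactly one tag is a singlet, for two or more a doublet, for none a negative.

Background selection: cells are clustered by k-means (k = n_tags + 1) on
CLR-transformed tag counts and, per tag, the cells of the cluster with the
LOWEST mean count for that tag form the background.  (Taking everything
outside the tag's top cluster instead leaves inter-tag doublets in the
background, which inflates the fitted variance and the threshold by an order
of magnitude; the lowest cluster is signal-free by construction.)  When
clustering degenerates (too few background cells, or a single tag), the
fallback background is the cells at or below the tag's 90th count percentile.
Threshold comparison is strictly greater-than: ties at the threshold are
negative for that tag.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datatypes import DataError, HTOCounts, NBParams

MIN_BACKGROUND_CELLS = 20


def fit_background_nb(tag_counts: np.ndarray) -> NBParams:
    """Method-of-moments NB fit: mu = mean, size = mu^2 / (s^2 - mu).

    Falls back to Poisson (size = inf) when the sample variance does not
    exceed the mean.  Requires at least 20 background cells.
    """
    x = np.asarray(tag_counts, dtype=float)
    if x.size < MIN_BACKGROUND_CELLS:
        raise DataError(
            f"only {x.size} background cells (need >= {MIN_BACKGROUND_CELLS}); "
            "supply a manual threshold instead"
        )
    mu = float(x.mean())
    s2 = float(x.var(ddof=1))
    if s2 <= mu or mu == 0.0:
        return NBParams(mu=mu, size=math.inf)
    return NBParams(mu=mu, size=mu * mu / (s2 - mu))


def nb_quantile(params: NBParams, q: float) -> int:
    """Smallest integer k with CDF(k) >= q, by direct summation of the pmf."""
    if not (0.0 < q < 1.0):
        raise DataError("quantile level must lie strictly between 0 and 1")
    mu = params.mu
    if mu == 0.0:
        return 0
    if math.isinf(params.size):
        pmf = math.exp(-mu)

        def step(k: int, pmf: float) -> float:
            return pmf * mu / (k + 1)

    else:
        r = params.size
        pmf = (r / (r + mu)) ** r
        frac = mu / (r + mu)

        def step(k: int, pmf: float) -> float:
            return pmf * (k + r) / (k + 1) * frac

    k = 0
    cdf = pmf
    while cdf < q:
        pmf = step(k, pmf)
        k += 1
        cdf += pmf
        if k > 10_000_000:  # pragma: no cover - guards pathological parameters
            raise DataError("NB quantile summation failed to converge")
    return k


def clr_transform(counts: np.ndarray) -> np.ndarray:
    """Centred log-ratio across tags: ln(c+1) minus the per-cell mean of ln(c+1)."""
    logged = np.log1p(np.asarray(counts, dtype=float))
    return logged - logged.mean(axis=0, keepdims=True)


def _background_masks(counts: np.ndarray, random_state: int) -> np.ndarray:
    """Per-tag boolean background masks, shape (n_tags, n_cells)."""
    n_tags, n_cells = counts.shape
    masks = np.zeros((n_tags, n_cells), dtype=bool)
    if n_cells >= n_tags + 1:
        # CLR is identically zero for a single tag; cluster on log counts then
        features = (clr_transform(counts) if n_tags >= 2
                    else np.log1p(counts.astype(float)))
        km = KMeans(n_clusters=n_tags + 1, n_init=10, random_state=random_state)
        labels = km.fit_predict(features.T)
        for t in range(n_tags):
            cluster_means = [
                counts[t, labels == c].mean() if (labels == c).any() else np.inf
                for c in range(n_tags + 1)
            ]
            low = int(np.argmin(cluster_means))
            masks[t] = labels == low
    for t in range(n_tags):
        if masks[t].sum() < MIN_BACKGROUND_CELLS:
            cutoff = np.percentile(counts[t], 90)
            masks[t] = counts[t] <= cutoff
    return masks


def demux(
    hto: HTOCounts, q: float = 0.99, random_state: int = 0
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Classify every cell from its hashtag counts.

    Returns ``(calls, thresholds)`` where ``calls`` is a DataFrame indexed by
    barcode with columns ``hto_class`` (singlet/doublet/negative) and
    ``assigned_tag`` (the tag id for singlets, empty otherwise), and
    ``thresholds`` maps each tag id to its integer count threshold.
    """
    if hto.n_tags < 1:
        raise DataError("demultiplexing requires at least one hashtag")
    counts = hto.dense()
    masks = _background_masks(counts, random_state)
    thresholds: Dict[str, int] = {}
    positive = np.zeros_like(counts, dtype=bool)
    for t, tag in enumerate(hto.hashtag_ids):
        params = fit_background_nb(counts[t, masks[t]])
        thr = nb_quantile(params, q)
        thresholds[str(tag)] = thr
        positive[t] = counts[t] > thr

    n_pos = positive.sum(axis=0)
    cls = np.where(n_pos == 0, "negative", np.where(n_pos == 1, "singlet", "doublet"))
    tag_of = np.asarray(hto.hashtag_ids, dtype=object)[positive.argmax(axis=0)]
    assigned = np.where(cls == "singlet", tag_of, "")
    calls = pd.DataFrame(
        {"hto_class": cls, "assigned_tag": assigned},
        index=pd.Index(hto.cell_barcodes, name="barcode"),
    )
    return calls, thresholds
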