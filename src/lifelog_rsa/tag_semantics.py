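"""Tag-set encoding, Hamming distances and tag co-occurrence structure.

Lifelogged episodes are annotated with a fixed vocabulary of content tags
(16 places, 22 activities, 13 people, plus a catch-all ``other`` — 52 tags in
all).  A tag set is encoded as a 52-dimensional binary presence vector; the
dissimilarity between two episodes' subjective contents is the Hamming
distance between their vectors.  Co-occurrence structure across events is
summarized by normalized pointwise mutual information (NPMI),

    PMI(x, y)  = log2 P(x, y) / (P(x) P(y))
    NPMI(x, y) = PMI(x, y) / h(x, y),     h(x, y) = -log2 P(x, y)

with probabilities estimated by pooling event counts (by default across all
participants).  NPMI is bounded in [-1, 1]: -1 when two tags never co-occur,
0 when they occur independently, and 1 when they always co-occur.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TagVocabulary",
    "NPMIMatrix",
    "load_vocabulary",
    "encode_tagset",
    "hamming",
    "npmi_matrix",
    "tag_network",
    "npmi_to_csv",
    "edges_to_csv",
]

#: category labels in their fixed serialization order
CATEGORY_ORDER = ("places", "activities", "people", "other")

#: expected number of tags per category in the default vocabulary
CATEGORY_SIZES = {"places": 16, "activities": 22, "people": 13, "other": 1}


@dataclass(frozen=True)
class TagVocabulary:
    """Ordered tag vocabulary with category membership.

    The tag order is fixed at construction and defines the bit order of every
    :func:`encode_tagset` vector, so it is serialized with any result that
    depends on it.
    """

    tags: tuple[str, ...]
    category: Mapping[str, str]
    version: str = "1.0"
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("vocabulary labels must be unique")
        missing = [t for t in self.tags if t not in self.category]
        if missing:
            raise ValueError(f"tags without a category: {missing!r}")
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.tags)}
        )

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self._index

    def index(self, tag: str) -> int:
        try:
            return self._index[tag]
        except KeyError:
            raise KeyError(f"unknown tag label: {tag!r}") from None

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORY_ORDER}
        for t in self.tags:
            counts[self.category[t]] += 1
        return counts

    def to_json(self, path: str | Path) -> None:
        by_cat: dict[str, list[str]] = {c: [] for c in CATEGORY_ORDER}
        for t in self.tags:
            by_cat[self.category[t]].append(t)
        payload = {"version": self.version, "categories": by_cat}
        Path(path).write_text(json.dumps(payload, indent=2))


def load_vocabulary(path: str | Path | None = None) -> TagVocabulary:
    """Load a tag vocabulary from JSON (default: the packaged 52-tag file).

    The JSON layout is ``{"version": ..., "categories": {category: [tags]}}``;
    tag order is category-major in the order places, activities, people,
    other.  The packaged default is validated to contain exactly 16 + 22 + 13
    + 1 = 52 tags.
    """
    if path is None:
        ref = resources.files("lifelog_rsa").joinpath("data/vocabulary.json")
        payload = json.loads(ref.read_text())
        validate = True
    else:
        payload = json.loads(Path(path).read_text())
        validate = False
    tags: list[str] = []
    category: dict[str, str] = {}
    for cat in CATEGORY_ORDER:
        for t in payload["categories"].get(cat, []):
            tags.append(t)
            category[t] = cat
    vocab = TagVocabulary(
        tags=tuple(tags), category=category, version=payload.get("version", "?")
    )
    if validate:
        counts = vocab.category_counts()
        if counts != CATEGORY_SIZES or len(vocab) != 52:
            raise ValueError(
                f"packaged vocabulary is corrupt: category counts {counts}"
            )
    return vocab


def encode_tagset(
    tags: Iterable[str], vocab: TagVocabulary
) -> np.ndarray:
    """Encode a set of tag labels as a binary presence vector.

    Bit ``i`` is set iff ``vocab.tags[i]`` is in ``tags``.  An empty tag set
    yields the all-zero vector; callers treating events should regard that as
    invalid (every real event carries at least one tag).

    Raises
    ------
    KeyError
        If a label is not in the vocabulary; the message names the label.
    """
    vec = np.zeros(len(vocab), dtype=np.uint8)
    for t in set(tags):
        vec[vocab.index(t)] = 1
    return vec


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two equal-length binary vectors.

    The number of positions where the vectors differ, i.e. ``sum(XOR(a, b))``.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(
            f"length mismatch: {a.shape} vs {b.shape}"
        )
    return int(np.sum(a.astype(bool) ^ b.astype(bool)))


@dataclass(frozen=True)
class NPMIMatrix:
    """Symmetric tag-by-tag NPMI matrix with the counts behind it.

    ``values[i, j]`` is NaN when either tag never occurs in the pooled events
    (NPMI is undefined there); finite entries lie in [-1, 1].  The diagonal is
    1 for every occurring tag since P(x, x) = P(x).
    """

    values: np.ndarray
    tag_counts: np.ndarray
    pair_counts: np.ndarray
    n_events: int
    tags: tuple[str, ...]


def npmi_matrix(
    events: Sequence[np.ndarray] | np.ndarray,
    tags: Sequence[str] | None = None,
) -> NPMIMatrix:
    """Normalized pointwise mutual information between all tag pairs.

    Parameters
    ----------
    events
        Binary tag vectors, one per event, pooled over whatever grouping the
        caller wants (the default analysis pools all participants' events to
        stabilize the co-occurrence frequencies).
    tags
        Optional tag labels for the columns (carried through to exports).

    Notes
    -----
    Probabilities are event frequencies: P(x) = count(x)/n and P(x, y) =
    count(x AND y)/n.  Two limits are fixed by convention to the endpoint
    values they approach: a pair that never co-occurs (P(x, y) = 0 with both
    tags occurring) gets NPMI = -1, and a pair with P(x, y) = 1 (both tags in
    every event, where h = 0) gets NPMI = 1.  A tag that never occurs at all
    has an undefined row/column, marked NaN rather than silently zero.
    """
    E = np.asarray(events, dtype=float)
    if E.ndim != 2 or E.shape[0] < 1:
        raise ValueError("need a non-empty 2-D array of event tag vectors")
    n, n_tags = E.shape
    if tags is None:
        tag_labels: tuple[str, ...] = tuple(f"tag{i}" for i in range(n_tags))
    else:
        if len(tags) != n_tags:
            raise ValueError("tag labels do not match vector length")
        tag_labels = tuple(tags)

    counts = E.sum(axis=0)
    pair = E.T @ E  # joint occurrence counts, diagonal = marginal counts
    p = counts / n
    pxy = pair / n

    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log2(pxy / np.outer(p, p))
        h = -np.log2(pxy)
        values = pmi / h

    occurs = counts > 0
    both = np.outer(occurs, occurs)
    # endpoint conventions
    values[both & (pair == 0)] = -1.0
    values[both & (pxy == 1.0)] = 1.0
    # perfect co-occurrence with P < 1 already yields exactly 1 analytically,
    # but guard against round-off on the diagonal of occurring tags
    np.fill_diagonal(values, np.where(occurs, 1.0, np.nan))
    values[~both] = np.nan
    return NPMIMatrix(
        values=values,
        tag_counts=counts.astype(int),
        pair_counts=pair.astype(int),
        n_events=n,
        tags=tag_labels,
    )


def tag_network(
    m: NPMIMatrix, threshold: float
) -> list[tuple[str, str, float]]:
    """Undirected tag co-occurrence edges with NPMI strictly above threshold.

    Self-edges are never emitted and undefined (NaN) entries never produce an
    edge.  A threshold of 0.2 reproduces the usual co-occurrence network view.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    edges = []
    n = len(m.tags)
    for i in range(n):
        for j in range(i + 1, n):
            v = m.values[i, j]
            if np.isfinite(v) and v > threshold:
                edges.append((m.tags[i], m.tags[j], float(v)))
    return edges


def npmi_to_csv(m: NPMIMatrix, path: str | Path) -> None:
    """Write the NPMI matrix as CSV with tag labels as header row/column."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tag", *m.tags])
        for i, t in enumerate(m.tags):
            w.writerow([t, *(f"{v:.10g}" if np.isfinite(v) else "" for v in m.values[i])])


def edges_to_csv(
    edges: Sequence[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tag_a", "tag_b", "npmi"])
        for a, b, v in edges:
            w.writerow([a, b, f"{v:.10g}"])
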