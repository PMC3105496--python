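"""Semantic profiles: resource × descriptor sentence co-occurrence counts.

A resource's semantic profile is the vector of descriptors that co-occur
with it in the same sentence, aggregated over a corpus.  Counts are capped
at one per sentence per (resource, descriptor) pair, so a descriptor
repeated within a sentence contributes a single co-occurrence event.
Profiles can be weighted as binary indicators or with tf*idf, where
tf is the relative co-occurrence frequency within the resource's profile
and idf = ln(N / n_d) down-weights descriptors shared by many resources.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extract import SentenceRecord, normalize_class

BINARY = "binary"
TFIDF = "tfidf"


@dataclass(frozen=True)
class ResourceInfo:
    canonical_key: str
    semantic_class: str
    corpus_frequency: int  # number of sentences mentioning the resource


class ProfileMatrix:
    """Resource × descriptor co-occurrence counts.

    Resources are identified by (canonical_key, semantic_class): two
    same-named entities of different classes are distinct resources.
    Rows and columns are kept in sorted, stable order; descriptor columns
    with zero total count are dropped at construction.
    """

    def __init__(self, resources: Sequence[ResourceInfo], counts: pd.DataFrame):
        if len(resources) != counts.shape[0]:
            raise ValueError("resource index and count rows disagree")
        self.resources = list(resources)
        self.counts = counts
        self._row_of: dict[tuple[str, str], int] = {
            (r.canonical_key, r.semantic_class): i for i, r in enumerate(self.resources)
        }
        keys = [r.canonical_key for r in self.resources]
        self._row_of_key = {k: i for i, k in enumerate(keys)} if len(set(keys)) == len(keys) else {}

    # -- lookups ----------------------------------------------------------
    def row_index(self, resource: str | tuple[str, str]) -> int:
        if isinstance(resource, tuple):
            try:
                return self._row_of[resource]
            except KeyError:
                raise KeyError(f"unknown resource: {resource!r}") from None
        try:
            return self._row_of_key[resource]
        except KeyError:
            raise KeyError(
                f"unknown or ambiguous resource key: {resource!r}; pass (key, class)"
            ) from None

    @property
    def descriptors(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_resources(self) -> int:
        return len(self.resources)

    def average_descriptors_per_resource(self) -> float:
        """Mean number of distinct descriptors per resource profile."""
        if not self.resources:
            return 0.0
        return float((self.counts.to_numpy() > 0).sum(axis=1).mean())

    # -- serialization ----------------------------------------------------
    def to_tsv(self, counts_path: str | Path, index_path: str | Path) -> None:
        """Write sparse counts (key, class, descriptor, count) + resource index."""
        lines = ["resource_key\tclass\tdescriptor\tcount"]
        arr = self.counts.to_numpy()
        for i, r in enumerate(self.resources):
            for j, d in enumerate(self.counts.columns):
                c = arr[i, j]
                if c > 0:
                    lines.append(f"{r.canonical_key}\t{r.semantic_class}\t{d}\t{int(c)}")
        Path(counts_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
        idx = ["resource_key\tclass\tcorpus_frequency"]
        idx += [f"{r.canonical_key}\t{r.semantic_class}\t{r.corpus_frequency}" for r in self.resources]
        Path(index_path).write_text("\n".join(idx) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, index_path: str | Path) -> "ProfileMatrix":
        idx_lines = Path(index_path).read_text(encoding="utf-8").splitlines()[1:]
        resources = []
        for line in idx_lines:
            if not line.strip():
                continue
            key, klass, freq = line.split("\t")
            resources.append(ResourceInfo(key, normalize_class(klass), int(freq)))
        triples = []
        for line in Path(counts_path).read_text(encoding="utf-8").splitlines()[1:]:
            if not line.strip():
                continue
            key, klass, d, c = line.split("\t")
            triples.append((key, normalize_class(klass), d, int(c)))
        descriptors = sorted({d for _, _, d, _ in triples})
        counts = pd.DataFrame(
            0,
            index=range(len(resources)),
            columns=descriptors,
            dtype=np.int64,
        )
        row = {(r.canonical_key, r.semantic_class): i for i, r in enumerate(resources)}
        for key, klass, d, c in triples:
            counts.loc[row[(key, klass)], d] = c
        return cls(resources, counts)


@dataclass
class WeightedProfileMatrix:
    """A ProfileMatrix with real-valued weights (binary or tf*idf)."""

    resources: list[ResourceInfo]
    weights: pd.DataFrame
    weighting: str

    def __post_init__(self) -> None:
        self._row_of = {
            (r.canonical_key, r.semantic_class): i for i, r in enumerate(self.resources)
        }
        keys = [r.canonical_key for r in self.resources]
        self._row_of_key = {k: i for i, k in enumerate(keys)} if len(set(keys)) == len(keys) else {}

    def row_index(self, resource: str | tuple[str, str]) -> int:
        if isinstance(resource, tuple):
            if resource in self._row_of:
                return self._row_of[resource]
            raise KeyError(f"unknown resource: {resource!r}")
        if resource in self._row_of_key:
            return self._row_of_key[resource]
        raise KeyError(f"unknown or ambiguous resource key: {resource!r}; pass (key, class)")

    def row(self, resource: str | tuple[str, str]) -> np.ndarray:
        return self.weights.to_numpy()[self.row_index(resource)]

    @property
    def descriptors(self) -> list[str]:
        return list(self.weights.columns)

    def to_tsv(self, weights_path: str | Path, index_path: str | Path) -> None:
        lines = ["resource_key\tclass\tdescriptor\tweight"]
        arr = self.weights.to_numpy()
        for i, r in enumerate(self.resources):
            for j, d in enumerate(self.weights.columns):
                w = arr[i, j]
                if w != 0:
                    lines.append(f"{r.canonical_key}\t{r.semantic_class}\t{d}\t{float(w)!r}")
        Path(weights_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
        idx = ["resource_key\tclass\tcorpus_frequency"]
        idx += [f"{r.canonical_key}\t{r.semantic_class}\t{r.corpus_frequency}" for r in self.resources]
        Path(index_path).write_text("\n".join(idx) + "\n", encoding="utf-8")


def build_profiles(records: Sequence[SentenceRecord]) -> ProfileMatrix:
    """Aggregate annotated sentences into a co-occurrence profile matrix.

    counts[r][d] = number of sentences in which resource r and descriptor d
    both occur (one increment per sentence regardless of repeats);
    corpus_frequency[r] = number of sentences mentioning r.
    """
    freq: dict[tuple[str, str], int] = {}
    pair_counts: dict[tuple[tuple[str, str], str], int] = {}
    for rec in records:
        res_here = {(m.canonical_key, m.semantic_class) for m in rec.mentions}
        terms_here = {h.term for h in rec.descriptor_hits}
        for r in res_here:
            freq[r] = freq.get(r, 0) + 1
            for d in terms_here:
                pair_counts[(r, d)] = pair_counts.get((r, d), 0) + 1
    res_keys = sorted(freq)
    descriptors = sorted({d for _, d in pair_counts})
    counts = pd.DataFrame(
        0, index=range(len(res_keys)), columns=descriptors, dtype=np.int64
    )
    row = {r: i for i, r in enumerate(res_keys)}
    for (r, d), c in pair_counts.items():
        counts.loc[row[r], d] = c
    resources = [ResourceInfo(k, c, freq[(k, c)]) for k, c in res_keys]
    return ProfileMatrix(resources, counts)


def binarize(profile: ProfileMatrix | WeightedProfileMatrix) -> WeightedProfileMatrix:
    """Binary indicator weights: 1 iff the count (or weight) is positive.

    Idempotent: binarizing an already-binary matrix is a no-op.
    """
    table = profile.weights if isinstance(profile, WeightedProfileMatrix) else profile.counts
    weights = (table > 0).astype(float)
    return WeightedProfileMatrix(list(profile.resources), weights, BINARY)


def tfidf(profile: ProfileMatrix) -> WeightedProfileMatrix:
    """tf*idf weights over co-occurrence counts.

    tf(d, s) = count(d, s) / sum_d' count(d', s)  (0 for all-zero rows);
    idf(d)   = ln(N / n_d) with N the number of resources and n_d the
    number of resources whose profile contains d.  A descriptor present in
    every profile gets idf 0 and hence weight 0 everywhere.
    """
    if profile.n_resources == 0:
        raise ValueError("tfidf requires at least one resource")
    counts = profile.counts.to_numpy(dtype=float)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tf = np.where(row_sums > 0, counts / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    n_d = (counts > 0).sum(axis=0)
    n = profile.n_resources
    idf = np.where(n_d > 0, np.log(n / np.where(n_d > 0, n_d, 1)), 0.0)
    weights = pd.DataFrame(tf * idf, index=profile.counts.index, columns=profile.counts.columns)
    return WeightedProfileMatrix(list(profile.resources), weights, TFIDF)


def weight_profiles(profile: ProfileMatrix, weighting: str) -> WeightedProfileMatrix:
    if weighting == BINARY:
        return binarize(profile)
    if weighting == TFIDF:
        return tfidf(profile)
    raise ValueError(f"unknown weighting: {weighting!r}")
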