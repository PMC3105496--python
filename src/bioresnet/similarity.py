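"""Three resource-similarity methods: lexical names, shared descriptors,
and a descriptor-smoothing kernel.

*Method 1* compares resource names through their lexical profiles — the set
of all contiguous word-level n-grams of a name — with a cosine over binary
indicator vectors.  *Method 2* compares descriptor profiles directly with a
cosine over (binary or tf*idf) weight vectors.  *Method 3* smooths method 2
with a descriptor similarity kernel: an m×m matrix A whose entry a_ij is the
lexical-profile cosine of descriptors d_i and d_j, giving

    Sim3(s1, s2) = (s1' A s2) / sqrt((s1' A s1) (s2' A s2)).

A is a Gram matrix of unit vectors, hence symmetric, unit-diagonal and
positive semi-definite: Sim3 is a normalised kernel and lives in [0, 1].
With A = I it reduces exactly to method 2.

Tokenization convention for lexical profiles: lowercase, tokens split on
whitespace, hyphenated tokens kept whole, the full token sequence included
among the n-grams, binary indicators (no counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .profile import WeightedProfileMatrix

METHOD_LEXICAL = "lexical"
METHOD_SHARED = "shared"
METHOD_SMOOTHED = "smoothed"

#: kernel entries smaller than this are stored as exact zeros
_SPARSITY_EPS = 1e-12


# --------------------------------------------------------------------------
# Method 1: lexical profiles of names

@dataclass(frozen=True)
class LexicalProfile:
    """All contiguous word n-grams of a term, as a set of token tuples.

    A k-token term with pairwise-distinct tokens has exactly k(k+1)/2
    n-grams; repeated tokens can only reduce the set.
    """

    source_term: str
    ngrams: frozenset[tuple[str, ...]]


def _name_tokens(term: str) -> list[str]:
    return term.lower().split()


def lexical_profile(term: str) -> LexicalProfile:
    """Build the lexical profile of a term.

    Raises ValueError on whitespace-only input.
    """
    tokens = _name_tokens(term)
    if not tokens:
        raise ValueError("cannot build a lexical profile of a whitespace-only term")
    grams: set[tuple[str, ...]] = set()
    k = len(tokens)
    for n in range(1, k + 1):
        for i in range(k - n + 1):
            grams.add(tuple(tokens[i: i + n]))
    return LexicalProfile(term, frozenset(grams))


def sim_lexical(name1: str, name2: str) -> float:
    """Cosine between binary n-gram indicator vectors of two names."""
    a = lexical_profile(name1).ngrams
    b = lexical_profile(name2).ngrams
    shared = len(a & b)
    if shared == 0:
        return 0.0
    return shared / float(np.sqrt(len(a) * len(b)))


# --------------------------------------------------------------------------
# Method 2: shared descriptors

def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def sim_shared(weighted: WeightedProfileMatrix, r1, r2) -> float:
    """Cosine between the two resources' weight vectors; 0 for empty profiles."""
    u = weighted.row(r1)
    v = weighted.row(r2)
    return min(1.0, max(0.0, _cosine(u, v)))


# --------------------------------------------------------------------------
# Method 3: descriptor-smoothing kernel

@dataclass
class DescriptorSimilarityMatrix:
    """The m×m descriptor kernel A, a_ij = lexical-profile cosine of d_i, d_j."""

    descriptors: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.descriptors)
        if self.entries.shape != (m, m):
            raise ValueError("kernel shape does not match descriptor count")

    @property
    def m(self) -> int:
        return len(self.descriptors)

    def min_eigenvalue(self) -> float:
        if self.m == 0:
            return 0.0
        return float(np.linalg.eigvalsh(self.entries)[0])

    # serialization: square CSV with header row/column, and triplet TSV
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, index=self.descriptors, columns=self.descriptors).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorSimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def descriptor_similarity_matrix(descriptors: Sequence[str]) -> DescriptorSimilarityMatrix:
    """Compute A over the full descriptor vocabulary.

    Implemented as a Gram matrix: each descriptor is a unit-normalised
    binary vector over the union of all n-grams, so A is positive
    semi-definite by construction.  Entries below 1e-12 are stored as 0.
    """
    descriptors = list(descriptors)
    if len(set(descriptors)) != len(descriptors):
        raise ValueError("descriptors must be distinct")
    profiles = [lexical_profile(d).ngrams for d in descriptors]
    vocab: dict[tuple[str, ...], int] = {}
    for p in profiles:
        for g in sorted(p):
            vocab.setdefault(g, len(vocab))
    rows, cols, vals = [], [], []
    for i, p in enumerate(profiles):
        norm = np.sqrt(len(p))
        for g in p:
            rows.append(i)
            cols.append(vocab[g])
            vals.append(1.0 / norm)
    m = len(descriptors)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(m, max(len(vocab), 1)))
    A = (M @ M.T).toarray()
    A[np.abs(A) < _SPARSITY_EPS] = 0.0
    np.fill_diagonal(A, 1.0)
    A = (A + A.T) / 2.0
    return DescriptorSimilarityMatrix(descriptors, A)


def identity_kernel(descriptors: Sequence[str]) -> DescriptorSimilarityMatrix:
    """A = I: smoothing disabled; Sim3 degenerates to Sim2."""
    descriptors = list(descriptors)
    return DescriptorSimilarityMatrix(descriptors, np.eye(len(descriptors)))


def sim_smoothed(weighted: WeightedProfileMatrix, A: DescriptorSimilarityMatrix, r1, r2) -> float:
    """Kernel-normalised smoothed similarity of two resources.

    Sim3 = (s1' A s2) / sqrt((s1' A s1)(s2' A s2)); 0 if either quadratic
    form vanishes (empty profile).
    """
    if A.descriptors != weighted.descriptors:
        raise ValueError("descriptor order of A does not match the profile matrix")
    s1 = weighted.row(r1)
    s2 = weighted.row(r2)
    q1 = float(s1 @ A.entries @ s1)
    q2 = float(s2 @ A.entries @ s2)
    if q1 <= 0.0 or q2 <= 0.0:
        return 0.0
    val = float(s1 @ A.entries @ s2) / np.sqrt(q1 * q2)
    return min(1.0, max(0.0, val))


# --------------------------------------------------------------------------
# batch wrapper

@dataclass
class SimilarityMatrix:
    """Symmetric resource×resource similarity table in [0, 1]."""

    resources: list[str]
    entries: np.ndarray
    method: str
    weighting: str = "n/a"

    def __post_init__(self) -> None:
        n = len(self.resources)
        if self.entries.shape != (n, n):
            raise ValueError("matrix shape does not match resource count")

    @property
    def n(self) -> int:
        return len(self.resources)

    def value(self, r1: str, r2: str) -> float:
        i = self.resources.index(r1)
        j = self.resources.index(r2)
        return float(self.entries[i, j])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, index=self.resources, columns=self.resources).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, method: str = "shared", weighting: str = "n/a") -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float), method, weighting)

    def to_triplets(self, path: str | Path) -> None:
        lines = ["resource1\tresource2\tsimilarity"]
        for i in range(self.n):
            for j in range(i + 1, self.n):
                v = self.entries[i, j]
                if v != 0:
                    lines.append(f"{self.resources[i]}\t{self.resources[j]}\t{float(v)!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _resource_labels(weighted: WeightedProfileMatrix) -> list[str]:
    keys = [r.canonical_key for r in weighted.resources]
    if len(set(keys)) == len(keys):
        return keys
    return [f"{r.canonical_key}|{r.semantic_class}" for r in weighted.resources]


def similarity_matrix(
    source: WeightedProfileMatrix | Sequence[str],
    method: str,
    A: DescriptorSimilarityMatrix | None = None,
) -> SimilarityMatrix:
    """Apply a pairwise similarity to all pairs.

    method='lexical' takes a sequence of resource names; 'shared' and
    'smoothed' take a WeightedProfileMatrix ('smoothed' additionally needs
    the descriptor kernel A, computed from the matrix columns if omitted).
    """
    if method == METHOD_LEXICAL:
        names = list(source)
        n = len(names)
        S = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                S[i, j] = S[j, i] = sim_lexical(names[i], names[j])
        return SimilarityMatrix(names, S, method)

    if not isinstance(source, WeightedProfileMatrix):
        raise TypeError(f"method {method!r} requires a WeightedProfileMatrix")
    W = source.weights.to_numpy(dtype=float)
    labels = _resource_labels(source)

    if method == METHOD_SMOOTHED:
        if A is None:
            A = descriptor_similarity_matrix(source.descriptors)
        if A.descriptors != source.descriptors:
            raise ValueError("descriptor order of A does not match the profile matrix")
        if np.array_equal(A.entries, np.eye(A.m)):
            # A = I reduces algebraically to the shared-descriptor cosine;
            # reuse that code path so the two are bit-identical
            method_impl = METHOD_SHARED
        else:
            method_impl = METHOD_SMOOTHED
    elif method == METHOD_SHARED:
        method_impl = METHOD_SHARED
    else:
        raise ValueError(f"unknown similarity method: {method!r}")

    if method_impl == METHOD_SHARED:
        norms = np.linalg.norm(W, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        Wn = W / safe[:, None]
        S = Wn @ Wn.T
        S[norms == 0, :] = 0.0
        S[:, norms == 0] = 0.0
    else:
        G = W @ A.entries @ W.T
        q = np.diag(G).copy()
        safe = np.where(q > 0, np.sqrt(q), 1.0)
        S = G / safe[:, None] / safe[None, :]
        S[q <= 0, :] = 0.0
        S[:, q <= 0] = 0.0

    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    nz = np.linalg.norm(W, axis=1) > 0
    for i in np.where(nz)[0]:
        S[i, i] = 1.0
    return SimilarityMatrix(labels, S, method, source.weighting)
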