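"""Synthetic corpora with planted community structure, and reference name lists.

The generator emulates the statistical shape of a resource-mention corpus:
each community of resources talks about its own descriptor vocabulary,
every community additionally shares a pool of generic descriptors (the
"gene"/"method"/"analysis" phenomenon), and a noise rate makes sentences
occasionally borrow descriptors from foreign communities.  Sentences are
fixed-template strings, so the extraction stage can parse its own fixtures
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .extract import (
    ALGORITHM,
    APPLICATION,
    DATA,
    DATA_RESOURCE,
    SEMANTIC_CLASSES,
    DescriptorDictionary,
    HeadLexicon,
)

#: terminological heads per class (single lowercase tokens)
DEFAULT_HEADS: dict[str, str] = {
    "algorithm": ALGORITHM,
    "alignment": ALGORITHM,
    "analysis": ALGORITHM,
    "approach": ALGORITHM,
    "method": ALGORITHM,
    "procedure": ALGORITHM,
    "program": APPLICATION,
    "service": APPLICATION,
    "application": APPLICATION,
    "tool": APPLICATION,
    "software": APPLICATION,
    "system": APPLICATION,
    "record": DATA,
    "sequence": DATA,
    "sequences": DATA,
    "report": DATA,
    "resource": DATA_RESOURCE,
    "database": DATA_RESOURCE,
    "dataset": DATA_RESOURCE,
    "repository": DATA_RESOURCE,
}

#: one representative head per class, used when naming synthetic resources
_CLASS_HEAD = {
    ALGORITHM: "algorithm",
    APPLICATION: "software",
    DATA: "record",
    DATA_RESOURCE: "database",
}

_GENERIC_POOL = ["gene", "protein", "method", "analysis", "sequence motif", "model"]

_COMMUNITY_STEMS = [
    "phylo", "microarray", "proteomic", "ontology", "imaging", "variant",
    "pathway", "docking",
]


def default_head_lexicon() -> HeadLexicon:
    return HeadLexicon(dict(DEFAULT_HEADS))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-community synthetic corpus.

    noise is the probability that a topical descriptor in a sentence is
    drawn from a foreign community instead of the resource's own.
    """

    n_communities: int = 2
    resources_per_community: int = 4
    class_mix: tuple[str, ...] = SEMANTIC_CLASSES
    community_vocab_size: int = 8
    n_generic: int = 3
    sentences_per_resource: int = 10
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities < 1 or self.resources_per_community < 1:
            raise ValueError("community counts must be positive")
        if self.community_vocab_size < 1 or self.sentences_per_resource < 1:
            raise ValueError("vocabulary size and sentences per resource must be positive")
        if self.n_generic < 0:
            raise ValueError("generic descriptor count must be non-negative")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise rate must lie in [0, 1]")
        for c in self.class_mix:
            if c not in SEMANTIC_CLASSES:
                raise ValueError(f"unknown semantic class in mix: {c!r}")


@dataclass
class CorpusBundle:
    """A generated corpus plus everything needed to process and score it."""

    documents: dict[str, str]
    head_lexicon: HeadLexicon
    dictionary: DescriptorDictionary
    communities: dict[str, int]  # canonical resource key -> community id
    spec: SyntheticSpec = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for doc_id, text in self.documents.items():
            (out / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        self.head_lexicon.to_tsv(out / "head_lexicon.tsv")
        self.dictionary.to_tsv(out / "descriptors.tsv")
        lines = ["resource_key\tcommunity"]
        lines += [f"{k}\t{c}" for k, c in sorted(self.communities.items())]
        (out / "communities.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def _community_vocab(c: int, size: int) -> list[str]:
    stem = _COMMUNITY_STEMS[c % len(_COMMUNITY_STEMS)]
    suffix = "" if c < len(_COMMUNITY_STEMS) else str(c)
    return [f"{stem}{suffix} marker{c}x{j}" for j in range(size)]


def generate_corpus(spec: SyntheticSpec) -> CorpusBundle:
    """Generate a deterministic corpus with planted communities.

    Every sentence names exactly one resource (a capitalised name token
    followed by its class head word) and two topical descriptors; when
    generic descriptors are configured, each sentence also carries one,
    drawn community-independently.  Identical seeds give byte-identical
    corpora.
    """
    rng = np.random.default_rng(spec.seed)
    vocabs = [_community_vocab(c, spec.community_vocab_size) for c in range(spec.n_communities)]
    generics = list(_GENERIC_POOL[: spec.n_generic])
    generics += [f"assay{j}" for j in range(len(generics), spec.n_generic)]
    all_terms = [t for v in vocabs for t in v] + generics
    dictionary = DescriptorDictionary.from_terms(all_terms, source="ontology")
    lexicon = default_head_lexicon()

    documents: dict[str, str] = {}
    communities: dict[str, int] = {}
    for c in range(spec.n_communities):
        for i in range(spec.resources_per_community):
            klass = spec.class_mix[(c * spec.resources_per_community + i) % len(spec.class_mix)]
            head = _CLASS_HEAD[klass]
            name_token = f"Res{c}x{i}"
            name = f"{name_token} {head}"
            key = name.lower()
            communities[key] = c
            sentences = []
            for _ in range(spec.sentences_per_resource):
                terms = []
                for _ in range(2):
                    if spec.n_communities > 1 and rng.random() < spec.noise:
                        other = int(rng.integers(spec.n_communities - 1))
                        other = other if other < c else other + 1
                        pool = vocabs[other]
                    else:
                        pool = vocabs[c]
                    terms.append(pool[int(rng.integers(len(pool)))])
                if generics:
                    g = generics[int(rng.integers(len(generics)))]
                    sentences.append(
                        f"The {name_token} {head} computes {terms[0]} and {terms[1]} using {g}."
                    )
                else:
                    sentences.append(
                        f"The {name_token} {head} computes {terms[0]} and {terms[1]}."
                    )
            documents[f"doc_{c}_{i}"] = " ".join(sentences) + "\n"
    return CorpusBundle(documents, lexicon, dictionary, communities, spec)


def table4_names() -> list[tuple[str, str]]:
    """The 18-resource exploration sample: (printed name, semantic class)."""
    return [
        ("Gene ontology (GO)", DATA_RESOURCE),
        ("Support vector machine (SVM)", ALGORITHM),
        ("Protein data bank (PDB)", DATA_RESOURCE),
        ("Hidden Markov model (HMM)", ALGORITHM),
        ("Principal components analysis (PCA)", ALGORITHM),
        ("Position-specific scoring matrix (PSSM)", ALGORITHM),
        ("Self organising map (SOM)", ALGORITHM),
        ("Medical subject headings (MeSH)", DATA_RESOURCE),
        ("Neural network", ALGORITHM),
        ("Markov chain Monte Carlo (MCMC)", ALGORITHM),
        ("Expression profile", DATA),
        ("Basic local alignment search tool (BLAST)", APPLICATION),
        ("Phylogenetic tree", DATA),
        ("Structural classification of proteins (SCOP)", DATA_RESOURCE),
        ("Kyoto encyclopaedia of genes and genomes (KEGG)", DATA_RESOURCE),
        ("Clusters of orthologous groups (COG)", DATA_RESOURCE),
        ("ChIp-chip data", DATA),
        ("Pairwise alignment", DATA),
    ]
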