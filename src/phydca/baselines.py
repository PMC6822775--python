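"""Local pairwise correlation measures over phylogenetic profiles.

Classical phylogenetic profiling relates two domain families by comparing
their profile columns directly: Hamming distance, Pearson correlation, or
the p-value of Fisher's exact test on the 2x2 co-occurrence table.  These
are *local* measures — each pair is scored in isolation, so correlation
transmitted through intermediate partners is indistinguishable from a
direct relationship.  They serve here as the baselines against which the
global coupling inference is compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats

from .profiles import ProfileMatrix

__all__ = [
    "PairScoreList",
    "hamming_scores",
    "pearson_scores",
    "fisher_scores",
]

ScoreKind = Literal["hamming", "pearson", "fisher_p", "coupling", "coupling_apc"]


@dataclass(frozen=True)
class PairScoreList:
    """Ranked list of unordered domain pairs with a relatedness score.

    ``pairs`` holds (domain_i, domain_j, score) triples with i < j
    lexicographically, sorted most-related-first according to ``direction``
    ("larger" or "smaller" score means more related); ties are broken
    lexicographically by the pair.  No self-pairs, no duplicates, all
    scores finite.
    """

    pairs: tuple[tuple[str, str, float], ...]
    score_kind: ScoreKind
    direction: Literal["larger", "smaller"]

    def __post_init__(self) -> None:
        seen = set()
        for i, j, s in self.pairs:
            if i == j:
                raise ValueError(f"self-pair {i!r}")
            if i > j:
                raise ValueError(f"pair ({i!r}, {j!r}) not in canonical order")
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for pair ({i}, {j})")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))
        object.__setattr__(self, "pairs", tuple(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def top(self, k: int) -> set[tuple[str, str]]:
        """The first k pairs (identifiers only)."""
        return {(i, j) for i, j, _ in self.pairs[:k]}

    @classmethod
    def from_unsorted(cls, triples, score_kind: ScoreKind,
                      direction: Literal["larger", "smaller"]) -> "PairScoreList":
        """Canonicalize pair order and sort most-related-first."""
        canon = []
        for i, j, s in triples:
            if i > j:
                i, j = j, i
            canon.append((i, j, float(s)))
        sign = -1.0 if direction == "larger" else 1.0
        canon.sort(key=lambda t: (sign * t[2], t[0], t[1]))
        return cls(tuple(canon), score_kind, direction)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("domain_i\tdomain_j\tscore\n")
            for i, j, s in self.pairs:
                fh.write(f"{i}\t{j}\t{s:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, score_kind: ScoreKind,
                 direction: Literal["larger", "smaller"]) -> "PairScoreList":
        triples = []
        with Path(path).open() as fh:
            header = fh.readline()
            assert header.startswith("domain_i")
            for line in fh:
                i, j, s = line.rstrip("\n").split("\t")
                triples.append((i, j, float(s)))
        return cls.from_unsorted(triples, score_kind, direction)


def _pair_counts(ppm: ProfileMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column presence counts and pairwise co-presence counts."""
    x = ppm.entries.astype(np.int64)
    return x.sum(axis=0), x.T @ x


def hamming_scores(ppm: ProfileMatrix) -> PairScoreList:
    """Normalized Hamming distance between all profile-column pairs.

    score(i, j) = #{genomes where the two columns differ} / M, in [0, 1];
    smaller means more related.  Normalization by M does not affect the
    ranking but makes scores comparable across panels of different size.
    """
    if ppm.n_domains < 2:
        raise ValueError("need at least two domains")
    counts, co = _pair_counts(ppm)
    m = ppm.n_species
    triples = []
    for a in range(ppm.n_domains):
        for b in range(a + 1, ppm.n_domains):
            mismatches = counts[a] + counts[b] - 2 * co[a, b]
            triples.append((ppm.domain_ids[a], ppm.domain_ids[b],
                            mismatches / m))
    return PairScoreList.from_unsorted(triples, "hamming", "smaller")


def pearson_scores(ppm: ProfileMatrix) -> PairScoreList:
    """Sample Pearson correlation between all profile-column pairs.

    Larger r means more related; the ranking is by signed r, so mutual
    exclusion (negative r) ranks at the bottom rather than being folded
    into relatedness.  Requires every column to be non-constant, which the
    frequency filter guarantees for 0 < f_min <= f_max < 1.
    """
    if ppm.n_domains < 2:
        raise ValueError("need at least two domains")
    x = ppm.entries.astype(np.float64)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = ppm.domain_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"domain {bad!r} has a constant profile column; "
                         "Pearson correlation is undefined")
    r = np.corrcoef(x, rowvar=False)
    triples = [
        (ppm.domain_ids[a], ppm.domain_ids[b], r[a, b])
        for a in range(ppm.n_domains) for b in range(a + 1, ppm.n_domains)
    ]
    return PairScoreList.from_unsorted(triples, "pearson", "larger")


def fisher_scores(ppm: ProfileMatrix) -> PairScoreList:
    """Two-sided Fisher's exact test on every pair's 2x2 table.

    The table cross-tabulates co-presence, presence of one domain only,
    and co-absence over the M genomes.  Two-sided p-value under the
    conventional rule: the total hypergeometric probability of all tables
    (with the observed margins) whose probability does not exceed that of
    the observed table.  Smaller p means more related.
    """
    if ppm.n_domains < 2:
        raise ValueError("need at least two domains")
    counts, co = _pair_counts(ppm)
    m = ppm.n_species
    triples = []
    cache: dict[tuple[int, int, int], float] = {}
    for a in range(ppm.n_domains):
        for b in range(a + 1, ppm.n_domains):
            both = int(co[a, b])
            key = (counts[a], counts[b], both)
            p = cache.get(key)
            if p is None:
                table = [[both, counts[a] - both],
                         [counts[b] - both, m - counts[a] - counts[b] + both]]
                p = float(stats.fisher_exact(table, alternative="two-sided")[1])
                cache[key] = p
            triples.append((ppm.domain_ids[a], ppm.domain_ids[b], min(p, 1.0)))
    return PairScoreList.from_unsorted(triples, "fisher_p", "smaller")
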