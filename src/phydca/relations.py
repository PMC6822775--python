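"""Curated positive sets of known domain-domain relationships.

Predictions are benchmarked against domain pairs with independent evidence
of a relationship.  Five evidence classes are assembled and merged into one
deduplicated set of unordered pairs:

* ``intra_protein`` — two domains co-occurring in a single protein;
* ``operon``        — domains of proteins co-localized in one operon;
* ``ppi``           — all-against-all domain pairs of two proteins with an
                      experimentally reported interaction (a deliberately
                      permissive expansion);
* ``structure``     — domain-domain contacts from solved complex
                      structures, ingested as a pre-computed pair list;
* ``metabolic``     — enzyme domains of reactions sharing a substrate,
                      sharing a product, or chained product-to-substrate,
                      after removal of promiscuous "currency" metabolites
                      (ATP, water, ...) that would link everything.

A pair may be supported by several classes but counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "RelationSet",
    "intra_protein_pairs",
    "operon_pairs",
    "ppi_pairs",
    "structure_pairs",
    "metabolic_pairs",
    "merge",
    "read_architectures",
    "read_pair_list",
]

Pair = tuple[str, str]

SOURCES = ("intra_protein", "operon", "ppi", "structure", "metabolic")


def _canon(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass
class RelationSet:
    """Deduplicated unordered domain pairs with their evidence sources."""

    sources: dict[Pair, frozenset[str]] = field(default_factory=dict)

    def add(self, a: str, b: str, source: str) -> None:
        if a == b:
            return
        pair = _canon(a, b)
        self.sources[pair] = self.sources.get(pair, frozenset()) | {source}

    @property
    def pairs(self) -> set[Pair]:
        return set(self.sources)

    def __len__(self) -> int:
        return len(self.sources)

    def __contains__(self, pair: Sequence[str]) -> bool:
        a, b = pair
        return _canon(a, b) in self.sources

    def restricted_to(self, source: str) -> "RelationSet":
        """Sub-set of pairs carrying a given evidence label."""
        return RelationSet({p: s for p, s in self.sources.items()
                            if source in s})

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("domain_i\tdomain_j\tsources\n")
            for (a, b) in sorted(self.sources):
                labels = ",".join(sorted(self.sources[(a, b)]))
                fh.write(f"{a}\t{b}\t{labels}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelationSet":
        out = cls()
        with Path(path).open() as fh:
            header = fh.readline()
            assert header.startswith("domain_i")
            for line in fh:
                a, b, labels = line.rstrip("\n").split("\t")
                out.sources[_canon(a, b)] = frozenset(labels.split(","))
        return out


def _pairs_from_group(domains: Iterable[str]) -> set[Pair]:
    distinct = sorted(set(domains))
    return {(a, b) for a, b in combinations(distinct, 2)}


def intra_protein_pairs(
        architectures: Iterable[tuple[str, Sequence[str]]]) -> RelationSet:
    """Pairs of distinct domains co-occurring inside a single protein.

    A protein carrying the same domain twice contributes no self-pair;
    pair order within/between proteins is irrelevant.
    """
    out = RelationSet()
    for _protein, domains in architectures:
        for a, b in _pairs_from_group(domains):
            out.add(a, b, "intra_protein")
    return out


def operon_pairs(operons: Iterable[tuple[str, Sequence[str]]],
                 architectures: Mapping[str, Sequence[str]]) -> RelationSet:
    """Pairs of distinct domains found anywhere within one operon.

    Domains may come from the same or different member proteins.  Operon
    members without a known architecture are skipped with a warning.
    """
    out = RelationSet()
    for operon_id, proteins in operons:
        domains: list[str] = []
        for p in proteins:
            if p not in architectures:
                logger.warning("operon %s: protein %s has no architecture; "
                               "skipped", operon_id, p)
                continue
            domains.extend(architectures[p])
        for a, b in _pairs_from_group(domains):
            out.add(a, b, "operon")
    return out


def ppi_pairs(interactions: Iterable[tuple[str, str]],
              architectures: Mapping[str, Sequence[str]]) -> RelationSet:
    """Bipartite domain expansion of protein-protein interaction records.

    Every domain of one partner is paired with every distinct domain of the
    other; for a homodimeric record the expansion degenerates to the pairs
    within the protein's own domain set.  Unknown proteins are skipped with
    a warning.
    """
    out = RelationSet()
    for pa, pb in interactions:
        if pa not in architectures or pb not in architectures:
            missing = pa if pa not in architectures else pb
            logger.warning("interaction (%s, %s): protein %s has no "
                           "architecture; skipped", pa, pb, missing)
            continue
        for a in architectures[pa]:
            for b in architectures[pb]:
                out.add(a, b, "ppi")
    return out


def structure_pairs(pairs: Iterable[tuple[str, str]]) -> RelationSet:
    """Pass-through ingestion of a pre-computed structural contact list."""
    out = RelationSet()
    for a, b in pairs:
        out.add(a, b, "structure")
    return out


def metabolic_pairs(
        reactions: Iterable[tuple[str, Sequence[str], Sequence[str],
                                  Sequence[str]]],
        currency_threshold: int = 50) -> RelationSet:
    """Enzyme-domain pairs of metabolically related reaction pairs.

    Records are (reaction_id, enzyme domains, substrates, products).
    Metabolites participating — on either side — in more than
    ``currency_threshold`` reactions are removed first; the relation rules
    then apply to reaction pairs that (a) share a substrate, (b) share a
    product, or (c) chain (a product of one is a substrate of the other,
    in either direction, which also covers reversible reactions).
    """
    if currency_threshold < 1:
        raise ValueError("currency_threshold must be >= 1")
    recs = [(rid, tuple(doms), set(subs), set(prods))
            for rid, doms, subs, prods in reactions]
    participation: dict[str, int] = {}
    for _rid, _doms, subs, prods in recs:
        for met in subs | prods:
            participation[met] = participation.get(met, 0) + 1
    currency = {m for m, k in participation.items() if k > currency_threshold}
    filtered = [(rid, doms, subs - currency, prods - currency)
                for rid, doms, subs, prods in recs]
    out = RelationSet()
    for (r1, d1, s1, p1), (r2, d2, s2, p2) in combinations(filtered, 2):
        related = bool(s1 & s2) or bool(p1 & p2) or bool(p1 & s2) \
            or bool(p2 & s1)
        if not related:
            continue
        for a in d1:
            for b in d2:
                out.add(a, b, "metabolic")
    return out


def merge(sets: Iterable[RelationSet]) -> RelationSet:
    """Union of relation sets; per-pair source labels are merged."""
    out = RelationSet()
    for rs in sets:
        for pair, labels in rs.sources.items():
            out.sources[pair] = out.sources.get(pair, frozenset()) | labels
    return out


def read_architectures(path: str | Path) -> dict[str, list[str]]:
    """Read ``protein_id<TAB>dom1,dom2,...`` architecture TSV."""
    out: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("protein_id\t"):
                continue
            pid, _, doms = line.partition("\t")
            out[pid] = [d for d in doms.split(",") if d]
    return out


def read_pair_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV of identifier pairs (header optional)."""
    pairs = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("domain_i\t", "protein_A\t")):
                continue
            a, b = line.split("\t")[:2]
            pairs.append((a, b))
    return pairs
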