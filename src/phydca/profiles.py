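"""Binary phylogenetic profile matrices (PPMs).

A phylogenetic profile records, for one protein-domain family, in which
genomes of a reference panel the family occurs.  Stacking the profiles of
many families gives the phylogenetic profile matrix: a binary M x N matrix
whose entry (a, i) is 1 if genome ``a`` carries at least one copy of domain
family ``i`` and 0 otherwise.  Copy numbers beyond the first are discarded:
the model downstream is a lattice gas over presence/absence, not abundance.

This module builds PPMs from long-format occurrence records or per-genome
presence lists, filters families by occurrence frequency, restricts the
family set to a reference genome's repertoire, and round-trips matrices
through a plain TSV representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "build_ppm",
    "presence_bounds",
    "filter_by_frequency",
    "restrict_to_reference",
    "read_occurrences",
]


@dataclass(frozen=True)
class ProfileMatrix:
    """Binary genome x domain-family presence/absence matrix.

    Attributes
    ----------
    species_ids : tuple of str
        Genome identifiers, one per row (length M), no duplicates.
    domain_ids : tuple of str
        Domain-family identifiers, one per column (length N), no duplicates.
    entries : numpy.ndarray
        M x N array with values in {0, 1}; entry (a, i) is the presence
        indicator of domain i in genome a.
    """

    species_ids: tuple[str, ...]
    domain_ids: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.uint8)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-D array")
        if entries.shape != (len(self.species_ids), len(self.domain_ids)):
            raise ValueError(
                f"entries shape {entries.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.domain_ids)} domains"
            )
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("entries must contain only 0 and 1")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species identifiers")
        if len(set(self.domain_ids)) != len(self.domain_ids):
            raise ValueError("duplicate domain identifiers")
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "domain_ids", tuple(self.domain_ids))
        object.__setattr__(self, "entries", entries)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_domains(self) -> int:
        return len(self.domain_ids)

    def column_counts(self) -> np.ndarray:
        """Number of genomes carrying each domain (column sums)."""
        return self.entries.sum(axis=0, dtype=np.int64)

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV: first column ``genome_id``, then one
        0/1 column per domain.  The representation round-trips bit-exactly."""
        df = pd.DataFrame(self.entries, index=list(self.species_ids),
                          columns=list(self.domain_ids))
        df.to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col="genome_id")
        entries = df.to_numpy(dtype=np.uint8) if df.shape[1] else \
            np.zeros((df.shape[0], 0), dtype=np.uint8)
        return cls(tuple(str(s) for s in df.index),
                   tuple(str(c) for c in df.columns), entries)


def build_ppm(occurrences: Iterable[tuple[str, str, int]]) -> ProfileMatrix:
    """Build a ProfileMatrix from long-format occurrence records.

    Parameters
    ----------
    occurrences : iterable of (genome_id, domain_id, copy_number)
        One record per observed (genome, domain) occurrence; copy numbers
        must be strictly positive.  Presence is idempotent: repeated records
        for the same pair, with any copy numbers, still yield a single 1.

    Returns
    -------
    ProfileMatrix
        Rows and columns sorted lexicographically by identifier, so the
        result is invariant under permutation of the input records.
    """
    present: set[tuple[str, str]] = set()
    genomes: set[str] = set()
    domains: set[str] = set()
    for genome_id, domain_id, copies in occurrences:
        if not genome_id or not domain_id:
            raise ValueError("genome and domain identifiers must be non-empty")
        if copies < 1:
            raise ValueError(
                f"copy number must be >= 1, got {copies} for "
                f"({genome_id}, {domain_id})"
            )
        present.add((str(genome_id), str(domain_id)))
        genomes.add(str(genome_id))
        domains.add(str(domain_id))
    if not present:
        raise ValueError("no occurrence records: cannot build an empty PPM")
    species_ids = tuple(sorted(genomes))
    domain_ids = tuple(sorted(domains))
    row = {g: a for a, g in enumerate(species_ids)}
    col = {d: i for i, d in enumerate(domain_ids)}
    entries = np.zeros((len(species_ids), len(domain_ids)), dtype=np.uint8)
    for g, d in present:
        entries[row[g], col[d]] = 1
    return ProfileMatrix(species_ids, domain_ids, entries)


def presence_bounds(n_species: int, f_min: float, f_max: float) -> tuple[int, int]:
    """Integer presence-count bounds implied by fractional frequency bounds.

    A domain is retained if its occurrence count lies in
    [ceil(f_min * M), floor(f_max * M)].  For M = 1041 and the conventional
    5%/95% band this gives the bounds (53, 988).
    """
    if not 0.0 <= f_min <= f_max <= 1.0:
        raise ValueError("require 0 <= f_min <= f_max <= 1")
    return math.ceil(f_min * n_species), math.floor(f_max * n_species)


def filter_by_frequency(ppm: ProfileMatrix, f_min: float,
                        f_max: float) -> ProfileMatrix:
    """Drop domain families that are too rare or too common.

    Near-omnipresent families (replication, transcription, translation
    machinery) and very rare ones carry little co-occurrence signal; both
    ends are cut.  Column i is kept iff its presence count lies within
    ``presence_bounds(M, f_min, f_max)``.  Rows are unchanged.
    """
    if ppm.n_species == 0:
        raise ValueError("PPM has no species")
    lo, hi = presence_bounds(ppm.n_species, f_min, f_max)
    counts = ppm.column_counts()
    keep = (counts >= lo) & (counts <= hi)
    if not keep.any():
        logger.warning(
            "frequency filter [%g, %g] removed all %d domains", f_min, f_max,
            ppm.n_domains)
    domain_ids = tuple(d for d, k in zip(ppm.domain_ids, keep) if k)
    return ProfileMatrix(ppm.species_ids, domain_ids, ppm.entries[:, keep])


def restrict_to_reference(ppm: ProfileMatrix,
                          reference_domains: Iterable[str]) -> ProfileMatrix:
    """Keep only domain families present in a reference genome's repertoire.

    Column order is preserved.  An empty intersection yields a 0-column
    matrix and a logged warning rather than an error.
    """
    reference = set(reference_domains)
    keep = np.array([d in reference for d in ppm.domain_ids], dtype=bool)
    if len(keep) and not keep.any():
        logger.warning("reference domain set is disjoint from the PPM; "
                       "all %d domains removed", ppm.n_domains)
    domain_ids = tuple(d for d, k in zip(ppm.domain_ids, keep) if k)
    return ProfileMatrix(ppm.species_ids, domain_ids, ppm.entries[:, keep])


def read_occurrences(path: str | Path) -> list[tuple[str, str, int]]:
    """Read occurrence records from TSV.

    Two layouts are accepted:

    * long format with header ``genome_id<TAB>domain_id<TAB>count``;
    * presence lists, one genome per line: ``genome_id<TAB>dom1,dom2,...``
      (every listed domain counts as one copy).
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
    fields = first.split("\t")
    if len(fields) >= 3 and fields[:3] == ["genome_id", "domain_id", "count"]:
        df = pd.read_csv(path, sep="\t", dtype={"genome_id": str,
                                                "domain_id": str,
                                                "count": np.int64})
        return list(zip(df["genome_id"], df["domain_id"], df["count"]))
    records: list[tuple[str, str, int]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            genome_id, _, doms = line.partition("\t")
            for d in doms.split(","):
                d = d.strip()
                if d:
                    records.append((genome_id, d, 1))
    return records
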