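"""Canonical in-memory model for amplicon profile data.

Every other module speaks these types: a seven-rank :class:`Lineage`, a
feature-by-sample :class:`FeatureTable` of integer counts, per-sample
:class:`SampleMetadata`, an ordered :class:`SequenceSet` of representative
sequences, a KO/pathway :class:`FunctionalTable`, and the KEGG BRITE
category tree (:class:`BriteHierarchy`).  No I/O happens here.

Unclassified rank entries are represented internally as ``None`` and
rendered as the literal label ``"unclassified"`` wherever a string is
needed; a blank taxon label therefore cannot escape into an output file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

N_RANKS = 7

#: Rank ladders of the two naming conventions seen upstream.  They differ
#: only in the top rank's spelling; positional semantics are identical.
RANKS_MRDNA = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANKS_ANACAPA = ("domain", "phylum", "class", "order", "family", "genus", "species")

UNCLASSIFIED_LABEL = "unclassified"

# Tokens treated as "unclassified" on ingest (case-insensitive), plus bare
# rank prefixes such as "g__" that some classifiers emit for empty slots.
_UNCLASSIFIED_TOKENS = {"unclassified", "unknown", "na", ""}
_BARE_PREFIX_RE = re.compile(r"^[a-zA-Z]__$")
_PREFIX_RE = re.compile(r"^[a-zA-Z]__")

KO_GENE_RE = re.compile(r"^K\d{5}$")
KO_PATHWAY_RE = re.compile(r"^(ko|map)\d{5}$")


class TaxbridgeError(Exception):
    """Base class for all errors raised by this package."""


class DialectError(TaxbridgeError):
    """An input file does not conform to the dialect it was declared as."""


def is_unclassified_token(label: str) -> bool:
    """True if a verbatim input label denotes an unclassified rank slot."""
    s = label.strip()
    return s.lower() in _UNCLASSIFIED_TOKENS or bool(_BARE_PREFIX_RE.match(s))


def clean_taxon_label(label: str) -> Optional[str]:
    """Normalize one verbatim taxon label; ``None`` means unclassified."""
    s = label.strip()
    if is_unclassified_token(s):
        return None
    s = _PREFIX_RE.sub("", s).strip()
    if s == "" or s.lower() in _UNCLASSIFIED_TOKENS:
        return None
    return s


@dataclass(frozen=True)
class Rank:
    """One level of the seven-rank ladder.

    ``index`` runs 0 (most inclusive: kingdom/domain) to 6 (species).
    """

    name: str
    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_RANKS:
            raise ValueError(f"rank index must be 0..{N_RANKS - 1}, got {self.index}")
        if self.name not in RANKS_MRDNA and self.name not in RANKS_ANACAPA:
            raise ValueError(f"unknown rank name {self.name!r}")
        expected = {RANKS_MRDNA[self.index], RANKS_ANACAPA[self.index]}
        if self.name not in expected:
            raise ValueError(
                f"rank name {self.name!r} does not belong at index {self.index}"
            )

    @classmethod
    def from_name(cls, name: str) -> "Rank":
        key = name.strip().lower()
        for ladder in (RANKS_MRDNA, RANKS_ANACAPA):
            if key in ladder:
                return cls(key, ladder.index(key))
        raise ValueError(f"unknown rank name {name!r}")

    @classmethod
    def from_index(cls, index: int, style: str = "mrdna") -> "Rank":
        ladder = RANKS_MRDNA if style == "mrdna" else RANKS_ANACAPA
        return cls(ladder[index], index)


@dataclass(frozen=True)
class Lineage:
    """A full seven-rank taxonomy path.

    ``taxa`` always has length 7; ``None`` marks an unclassified slot.
    ``source_labels`` keeps the verbatim strings seen on input for
    diagnostics and is ignored in equality comparisons.
    """

    taxa: tuple
    source_labels: tuple = field(default=(), compare=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != N_RANKS:
            raise ValueError(f"lineage must have {N_RANKS} entries, got {len(self.taxa)}")
        for t in self.taxa:
            if t is not None and (not isinstance(t, str) or t.strip() == ""):
                raise ValueError("classified lineage entries must be non-empty strings")

    @classmethod
    def from_labels(cls, labels: Sequence[str], warn=None) -> "Lineage":
        """Build a lineage from verbatim labels, padding/truncating to 7.

        Labels beyond rank 7 (e.g. subspecies) are discarded; ``warn`` is
        called with a message when that happens.
        """
        labels = list(labels)
        if len(labels) > N_RANKS and warn is not None:
            warn(f"lineage has {len(labels)} segments; truncating to {N_RANKS}")
        kept = labels[:N_RANKS]
        taxa = [clean_taxon_label(s) for s in kept]
        taxa += [None] * (N_RANKS - len(taxa))
        return cls(tuple(taxa), tuple(kept))

    @classmethod
    def all_unclassified(cls) -> "Lineage":
        return cls((None,) * N_RANKS)

    def is_strict(self) -> bool:
        """True iff no classified entry sits below an unclassified one."""
        return lineage_is_strict(self)

    def labels(self) -> tuple:
        """Rendered labels: unclassified slots become the literal token."""
        return tuple(UNCLASSIFIED_LABEL if t is None else t for t in self.taxa)

    def joined(self, sep: str = ";") -> str:
        return sep.join(self.labels())

    def depth(self) -> int:
        """Number of leading classified ranks (only meaningful if strict)."""
        d = 0
        for t in self.taxa:
            if t is None:
                break
            d += 1
        return d


def lineage_is_strict(lineage: Lineage) -> bool:
    """Check the strict-hierarchy rule downstream profile tools enforce.

    A lineage is strict when every classified entry precedes every
    unclassified entry — i.e. classification never resumes beneath a gap.
    An all-classified or all-unclassified lineage is trivially strict.
    """
    seen_gap = False
    for t in lineage.taxa:
        if t is None:
            seen_gap = True
        elif seen_gap:
            return False
    return True


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Feature (OTU/ASV) × sample matrix of non-negative integer counts.

    ``counts`` is a pandas DataFrame indexed by feature ID with sample IDs
    as columns; ``lineages`` is positionally aligned with the rows.
    """

    counts: pd.DataFrame
    lineages: list

    def __post_init__(self) -> None:
        if len(self.lineages) != len(self.counts.index):
            raise ValueError("one lineage required per feature")
        _check_unique(list(self.counts.index), "feature ID")
        _check_unique(list(self.counts.columns), "sample ID")
        arr = self.counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.equal(np.mod(arr, 1), 0)):
                    raise ValueError(
                        "counts must be integral; fractional (percentage-style) "
                        "tables are not accepted"
                    )
                self.counts = self.counts.astype(np.int64)
                arr = self.counts.to_numpy()
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return len(self.counts.index)

    @property
    def n_samples(self) -> int:
        return len(self.counts.columns)

    def sample_total(self, sample_id: str) -> int:
        return int(self.counts[sample_id].sum())

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def lineage_of(self, feature_id: str) -> Lineage:
        return self.lineages[self.counts.index.get_loc(feature_id)]

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.counts.index.get_loc(f) for f in feature_ids]
        return FeatureTable(
            self.counts.loc[list(feature_ids)].copy(),
            [self.lineages[i] for i in idx],
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.counts.equals(other.counts)
            and self.lineages == other.lineages
        )


@dataclass
class SampleMetadata:
    """Per-sample attributes keyed by sample ID (DataFrame-backed)."""

    frame: pd.DataFrame  # index = sample IDs, columns = attributes

    def __post_init__(self) -> None:
        ids = list(self.frame.index)
        for i in ids:
            if str(i).strip() == "":
                raise ValueError("empty sample ID in metadata")
        _check_unique([str(i) for i in ids], "metadata sample ID")
        for c in self.frame.columns:
            if str(c).strip() == "":
                raise ValueError("metadata has an empty column name")

    @property
    def sample_ids(self) -> list:
        return [str(i) for i in self.frame.index]


@dataclass(frozen=True)
class SeqRecord:
    """One FASTA record; serialization is canonical single-line form."""

    id: str
    sequence: str

    def fasta_bytes(self) -> bytes:
        return f">{self.id}\n{self.sequence}\n".encode("utf-8")

    def byte_size(self) -> int:
        return len(self.fasta_bytes())


@dataclass
class SequenceSet:
    """Ordered FASTA records with unique IDs."""

    records: list

    def __post_init__(self) -> None:
        _check_unique([r.id for r in self.records], "sequence ID")

    @property
    def ids(self) -> list:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def total_bytes(self) -> int:
        return sum(r.byte_size() for r in self.records)

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        wanted = set(ids)
        return SequenceSet([r for r in self.records if r.id in wanted])


@dataclass
class FunctionalTable:
    """KO-or-pathway × sample abundance matrix from functional inference.

    ``kind`` is ``"gene"`` (IDs like K00001) or ``"pathway"`` (ko/map
    numbers).  Abundances may be fractional — inference servers return
    weighted estimates, not raw counts.
    """

    counts: pd.DataFrame  # index = KO/pathway IDs, columns = sample IDs
    kind: str  # "gene" | "pathway"

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "pathway"):
            raise ValueError(f"kind must be 'gene' or 'pathway', got {self.kind!r}")
        _check_unique(list(self.counts.index), "functional ID")
        _check_unique(list(self.counts.columns), "sample ID")
        pattern = KO_GENE_RE if self.kind == "gene" else KO_PATHWAY_RE
        for i in self.counts.index:
            if not pattern.match(str(i)):
                raise ValueError(f"ID {i!r} does not match the {self.kind} pattern")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("functional abundances must be non-negative")

    @property
    def ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def grand_total(self) -> float:
        return float(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class BriteEntry:
    """Description plus every (A, B, C) category path a KO appears under."""

    description: str
    paths: tuple  # tuple of (levelA, levelB, levelC) string triples

    def __post_init__(self) -> None:
        if not self.description:
            raise ValueError("BRITE entry needs a non-empty description")
        if not self.paths:
            raise ValueError("BRITE entry needs at least one category path")


@dataclass
class BriteHierarchy:
    """KEGG BRITE KO hierarchy: KO id → description + category paths.

    ``pathway_names`` maps C-level pathway numbers (``ko#####``) to their
    names, for annotating pathway-level abundance tables.
    """

    entries: Mapping[str, BriteEntry]
    pathway_names: Mapping[str, str] = field(default_factory=dict)

    def __contains__(self, ko: str) -> bool:
        return ko in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, ko: str) -> Optional[BriteEntry]:
        return self.entries.get(ko)
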