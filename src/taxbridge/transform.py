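"""Validation, strict-hierarchy repair, collapsing, rarefaction, chunking.

These are the computations that sit between ingest and export: checking
sample-ID agreement between metadata and table, repairing lineages so
downstream profile tools accept them, collapsing tables to a chosen rank,
rarefaction subsampling to a common depth, and splitting sequence sets
into upload-sized chunks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .model import (
    N_RANKS,
    UNCLASSIFIED_LABEL,
    FeatureTable,
    Lineage,
    Rank,
    SampleMetadata,
    SequenceSet,
    TaxbridgeError,
)

DEFAULT_MAX_UPLOAD_BYTES = 10 * 2**20  # the functional-inference server's 10 MB cap
MAX_RAREFY_ITERATIONS = 10

_ID_ALPHABET_RE = re.compile(r"^[A-Za-z0-9_]+$")


class RarefactionWarning(UserWarning):
    """Emitted when a sample is dropped for insufficient depth."""


@dataclass
class ValidationReport:
    """Outcome of metadata/table sample-ID validation.

    ``ok`` is true iff all four lists are empty.  Validation never raises;
    callers decide whether a bad report aborts the run.
    """

    missing_in_table: List[str] = field(default_factory=list)
    missing_in_metadata: List[str] = field(default_factory=list)
    bad_character_ids: List[str] = field(default_factory=list)
    duplicates: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.missing_in_table
            or self.missing_in_metadata
            or self.bad_character_ids
            or self.duplicates
        )

    def summary(self) -> str:
        if self.ok:
            return "sample IDs consistent and well-formed"
        parts = []
        if self.missing_in_table:
            parts.append(f"in metadata but not table: {self.missing_in_table}")
        if self.missing_in_metadata:
            parts.append(f"in table but not metadata: {self.missing_in_metadata}")
        if self.bad_character_ids:
            parts.append(f"IDs with disallowed characters: {self.bad_character_ids}")
        if self.duplicates:
            parts.append(f"duplicate IDs: {self.duplicates}")
        return "; ".join(parts)


class ValidationError(TaxbridgeError):
    def __init__(self, report: ValidationReport):
        super().__init__(f"sample-ID validation failed: {report.summary()}")
        self.report = report


def validate(
    meta: SampleMetadata, table: FeatureTable, target: str = "generic"
) -> ValidationReport:
    """Check that metadata and table agree on well-formed sample IDs.

    The allowed ID alphabet is letters, digits and underscore.  Some
    downstream tools are stricter about specific characters — ranacapa
    accepts underscores but not periods in sample IDs — so IDs containing
    a period are always flagged by the alphabet rule; ``target`` is
    accepted for future per-tool rules and recorded in no way here.
    """
    meta_ids = meta.sample_ids
    table_ids = [str(s) for s in table.sample_ids]
    meta_set, table_set = set(meta_ids), set(table_ids)

    # duplicate IDs inside either source are rejected at construction time,
    # so only IDs slipping past the canonical types could land here
    duplicates = [i for i in dict.fromkeys(meta_ids) if meta_ids.count(i) > 1]
    duplicates += [i for i in dict.fromkeys(table_ids) if table_ids.count(i) > 1]
    report = ValidationReport(
        missing_in_table=[i for i in meta_ids if i not in table_set],
        missing_in_metadata=[i for i in table_ids if i not in meta_set],
        bad_character_ids=sorted(
            {i for i in meta_ids + table_ids if not _ID_ALPHABET_RE.match(i)}
        ),
        duplicates=duplicates,
    )
    return report


# ---------------------------------------------------------------------------
# Strict-hierarchy repair


def repair_lineage(lineage: Lineage, mode: str = "fill") -> Lineage:
    """Make a lineage satisfy the strict-hierarchy rule.

    mode="fill"
        Each *interior* unclassified slot (one with a classified entry
        somewhere below it) becomes the named node
        ``unclassified_<nearest classified ancestor>``, so information at
        deeper ranks is preserved.  Trailing unclassified slots stay
        unclassified.
    mode="truncate"
        Every slot at or below the shallowest unclassified one becomes
        unclassified, discarding any deeper classification.

    Either way the result passes the strict predicate and no rendered
    label is blank.
    """
    if mode not in ("fill", "truncate"):
        raise ValueError(f"repair mode must be 'fill' or 'truncate', got {mode!r}")
    taxa = list(lineage.taxa)
    if mode == "truncate":
        for i, t in enumerate(taxa):
            if t is None:
                return Lineage(tuple(taxa[:i]) + (None,) * (N_RANKS - i), lineage.source_labels)
        return lineage

    # fill: indices of classified entries, deepest first
    deepest_classified = max((i for i, t in enumerate(taxa) if t is not None), default=-1)
    ancestor = None
    out = []
    for i, t in enumerate(taxa):
        if t is not None:
            ancestor = t
            out.append(t)
        elif i < deepest_classified:
            # a top-rank gap has no ancestor; "root" keeps the filled node
            # distinct from the unclassified marker so round-trips are exact
            label = (
                f"{UNCLASSIFIED_LABEL}_{ancestor}"
                if ancestor is not None
                else f"{UNCLASSIFIED_LABEL}_root"
            )
            out.append(label)
            ancestor = label
        else:
            out.append(None)
    return Lineage(tuple(out), lineage.source_labels)


def repair_table(table: FeatureTable, mode: str = "fill") -> FeatureTable:
    """Repair every lineage of a table; counts are untouched."""
    return FeatureTable(
        table.counts.copy(), [repair_lineage(l, mode) for l in table.lineages]
    )


def is_repaired(table: FeatureTable) -> bool:
    return all(l.is_strict() for l in table.lineages)


# ---------------------------------------------------------------------------
# Rank collapsing


def collapse(table: FeatureTable, rank: Rank) -> FeatureTable:
    """Merge features sharing the same lineage prefix through ``rank``.

    Counts of merged features are summed, so every sample total is
    conserved exactly.  Requires repaired (strict) lineages; collapsing a
    non-strict table would silently merge unrelated gaps.
    """
    for fid, lin in zip(table.feature_ids, table.lineages):
        if not lin.is_strict():
            raise TaxbridgeError(
                f"feature {fid!r} has a non-strict lineage; repair the table "
                f"before collapsing"
            )
    depth = rank.index + 1
    groups: dict = {}
    order = []
    for i, lin in enumerate(table.lineages):
        key = lin.taxa[:depth]
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)

    rows = []
    lineages = []
    ids = []
    for key in order:
        idx = groups[key]
        rows.append(table.counts.iloc[idx].sum(axis=0))
        lineages.append(Lineage(tuple(key) + (None,) * (N_RANKS - depth)))
        ids.append(
            ";".join(UNCLASSIFIED_LABEL if t is None else t for t in key)
        )
    counts = (
        pd.DataFrame(rows, index=pd.Index(ids), columns=table.counts.columns)
        if rows
        else pd.DataFrame(index=pd.Index([]), columns=table.counts.columns, dtype=np.int64)
    )
    return FeatureTable(counts.astype(np.int64), lineages)


# ---------------------------------------------------------------------------
# Rarefaction


def rarefy(
    table: FeatureTable, depth: int, iterations: int = 1, seed: int = 0
) -> FeatureTable:
    """Rarefy each sample to ``depth`` reads without replacement.

    Each retained sample is subsampled ``iterations`` times (capped at
    10); per-feature counts are averaged over iterations and rounded
    half-up.  Samples whose total is below ``depth`` are dropped with a
    :class:`RarefactionWarning`.  Features whose rounded average is zero
    in every retained sample are dropped.  Output is bit-reproducible
    given (seed, depth, iterations).
    """
    if not 1 <= iterations <= MAX_RAREFY_ITERATIONS:
        raise ValueError(
            f"iterations must be between 1 and {MAX_RAREFY_ITERATIONS}, "
            f"got {iterations}"
        )
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")

    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    for s in dropped:
        warnings.warn(
            f"sample {s!r} (total {int(totals[s])}) below rarefaction depth "
            f"{depth}; dropped",
            RarefactionWarning,
            stacklevel=2,
        )
    if not keep:
        raise TaxbridgeError(
            f"rarefaction depth {depth} exceeds every sample total; no samples left"
        )

    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        acc = np.zeros(len(col), dtype=np.float64)
        for _ in range(iterations):
            acc += rng.multivariate_hypergeometric(col, depth)
        avg = acc / iterations
        out[s] = np.floor(avg + 0.5).astype(np.int64)  # round half-up

    counts = pd.DataFrame(out, index=table.counts.index)
    nonzero = counts.sum(axis=1) > 0
    counts = counts.loc[nonzero]
    lineages = [l for l, keep_f in zip(table.lineages, nonzero) if keep_f]
    return FeatureTable(counts, lineages)


# ---------------------------------------------------------------------------
# Size-constrained co-chunking


def chunk_for_upload(
    seqs: SequenceSet,
    table: FeatureTable,
    max_bytes: int = DEFAULT_MAX_UPLOAD_BYTES,
) -> List[Tuple[SequenceSet, FeatureTable]]:
    """Split sequences + table into chunks whose FASTA fits an upload cap.

    Greedy first-fit in input order: records are appended to the current
    chunk until adding one would push its serialized FASTA past
    ``max_bytes``.  Each chunk is paired with the sub-table holding
    exactly its features (all samples retained).  The chunks partition
    the input: union equals it, pairwise intersection is empty, order is
    preserved.
    """
    seq_ids = set(seqs.ids)
    feat_ids = set(table.feature_ids)
    missing_seq = sorted(feat_ids - seq_ids)
    missing_feat = sorted(seq_ids - feat_ids)
    if missing_seq or missing_feat:
        raise TaxbridgeError(
            f"feature/sequence ID mismatch: features without sequences "
            f"{missing_seq}; sequences without features {missing_feat}"
        )

    chunks: List[List] = []
    current: List = []
    current_bytes = 0
    for rec in seqs:
        size = rec.byte_size()
        if size > max_bytes:
            raise TaxbridgeError(
                f"record {rec.id!r} alone serializes to {size} bytes, "
                f"exceeding the {max_bytes}-byte limit"
            )
        if current and current_bytes + size > max_bytes:
            chunks.append(current)
            current = []
            current_bytes = 0
        current.append(rec)
        current_bytes += size
    if current:
        chunks.append(current)

    out = []
    for recs in chunks:
        ids = [r.id for r in recs]
        out.append((SequenceSet(list(recs)), table.subset_features(ids)))
    return out
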