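"""Parsers for the supported upstream dialects.

Three taxonomic-table dialects are read into the canonical
:class:`~taxbridge.model.FeatureTable`:

* **MrDNA** — one delimited table per taxonomic rank; the deepest file
  defines the features and lineages are reconstructed by joining the
  per-rank files (see :func:`read_mrdna`).
* **Anacapa** — a single ASV table with a semicolon-joined
  ``sum.taxonomy`` lineage column.
* **QIIME 2** — a feature-table text export (``#OTU ID`` header) with a
  separate taxonomy mapping file, or the ``.qza`` zip container wrapping
  such an export.

Plus FASTA representative sequences and Piphillin ``.tar`` result
archives of KO / pathway abundance tables.

Delimiters are sniffed per file from the header line: tab wins if
present, otherwise comma.
"""

from __future__ import annotations

import io
import tarfile
import warnings
import zipfile
from pathlib import Path
from typing import List, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO

from .model import (
    N_RANKS,
    KO_GENE_RE,
    KO_PATHWAY_RE,
    DialectError,
    FeatureTable,
    FunctionalTable,
    Lineage,
    Rank,
    SampleMetadata,
    SeqRecord,
    SequenceSet,
)

PathLike = Union[str, Path]


def sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_delimited(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = sniff_delimiter(first)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _counts_frame(raw: pd.DataFrame, sample_cols: List[str], path: PathLike) -> pd.DataFrame:
    """Convert string cells to integer counts with coordinates on failure."""
    out = {}
    for col in sample_cols:
        vals = []
        for row_i, cell in enumerate(raw[col]):
            try:
                f = float(cell)
            except ValueError:
                raise DialectError(
                    f"{path}: non-numeric count {cell!r} at row {row_i + 2}, "
                    f"column {col!r}"
                ) from None
            vals.append(f)
        out[col] = vals
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# MrDNA


def read_mrdna(per_rank_files: Mapping[Union[Rank, str], PathLike]) -> FeatureTable:
    """Read MrDNA-style per-rank OTU tables into one genus/species table.

    Each file's layout: first column = taxon name at that rank, an
    optional ``taxonomy`` column holding the semicolon-joined path, then
    one count column per sample.  The deepest provided rank file defines
    the features; lineages above it are reconstructed by matching each
    feature's count vector against shallower-rank taxa (a parent with a
    single child shares its count vector exactly).  Where the match is
    absent or ambiguous, the deepest file's ``taxonomy`` path column is
    used instead if present; otherwise the unresolved ranks are left
    unclassified.

    MrDNA deliveries carry no feature IDs, so IDs are synthesized as
    ``F`` + zero-padded row index, deterministic in input order.
    """
    ranks = {
        (r if isinstance(r, Rank) else Rank.from_name(r)): Path(p)
        for r, p in per_rank_files.items()
    }
    if not ranks:
        raise DialectError("no per-rank files supplied")
    deepest = max(ranks, key=lambda r: r.index)

    tables = {}
    sample_cols: Optional[List[str]] = None
    tax_cols = {}
    for rank in sorted(ranks, key=lambda r: r.index):
        raw = _read_delimited(ranks[rank])
        cols = list(raw.columns)
        if not cols:
            raise DialectError(f"{ranks[rank]}: empty header")
        name_col = cols[0]
        tax_col = next((c for c in cols[1:] if c.strip().lower() == "taxonomy"), None)
        scols = [c for c in cols[1:] if c != tax_col]
        if sample_cols is None:
            sample_cols = scols
        elif scols != sample_cols:
            raise DialectError(
                f"{ranks[rank]}: sample columns {scols} do not match "
                f"those of the other rank files {sample_cols}"
            )
        tables[rank] = (raw, name_col)
        tax_cols[rank] = tax_col

    deep_raw, deep_name_col = tables[deepest]
    assert sample_cols is not None
    counts = _counts_frame(deep_raw, sample_cols, ranks[deepest])

    n = len(deep_raw)
    width = max(4, len(str(max(n - 1, 0))))
    feature_ids = [f"F{str(i).zfill(width)}" for i in range(n)]

    # count-vector -> unique taxon name, per shallower rank
    vector_maps = {}
    for rank in ranks:
        if rank.index >= deepest.index:
            continue
        raw, name_col = tables[rank]
        cf = _counts_frame(raw, sample_cols, ranks[rank])
        vm: dict = {}
        for i, name in enumerate(raw[name_col]):
            key = tuple(cf.iloc[i])
            vm.setdefault(key, []).append(name)
        vector_maps[rank] = vm

    deep_tax_col = tax_cols[deepest]
    lineages = []
    for i in range(n):
        key = tuple(counts.iloc[i])
        taxa: list = [None] * N_RANKS
        taxa[deepest.index] = deep_raw[deep_name_col].iloc[i]
        resolved = True
        for rank, vm in vector_maps.items():
            names = vm.get(key, [])
            if len(names) == 1:
                taxa[rank.index] = names[0]
            else:
                resolved = False
        if (not resolved or not vector_maps) and deep_tax_col is not None:
            lineages.append(
                Lineage.from_labels(
                    deep_raw[deep_tax_col].iloc[i].split(";"),
                    warn=lambda m: warnings.warn(m, stacklevel=2),
                )
            )
        else:
            lineages.append(Lineage.from_labels([t if t is not None else "" for t in taxa]))

    counts.index = pd.Index(feature_ids)
    return FeatureTable(counts, lineages)


# ---------------------------------------------------------------------------
# Anacapa


def read_anacapa(table: PathLike) -> FeatureTable:
    """Read an Anacapa ASV table (``sum.taxonomy`` lineage column)."""
    raw = _read_delimited(table)
    cols = list(raw.columns)
    tax_col = next((c for c in cols if c.strip().lower() == "sum.taxonomy"), None)
    if tax_col is None:
        raise DialectError(f"{table}: no 'sum.taxonomy' lineage column found")
    id_col = cols[0]
    sample_cols = [c for c in cols if c not in (id_col, tax_col)]
    if not sample_cols:
        raise DialectError(f"{table}: no sample count columns")
    counts = _counts_frame(raw, sample_cols, table)
    counts.index = pd.Index(list(raw[id_col]))
    lineages = [
        Lineage.from_labels(
            s.split(";") if s != "" else [],
            warn=lambda m: warnings.warn(m, stacklevel=2),
        )
        for s in raw[tax_col]
    ]
    return FeatureTable(counts, lineages)


# ---------------------------------------------------------------------------
# QIIME 2


def _parse_qiime2_export(text: str, source: str) -> pd.DataFrame:
    lines = text.splitlines()
    # skip biom-style comment lines before the '#OTU ID' header
    start = 0
    while start < len(lines) and not lines[start].startswith("#OTU ID"):
        if not lines[start].startswith("#"):
            break
        start += 1
    if start >= len(lines) or not lines[start].startswith("#OTU ID"):
        raise DialectError(f"{source}: no '#OTU ID' header line found")
    body = "\n".join(lines[start:])
    sep = sniff_delimiter(lines[start])
    return pd.read_csv(io.StringIO(body), sep=sep, dtype=str, keep_default_na=False)


def _parse_taxonomy_mapping(text: str, source: str) -> dict:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return {}
    sep = sniff_delimiter(lines[0])
    mapping = {}
    first_cells = lines[0].split(sep)
    start = 1 if first_cells and first_cells[0].strip().lower() in (
        "feature id",
        "#otu id",
        "otu id",
    ) else 0
    for ln in lines[start:]:
        cells = ln.split(sep)
        if len(cells) >= 2:
            # a trailing confidence column, if any, is ignored
            mapping[cells[0]] = cells[1]
    return mapping


def read_qiime2(
    artifact_or_export: PathLike, taxonomy: Optional[PathLike] = None
) -> FeatureTable:
    """Read a QIIME 2 feature table from a text export or ``.qza`` zip.

    A ``.qza`` artifact is a zip container; the packaged text export under
    its internal ``data/`` directory is located and parsed.  Without a
    taxonomy mapping (separate file, or a taxonomy member inside the same
    archive) every lineage is all-unclassified and a warning is recorded.
    """
    path = Path(artifact_or_export)
    tax_text: Optional[str] = None
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            members = zf.namelist()
            table_member = None
            tax_member = None
            for m in members:
                if "/data/" in m and m.endswith((".tsv", ".txt", ".csv")):
                    low = Path(m).name.lower()
                    if "taxonomy" in low:
                        tax_member = m
                    else:
                        table_member = table_member or m
            if table_member is None:
                raise DialectError(
                    f"{path}: no feature-table export found in archive; "
                    f"members: {members}"
                )
            text = zf.read(table_member).decode("utf-8")
            if tax_member is not None:
                tax_text = zf.read(tax_member).decode("utf-8")
    else:
        text = path.read_text(encoding="utf-8")

    raw = _parse_qiime2_export(text, str(path))
    cols = list(raw.columns)
    id_col = cols[0]
    sample_cols = cols[1:]
    counts = _counts_frame(raw, sample_cols, path)
    counts.index = pd.Index(list(raw[id_col]))

    if taxonomy is not None:
        tax_text = Path(taxonomy).read_text(encoding="utf-8")
    if tax_text is None:
        warnings.warn(
            f"{path}: no taxonomy mapping supplied; all lineages unclassified",
            stacklevel=2,
        )
        lineages = [Lineage.all_unclassified() for _ in range(len(counts))]
    else:
        mapping = _parse_taxonomy_mapping(tax_text, str(path))
        lineages = []
        for fid in counts.index:
            tax = mapping.get(fid)
            if tax is None:
                lineages.append(Lineage.all_unclassified())
            else:
                lineages.append(
                    Lineage.from_labels(
                        tax.split(";") if tax else [],
                        warn=lambda m: warnings.warn(m, stacklevel=2),
                    )
                )
    return FeatureTable(counts, lineages)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> SequenceSet:
    """Read FASTA records; IDs are the header token before whitespace."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise DialectError(f"{path}: sequence data before the first FASTA header")
    records = [
        SeqRecord(rec.id, str(rec.seq))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    try:
        return SequenceSet(records)
    except ValueError as e:
        raise DialectError(f"{path}: {e}") from None


def read_metadata(path: PathLike) -> SampleMetadata:
    """Read a delimited metadata file; first column = sample IDs."""
    raw = _read_delimited(path)
    if raw.shape[1] < 1:
        raise DialectError(f"{path}: metadata has no columns")
    frame = raw.set_index(raw.columns[0])
    return SampleMetadata(frame)


# ---------------------------------------------------------------------------
# Piphillin result archives


def _classify_functional(ids: List[str]) -> Optional[str]:
    if ids and all(KO_GENE_RE.match(i) for i in ids):
        return "gene"
    if ids and all(KO_PATHWAY_RE.match(i) for i in ids):
        return "pathway"
    return None


def read_piphillin_tar(archive: PathLike) -> List[FunctionalTable]:
    """Read KO/pathway abundance tables from a Piphillin ``.tar`` result.

    Members are recognized by content shape — a delimited table whose
    first column is all K-numbers (gene) or ko/map numbers (pathway) —
    not by filename, since the archives carry no fixed naming.  Plain and
    gzip-compressed tars are both accepted.
    """
    archive = Path(archive)
    tables: List[FunctionalTable] = []
    member_names: List[str] = []
    with tarfile.open(archive, "r:*") as tf:
        for member in tf.getmembers():
            if not member.isfile():
                continue
            member_names.append(member.name)
            fh = tf.extractfile(member)
            if fh is None:
                continue
            try:
                text = fh.read().decode("utf-8")
            except UnicodeDecodeError:
                continue
            lines = [ln for ln in text.splitlines() if ln.strip()]
            if len(lines) < 2:
                continue
            sep = sniff_delimiter(lines[0])
            raw = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
            if raw.shape[1] < 2:
                continue
            ids = [str(x) for x in raw.iloc[:, 0]]
            kind = _classify_functional(ids)
            if kind is None:
                continue
            sample_cols = list(raw.columns[1:])
            counts = pd.DataFrame(
                {c: pd.to_numeric(raw[c], errors="coerce") for c in sample_cols}
            )
            if counts.isna().any().any():
                continue
            counts.index = pd.Index(ids)
            tables.append(FunctionalTable(counts, kind))
    if not tables:
        raise DialectError(
            f"{archive}: no KO or pathway abundance table recognized; "
            f"members: {member_names}"
        )
    return tables
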