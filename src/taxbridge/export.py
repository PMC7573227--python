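"""Writers for every downstream analysis/visualization target.

Each writer is total on valid input, writes UTF-8 text with LF line
endings, and conserves the table's grand total (a count appears exactly
once, or is distributed over rows that sum back to it).  Where a matching
reader exists in :mod:`taxbridge.ingest`, write → read round-trips are
exact.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd
import skbio

from .model import (
    N_RANKS,
    UNCLASSIFIED_LABEL,
    FeatureTable,
    FunctionalTable,
    Rank,
    SampleMetadata,
    SequenceSet,
    TaxbridgeError,
)
from .transform import (
    DEFAULT_MAX_UPLOAD_BYTES,
    ValidationError,
    chunk_for_upload,
    validate,
)

PathLike = Union[str, Path]

RUN_SUBFOLDERS = (
    "excel",
    "stamp",
    "ranacapa",
    "cytoscape",
    "qiime2",
    "piphillin",
    "functional",
)

SPF_LEVEL_HEADERS = tuple(f"Level_{i}" for i in range(1, N_RANKS + 1))


def _write_text(path: PathLike, lines: List[str]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ln in lines:
            fh.write(ln)
            fh.write("\n")
    return path


def write_spf(table: FeatureTable, path: PathLike) -> Path:
    """Write a STAMP profile (SPF): 7 hierarchy columns then samples.

    STAMP enforces a strict hierarchy and refuses blank labels, so a
    table with any non-strict lineage is rejected here with the feature
    and the offending rank named — repairing is the caller's decision,
    not the writer's.
    """
    for fid, lin in zip(table.feature_ids, table.lineages):
        if not lin.is_strict():
            bad = next(
                i
                for i in range(N_RANKS)
                if lin.taxa[i] is None and any(t is not None for t in lin.taxa[i + 1 :])
            )
            raise TaxbridgeError(
                f"feature {fid!r} is unclassified at rank index {bad} but "
                f"classified below it; repair the table before writing SPF"
            )
    header = "\t".join(SPF_LEVEL_HEADERS + tuple(str(s) for s in table.sample_ids))
    lines = [header]
    for fid, lin in zip(table.feature_ids, table.lineages):
        row = list(lin.labels()) + [str(int(v)) for v in table.counts.loc[fid]]
        lines.append("\t".join(row))
    return _write_text(path, lines)


def write_cytoscape(
    table: Union[FeatureTable, FunctionalTable],
    rank: Optional[Rank],
    path: PathLike,
) -> Path:
    """Write a weighted edge list (sample → taxon/KO, weight = count).

    Every (source, target) pair occurs once; features mapping to the same
    label at the chosen rank are summed into one edge.  Zero-weight pairs
    are omitted.
    """
    edges: dict = {}
    if isinstance(table, FeatureTable):
        idx = rank.index if rank is not None else N_RANKS - 1
        for fid, lin in zip(table.feature_ids, table.lineages):
            label = lin.labels()[idx]
            for s in table.sample_ids:
                v = int(table.counts.at[fid, s])
                if v:
                    edges[(str(s), label)] = edges.get((str(s), label), 0) + v
    else:
        for ko in table.ids:
            for s in table.sample_ids:
                v = table.counts.at[ko, s]
                if v:
                    edges[(str(s), str(ko))] = edges.get((str(s), str(ko)), 0) + v

    lines = ["source\ttarget\tweight"]
    for (src, tgt), w in edges.items():
        lines.append(f"{src}\t{tgt}\t{w}")
    return _write_text(path, lines)


def write_ranacapa(
    table: FeatureTable, meta: SampleMetadata, out_dir: PathLike
) -> List[Path]:
    """Write the taxonomy table + metadata pair the ranacapa Shiny app wants.

    The taxonomy table carries an ASV-ID column, a single semicolon-joined
    ``sum.taxonomy`` lineage column, then per-sample counts.  Sample IDs
    are validated first (ranacapa accepts underscores but not periods);
    a failing report raises :class:`ValidationError`.
    """
    report = validate(meta, table, target="ranacapa")
    if not report.ok:
        raise ValidationError(report)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    header = "\t".join(["ASV", "sum.taxonomy"] + [str(s) for s in table.sample_ids])
    lines = [header]
    for fid, lin in zip(table.feature_ids, table.lineages):
        row = [str(fid), lin.joined()] + [str(int(v)) for v in table.counts.loc[fid]]
        lines.append("\t".join(row))
    taxonomy_path = _write_text(out_dir / "ranacapa_taxonomy.txt", lines)

    meta_lines = ["\t".join(["sample_id"] + [str(c) for c in meta.frame.columns])]
    for sid in meta.sample_ids:
        meta_lines.append(
            "\t".join([sid] + [str(v) for v in meta.frame.loc[sid]])
        )
    meta_path = _write_text(out_dir / "ranacapa_metadata.txt", meta_lines)
    return [taxonomy_path, meta_path]


def write_qiime2_inputs(
    table: FeatureTable,
    meta: SampleMetadata,
    tree: Optional[str],
    out_dir: PathLike,
) -> List[Path]:
    """Write feature-table / metadata / taxonomy (and optional tree) files
    importable into a QIIME 2 environment.

    The feature table leads with ``#OTU ID``; metadata leads with
    ``sample-id``; the taxonomy mapping is feature → semicolon lineage.
    A supplied newick tree is copied verbatim after checking its leaf set
    is a subset of the feature IDs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    lines = ["\t".join(["#OTU ID"] + [str(s) for s in table.sample_ids])]
    for fid in table.feature_ids:
        lines.append(
            "\t".join([str(fid)] + [str(int(v)) for v in table.counts.loc[fid]])
        )
    written.append(_write_text(out_dir / "feature-table.tsv", lines))

    meta_lines = ["\t".join(["sample-id"] + [str(c) for c in meta.frame.columns])]
    for sid in meta.sample_ids:
        meta_lines.append("\t".join([sid] + [str(v) for v in meta.frame.loc[sid]]))
    written.append(_write_text(out_dir / "metadata.tsv", meta_lines))

    tax_lines = ["Feature ID\tTaxon"]
    for fid, lin in zip(table.feature_ids, table.lineages):
        tax_lines.append(f"{fid}\t{lin.joined()}")
    written.append(_write_text(out_dir / "taxonomy.tsv", tax_lines))

    if tree is not None:
        tnode = skbio.TreeNode.read([tree])
        leaves = {t.name for t in tnode.tips()}
        extras = sorted(leaves - set(str(f) for f in table.feature_ids))
        if extras:
            raise TaxbridgeError(
                f"tree has leaves not present in the feature table: {extras}"
            )
        tree_path = out_dir / "tree.nwk"
        tree_path.write_text(tree if tree.endswith("\n") else tree + "\n", encoding="utf-8")
        written.append(tree_path)
    return written


def write_excel_long(
    table: FeatureTable, rank: Optional[Rank], path: PathLike
) -> Path:
    """Write a long-format table ready for pivot-table summarization.

    Columns: SampleID, the 7 rank levels, Count — one row per nonzero
    (sample, feature) cell.  ``rank`` optionally collapses first so the
    pivot works at a coarser level; the Count column always totals the
    table's grand total.
    """
    from .transform import collapse

    work = collapse(table, rank) if rank is not None else table
    rank_headers = [f"Level_{i}" for i in range(1, N_RANKS + 1)]
    lines = ["\t".join(["SampleID"] + rank_headers + ["Count"])]
    for fid, lin in zip(work.feature_ids, work.lineages):
        labels = lin.labels()
        for s in work.sample_ids:
            v = int(work.counts.at[fid, s])
            if v:
                lines.append("\t".join([str(s)] + list(labels) + [str(v)]))
    return _write_text(path, lines)


def write_piphillin_inputs(
    seqs: SequenceSet,
    table: FeatureTable,
    out_dir: PathLike,
    max_bytes: int = DEFAULT_MAX_UPLOAD_BYTES,
) -> List[Path]:
    """Write upload-ready FASTA + abundance CSV pairs for Piphillin.

    One chunk yields exactly ``piphillinseqs.fasta`` and
    ``piphillinotu.csv``; k > 1 chunks yield ``piphillinseqs<i>.fasta``
    and ``piphillinotu.csv<i>.csv`` for i = 1..k — the upstream server's
    established (if idiosyncratic) naming, reproduced deliberately.  The
    CSV's first column repeats the FASTA header IDs verbatim.  Every
    FASTA file respects ``max_bytes``; an oversized CSV only warns, since
    the upload cap is documented for the FASTA.
    """
    import warnings as _warnings

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chunks = chunk_for_upload(seqs, table, max_bytes=max_bytes)
    written: List[Path] = []
    multi = len(chunks) > 1
    for i, (chunk_seqs, chunk_table) in enumerate(chunks, start=1):
        fasta_name = f"piphillinseqs{i}.fasta" if multi else "piphillinseqs.fasta"
        csv_name = f"piphillinotu.csv{i}.csv" if multi else "piphillinotu.csv"

        fasta_path = out_dir / fasta_name
        with open(fasta_path, "wb") as fh:
            for rec in chunk_seqs:
                fh.write(rec.fasta_bytes())
        written.append(fasta_path)

        lines = [",".join(["#OTU ID"] + [str(s) for s in chunk_table.sample_ids])]
        for rec in chunk_seqs:
            lines.append(
                ",".join(
                    [rec.id] + [str(int(v)) for v in chunk_table.counts.loc[rec.id]]
                )
            )
        csv_path = _write_text(out_dir / csv_name, lines)
        if csv_path.stat().st_size > max_bytes:
            _warnings.warn(
                f"{csv_name} exceeds {max_bytes} bytes; the upload cap is "
                f"documented for the FASTA only",
                stacklevel=2,
            )
        written.append(csv_path)
    return written


def make_run_folder(
    base_dir: PathLike, timestamp: Optional[_dt.datetime] = None
) -> Path:
    """Create ``<base>/output/<YYYYMMDD-HHMMSSZ>/`` with tool subfolders.

    Never overwrites: a second run in the same second gets ``-1``,
    ``-2``, … suffixes.  ``timestamp`` is injectable for reproducible
    layouts in tests.
    """
    ts = timestamp or _dt.datetime.now(_dt.timezone.utc)
    stamp = ts.strftime("%Y%m%d-%H%M%S") + "Z"
    base = Path(base_dir) / "output"
    base.mkdir(parents=True, exist_ok=True)
    candidate = base / stamp
    suffix = 0
    while candidate.exists():
        suffix += 1
        candidate = base / f"{stamp}-{suffix}"
    candidate.mkdir()
    for sub in RUN_SUBFOLDERS:
        (candidate / sub).mkdir()
    return candidate
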