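"""The inferred-function leg: merge chunked inference results, parse the
KEGG BRITE hierarchy, annotate KO tables, and write functional outputs.

Functional inference servers accept chunked uploads and return one
abundance table per chunk; :func:`merge_chunk_results` sums them back
into one table.  KO identifiers alone carry no biology, so
:func:`annotate` attaches descriptions and the three-level BRITE
category path parsed offline from a ``.keg`` file — a live KEGG query
adapter can sit behind the same :func:`parse_brite` contract, but the
offline file is the tested ground truth.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

import pandas as pd

from .model import (
    BriteEntry,
    BriteHierarchy,
    FunctionalTable,
    TaxbridgeError,
)

PathLike = Union[str, Path]

UNANNOTATED = "unannotated"

_D_LINE_RE = re.compile(r"^D\s+(K\d{5})\s+(.*)$")
_LEVEL_CODE_RE = re.compile(r"^\d{5}\s+")
# trailing bracketed tags: [PATH:ko00010], [EC:1.1.1.1], [BR:ko00001] ...
_PATH_TAG_RE = re.compile(r"\s*\[[^\]]*\]\s*$")
_C_PATHWAY_RE = re.compile(r"^(\d{5})\s+")


def merge_chunk_results(tables: List[FunctionalTable]) -> FunctionalTable:
    """Element-wise sum of per-chunk tables over the union of their IDs.

    All tables must share one sample-ID set and one gene/pathway kind.
    An ID absent from a chunk contributes zero; an ID present in several
    chunks (a KO predicted from features that landed in different
    chunks) sums.  ID order is first-seen across the input list.
    """
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    kinds = {t.kind for t in tables}
    if len(kinds) > 1:
        raise TaxbridgeError(f"cannot merge mixed table kinds: {sorted(kinds)}")
    ref = set(first.sample_ids)
    for t in tables[1:]:
        if set(t.sample_ids) != ref:
            only_ref = sorted(ref - set(t.sample_ids))
            only_t = sorted(set(t.sample_ids) - ref)
            raise TaxbridgeError(
                f"sample sets differ between chunks: only in first {only_ref}; "
                f"only in other {only_t}"
            )
    order: List[str] = []
    seen = set()
    for t in tables:
        for i in t.ids:
            if i not in seen:
                seen.add(i)
                order.append(i)
    acc = pd.DataFrame(0.0, index=pd.Index(order), columns=first.counts.columns)
    for t in tables:
        acc = acc.add(t.counts.reindex(index=order, columns=acc.columns, fill_value=0.0), fill_value=0.0)
    return FunctionalTable(acc, first.kind)


def parse_brite(keg_file: PathLike) -> BriteHierarchy:
    """Parse a KEGG BRITE ``.keg`` hierarchy file.

    The format is line-oriented: lines starting A/B/C open category
    levels, D lines hold gene entries of the shape
    ``K00001  E1.1.1.1, adh; alcohol dehydrogenase [EC:1.1.1.1]`` —
    the description is the text after the first semicolon, symbols
    before it.  A KO appearing under several C categories gets one path
    per occurrence.  Malformed D lines are skipped and counted in a
    single summary warning; a file yielding no D entries is an error.
    """
    keg_file = Path(keg_file)
    entries: Dict[str, dict] = {}
    pathway_names: Dict[str, str] = {}
    level_a = level_b = level_c = ""
    skipped = 0

    for raw_line in keg_file.read_text(encoding="utf-8").splitlines():
        if not raw_line or raw_line[0] in "#!+%":
            continue
        tag, rest = raw_line[0], raw_line[1:].strip()
        rest = re.sub(r"</?b>", "", rest).strip()  # some .keg files bold A-lines
        if tag == "A":
            level_a = _LEVEL_CODE_RE.sub("", rest)
        elif tag == "B":
            level_b = _LEVEL_CODE_RE.sub("", rest)
        elif tag == "C":
            m = _C_PATHWAY_RE.match(rest)
            name = _PATH_TAG_RE.sub("", _LEVEL_CODE_RE.sub("", rest))
            level_c = name
            if m:
                pathway_names[f"ko{m.group(1)}"] = name
        elif tag == "D":
            m = _D_LINE_RE.match(raw_line)
            if not m:
                skipped += 1
                continue
            ko, remainder = m.group(1), m.group(2)
            remainder = _PATH_TAG_RE.sub("", remainder).strip()
            if ";" in remainder:
                desc = remainder.split(";", 1)[1].strip()
            else:
                desc = remainder
            if not desc:
                skipped += 1
                continue
            path = (level_a, level_b, level_c)
            rec = entries.setdefault(ko, {"description": desc, "paths": []})
            if path not in rec["paths"]:
                rec["paths"].append(path)

    if skipped:
        warnings.warn(f"{keg_file}: skipped {skipped} malformed D line(s)", stacklevel=2)
    if not entries:
        raise TaxbridgeError(f"{keg_file}: no gene (D-level) entries parsed")
    return BriteHierarchy(
        {k: BriteEntry(v["description"], tuple(v["paths"])) for k, v in entries.items()},
        pathway_names,
    )


@dataclass
class AnnotatedFunctionalTable:
    """A functional table with BRITE category columns attached.

    ``frame`` holds levelA/levelB/levelC/description columns followed by
    the sample abundance columns, one row per KO in input order;
    ``all_paths`` is the sidecar mapping KO → every (A, B, C) path, for
    KOs that live under more than one category.
    """

    frame: pd.DataFrame  # index = KO ids
    kind: str
    sample_ids: List[str]
    all_paths: Dict[str, Tuple] = field(default_factory=dict)

    def abundances(self) -> pd.DataFrame:
        return self.frame[self.sample_ids]

    def grand_total(self) -> float:
        return float(self.abundances().to_numpy().sum())


def annotate(fn: FunctionalTable, brite: BriteHierarchy) -> AnnotatedFunctionalTable:
    """Attach BRITE levels + description to every row of a KO table.

    Abundance values are never modified.  A KO under multiple BRITE
    paths uses the lexicographically first as its primary row (profile
    tools need one parent per node) with the full list kept in the
    sidecar.  KOs missing from the hierarchy are labeled ``unannotated``
    at every level.  Pathway-kind tables are matched against C-level
    pathway names by ID.
    """
    rows = []
    all_paths: Dict[str, Tuple] = {}
    for i in fn.ids:
        if fn.kind == "gene":
            entry = brite.get(i)
            if entry is None:
                rows.append((UNANNOTATED, UNANNOTATED, UNANNOTATED, UNANNOTATED))
            else:
                paths = sorted(entry.paths)
                rows.append(paths[0] + (entry.description,))
                if len(entry.paths) > 1:
                    all_paths[i] = tuple(paths)
        else:
            name = brite.pathway_names.get(str(i))
            if name is None:
                rows.append((UNANNOTATED, UNANNOTATED, UNANNOTATED, UNANNOTATED))
            else:
                rows.append((UNANNOTATED, UNANNOTATED, name, name))
    ann = pd.DataFrame(
        rows, index=fn.counts.index, columns=["levelA", "levelB", "levelC", "description"]
    )
    frame = pd.concat([ann, fn.counts], axis=1)
    return AnnotatedFunctionalTable(frame, fn.kind, [str(s) for s in fn.sample_ids], all_paths)


def write_functional_outputs(
    annotated: AnnotatedFunctionalTable, out_dir: PathLike
) -> List[Path]:
    """Write the three functional files: STAMP SPF, Excel long, edge list.

    The SPF hierarchy is (levelA, levelB, levelC, "KO description") —
    strict by construction since each KO carries exactly one primary
    path.  The sidecar of KOs with multiple BRITE paths is written
    alongside when non-empty.
    """
    from .export import _write_text

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    frame = annotated.frame
    samples = annotated.sample_ids

    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    spf_lines = ["\t".join(["Level_1", "Level_2", "Level_3", "Level_4"] + samples)]
    for ko in frame.index:
        label = f"{ko} {frame.at[ko, 'description']}"
        row = [
            str(frame.at[ko, "levelA"]),
            str(frame.at[ko, "levelB"]),
            str(frame.at[ko, "levelC"]),
            label,
        ] + [fmt(frame.at[ko, s]) for s in samples]
        spf_lines.append("\t".join(row))
    written.append(_write_text(out_dir / "functional.spf", spf_lines))

    long_lines = ["\t".join(["SampleID", "ID", "levelA", "levelB", "levelC", "description", "Abundance"])]
    for ko in frame.index:
        for s in samples:
            v = float(frame.at[ko, s])
            if v:
                long_lines.append(
                    "\t".join(
                        [
                            s,
                            str(ko),
                            str(frame.at[ko, "levelA"]),
                            str(frame.at[ko, "levelB"]),
                            str(frame.at[ko, "levelC"]),
                            str(frame.at[ko, "description"]),
                            fmt(v),
                        ]
                    )
                )
    written.append(_write_text(out_dir / "functional_long.tsv", long_lines))

    edge_lines = ["source\ttarget\tweight"]
    for ko in frame.index:
        label = f"{ko} {frame.at[ko, 'description']}"
        for s in samples:
            v = float(frame.at[ko, s])
            if v:
                edge_lines.append("\t".join([s, label, fmt(v)]))
    written.append(_write_text(out_dir / "functional_edges.tsv", edge_lines))

    if annotated.all_paths:
        side_lines = ["\t".join(["ID", "levelA", "levelB", "levelC"])]
        for ko, paths in annotated.all_paths.items():
            for a, b, c in paths:
                side_lines.append("\t".join([str(ko), a, b, c]))
        written.append(_write_text(out_dir / "functional_paths.tsv", side_lines))
    return written
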