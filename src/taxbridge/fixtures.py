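"""Synthetic dataset generator with known ground truth.

Emulates every input the pipeline accepts — an abundance table in any of
the three upstream dialects, representative FASTA sequences with
controllable record sizes, sample metadata (optionally with disallowed
ID characters), a small KEGG BRITE ``.keg`` hierarchy, and a
Piphillin-style ``.tar`` result archive — and writes a ground-truth
manifest of the values a correct parse must recover.

What it emulates: marker-gene (16S-style) profiles with log-skewed
abundances, lineages drawn from a consistent synthetic taxonomy tree,
and classification gaps at random ranks (``gap_prob``), including the
interior gaps that violate downstream tools' strict-hierarchy rule.
What it does not emulate: sequencing error, chimeras, compositional
correlation between taxa, or any real reference taxonomy.
"""

from __future__ import annotations

import io
import json
import tarfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from .model import N_RANKS, Lineage

PathLike = Union[str, Path]

_KINGDOMS = ("Bacteria", "Archaea")
_PHYLA = ("Proteobacteria", "Firmicutes", "Bacteroidetes", "Actinobacteria", "Euryarchaeota")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults describe the standard study conditions used throughout the
    test suite: a dozen samples, a hundred features, moderate sequencing
    depth, and a 15% chance of a classification gap at each of the five
    lower ranks (top two ranks are always classified, as upstream
    classifiers essentially always resolve them).
    """

    n_samples: int = 12
    n_features: int = 100
    gap_prob: float = 0.15
    seed: int = 0
    dialect: str = "anacapa"  # anacapa | mrdna | qiime2 | qza
    seq_len: int = 250
    mean_depth: int = 5000
    bad_sample_chars: bool = False
    with_keg: bool = True
    with_tar: bool = True


@dataclass
class Fixture:
    """Paths of a generated dataset plus its ground truth."""

    spec: FixtureSpec
    paths: Dict[str, Path]
    ground_truth: dict = field(default_factory=dict)


def _taxon_name(rank_idx: int, key: int) -> str:
    if rank_idx == 0:
        return _KINGDOMS[key % len(_KINGDOMS)]
    if rank_idx == 1:
        return _PHYLA[key % len(_PHYLA)]
    stem = ("Cls", "Ord", "Fam", "Gen", "Sp")[rank_idx - 2]
    return f"{stem}_{key:03d}"


def _random_lineages(rng: np.random.Generator, n: int, gap_prob: float) -> List[Lineage]:
    """Draw lineages from a consistent synthetic tree, then knock out
    random rank slots with probability ``gap_prob`` (ranks 2..6 only)."""
    lineages = []
    for _ in range(n):
        key = 0
        taxa = []
        for r in range(N_RANKS):
            key = key * 3 + int(rng.integers(0, 3))
            taxa.append(_taxon_name(r, key))
        for r in range(2, N_RANKS):
            if rng.random() < gap_prob:
                taxa[r] = None
        lineages.append(Lineage(tuple(taxa)))
    return lineages


def _random_counts(
    rng: np.random.Generator, n_features: int, n_samples: int, mean_depth: int
) -> np.ndarray:
    """Log-skewed per-feature abundances scaled to ~mean_depth per sample."""
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_features)
    counts = np.zeros((n_features, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = base * rng.lognormal(0.0, 0.25, size=n_features)
        p = p / p.sum()
        depth = max(1, int(rng.normal(mean_depth, mean_depth * 0.2)))
        counts[:, j] = rng.multinomial(depth, p)
    return counts


def _sample_ids(spec: FixtureSpec) -> List[str]:
    ids = [f"S{j + 1:02d}" for j in range(spec.n_samples)]
    if spec.bad_sample_chars and ids:
        ids[0] = ids[0].replace("S", "S.")  # e.g. "S.01" — period is disallowed
    return ids


def _lineage_cells(lin: Lineage) -> List[str]:
    # blanks for gaps, as upstream tables leave unclassified slots empty
    return ["" if t is None else t for t in lin.taxa]


def generate_fixture(spec: FixtureSpec, out_dir: PathLike) -> Fixture:
    """Write a complete synthetic dataset and its ground-truth manifest."""
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    lineages = _random_lineages(rng, spec.n_features, spec.gap_prob)
    counts = _random_counts(rng, spec.n_features, spec.n_samples, spec.mean_depth)
    samples = _sample_ids(spec)
    feature_ids = [f"ASV_{i + 1:04d}" for i in range(spec.n_features)]

    # --- abundance table in the requested dialect
    if spec.dialect == "anacapa":
        lines = ["\t".join(["ASV", "sum.taxonomy"] + samples)]
        for i, fid in enumerate(feature_ids):
            tax = ";".join(_lineage_cells(lineages[i]))
            lines.append("\t".join([fid, tax] + [str(v) for v in counts[i]]))
        paths["table"] = _write(out_dir / "anacapa_table.txt", lines)
    elif spec.dialect in ("qiime2", "qza"):
        lines = ["# Constructed from biom file"]
        lines.append("\t".join(["#OTU ID"] + samples))
        for i, fid in enumerate(feature_ids):
            lines.append("\t".join([fid] + [str(v) for v in counts[i]]))
        tax_lines = ["Feature ID\tTaxon\tConfidence"]
        for i, fid in enumerate(feature_ids):
            tax = ";".join(_lineage_cells(lineages[i]))
            tax_lines.append(f"{fid}\t{tax}\t{rng.random():.3f}")
        if spec.dialect == "qiime2":
            paths["table"] = _write(out_dir / "feature-table.tsv", lines)
            paths["taxonomy"] = _write(out_dir / "taxonomy.tsv", tax_lines)
        else:
            qza = out_dir / "feature-table.qza"
            with zipfile.ZipFile(qza, "w") as zf:
                zf.writestr("artifact/data/feature-table.tsv", "\n".join(lines) + "\n")
                zf.writestr("artifact/data/taxonomy.tsv", "\n".join(tax_lines) + "\n")
            paths["table"] = qza
    elif spec.dialect == "mrdna":
        mrdna_paths, species_rows = _write_mrdna(out_dir, lineages, counts, samples)
        paths.update(mrdna_paths)
        # per-rank deliveries merge duplicate species paths, so the parsed
        # feature set is the distinct-path set, not the raw ASV set
        feature_ids = [f"F{str(i).zfill(4)}" for i in range(len(species_rows))]
        lineages = [Lineage.from_labels(list(key)) for key in species_rows]
        counts = np.stack([species_rows[key] for key in species_rows])
    else:
        raise ValueError(f"unknown dialect {spec.dialect!r}")

    # --- representative sequences
    fasta_lines = []
    for fid in feature_ids:
        seq = "".join(rng.choice(list("ACGT"), size=spec.seq_len))
        fasta_lines.append(f">{fid}")
        fasta_lines.append(seq)
    paths["fasta"] = _write(out_dir / "rep_seqs.fasta", fasta_lines)

    # --- metadata
    groups = ["GroupA" if j < spec.n_samples / 2 else "GroupB" for j in range(spec.n_samples)]
    meta_lines = ["\t".join(["sample_id", "group", "elevation_m"])]
    for sid, g in zip(samples, groups):
        meta_lines.append("\t".join([sid, g, str(int(rng.integers(10, 900)))]))
    paths["metadata"] = _write(out_dir / "metadata.txt", meta_lines)

    # --- KEGG BRITE hierarchy fixture
    ko_ids = [f"K{i:05d}" for i in range(1, 7)]
    if spec.with_keg:
        keg_lines = [
            "+D\tKO",
            "#DEFINITION  Synthetic KO hierarchy fixture",
            "A09100 Metabolism",
            "B  09101 Carbohydrate metabolism",
            "C    00010 Glycolysis / Gluconeogenesis [PATH:ko00010]",
            "D      K00001  E1.1.1.1, adh; alcohol dehydrogenase [EC:1.1.1.1]",
            "D      K00002  AKR1A1, adh; alcohol dehydrogenase (NADP+) [EC:1.1.1.2]",
            "C    00020 Citrate cycle (TCA cycle) [PATH:ko00020]",
            "D      K00001  E1.1.1.1, adh; alcohol dehydrogenase [EC:1.1.1.1]",
            "D      K00003  hom; homoserine dehydrogenase [EC:1.1.1.3]",
            "B  09102 Energy metabolism",
            "C    00190 Oxidative phosphorylation [PATH:ko00190]",
            "D      K00004  BDH, butB; (R,R)-butanediol dehydrogenase [EC:1.1.1.4]",
            "D      K00005  gldA; glycerol dehydrogenase [EC:1.1.1.6]",
            "A09120 Genetic Information Processing",
            "B  09121 Transcription",
            "C    03020 RNA polymerase [PATH:ko03020]",
            "D      K00006  GPD1; glycerol-3-phosphate dehydrogenase [EC:1.1.1.8]",
        ]
        paths["keg"] = _write(out_dir / "brite_ko.keg", keg_lines)

    # --- Piphillin-style result archive
    ko_matrix = None
    if spec.with_tar:
        ko_matrix = np.round(
            rng.lognormal(3.0, 1.0, size=(len(ko_ids), spec.n_samples)), 2
        )
        ko_lines = [",".join(["KO"] + samples)]
        for i, ko in enumerate(ko_ids):
            ko_lines.append(",".join([ko] + [f"{v:g}" for v in ko_matrix[i]]))
        pw_ids = ["ko00010", "ko00020", "ko00190"]
        pw_matrix = np.round(rng.lognormal(4.0, 0.8, size=(len(pw_ids), spec.n_samples)), 2)
        pw_lines = [",".join(["pathway"] + samples)]
        for i, pw in enumerate(pw_ids):
            pw_lines.append(",".join([pw] + [f"{v:g}" for v in pw_matrix[i]]))
        tar_path = out_dir / "piphillin_results.tar"
        with tarfile.open(tar_path, "w") as tf:
            for arcname, lines in (
                ("results/ko_abund_table_unnorm.csv", ko_lines),
                ("results/pathway_abund_table_unnorm.csv", pw_lines),
            ):
                data = ("\n".join(lines) + "\n").encode("utf-8")
                info = tarfile.TarInfo(arcname)
                info.size = len(data)
                info.mtime = 0  # fixed metadata keeps generation byte-identical
                tf.addfile(info, io.BytesIO(data))
        paths["tar"] = tar_path

    ground_truth = {
        "n_features": len(feature_ids),
        "n_samples": spec.n_samples,
        "sample_ids": samples,
        "feature_ids": feature_ids,
        "grand_total": int(counts.sum()),
        "sample_totals": {s: int(counts[:, j].sum()) for j, s in enumerate(samples)},
        "n_strict_lineages": sum(l.is_strict() for l in lineages),
        "lineages": [list(l.labels()) for l in lineages],
        "ko_grand_total": None if ko_matrix is None else float(ko_matrix.sum()),
    }
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(ground_truth, indent=1), encoding="utf-8")
    paths["ground_truth"] = gt_path
    return Fixture(spec, paths, ground_truth)


def _write(path: Path, lines: List[str]) -> Path:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def _write_mrdna(
    out_dir: Path,
    lineages: List[Lineage],
    counts: np.ndarray,
    samples: List[str],
) -> Dict[str, Path]:
    """Per-rank tables: counts summed per distinct taxon path prefix.

    The deepest (species) file carries a semicolon-joined ``taxonomy``
    path column, as commercial deliveries usually do; shallower files
    hold one row per distinct prefix at that rank.
    """
    from .model import RANKS_MRDNA

    paths = {}
    species_rows: Dict[tuple, np.ndarray] = {}
    for r, rank_name in enumerate(RANKS_MRDNA):
        agg: Dict[tuple, np.ndarray] = {}
        order: List[tuple] = []
        for i, lin in enumerate(lineages):
            key = lin.labels()[: r + 1]
            if key not in agg:
                agg[key] = np.zeros(counts.shape[1], dtype=np.int64)
                order.append(key)
            agg[key] += counts[i]
        if rank_name == "species":
            species_rows = {key: agg[key] for key in order}
            lines = ["\t".join([rank_name, "taxonomy"] + samples)]
            for key in order:
                lines.append(
                    "\t".join([key[-1], ";".join(key)] + [str(v) for v in agg[key]])
                )
        else:
            lines = ["\t".join([rank_name] + samples)]
            for key in order:
                lines.append("\t".join([key[-1]] + [str(v) for v in agg[key]]))
        paths[f"mrdna_{rank_name}"] = _write(out_dir / f"mrdna_{rank_name}.txt", lines)
    paths["table"] = paths["mrdna_species"]
    return paths, species_rows
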