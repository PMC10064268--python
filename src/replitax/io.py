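"""Readers, writers, and shared CLI/pipeline plumbing.

Sequences come and go as FASTA (Biopython), gene annotations as GFF3 or a
5-column TSV (gene_id, replicon_id, start, end, strand), matrices as TSV,
and trees as newick. Proteins are translated from CDS coordinates with the
bacterial code (translation table 11) when no protein FASTA is supplied.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .model import (
    GeneRecord,
    GenomeAssembly,
    ProteinRecord,
    Replicon,
    ValidationError,
)

__all__ = [
    "read_assembly",
    "write_assembly_fasta",
    "read_fasta",
    "write_fasta",
    "write_matrix",
    "read_matrix",
    "build_nj_tree",
    "load_config",
    "stage_log",
]

logger = logging.getLogger("replitax")


class FastaParseError(ValueError):
    """Malformed FASTA; message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs, validating basic structure."""
    path = Path(path)
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = line
                break
        if first is None:
            return []
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}:{lineno}: expected '>' header, got {first[:30]!r}"
            )
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append((rec.id, seq))
    return records


def write_fasta(
    records: list[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables

_TSV_COLUMNS = ["gene_id", "replicon_id", "start", "end", "strand"]


def _read_features_tsv(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    cols = [c.lower() for c in df.columns]
    if cols[:5] != _TSV_COLUMNS:
        # headerless variant
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str, 1: str})
        if df.shape[1] < 5:
            raise ValidationError(
                f"{path}: feature TSV needs 5 columns {_TSV_COLUMNS}"
            )
        df.columns = _TSV_COLUMNS + [f"extra{i}" for i in range(df.shape[1] - 5)]
    return [
        GeneRecord(
            gene_id=str(r.gene_id),
            replicon_id=str(r.replicon_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]


def _read_features_gff3(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    n_auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValidationError(
                    f"{path}:{lineno}: GFF3 line has {len(parts)} columns"
                )
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("CDS", "gene"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("locus_tag")
            if gid is None:
                n_auto += 1
                gid = f"gene_{n_auto:05d}"
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    replicon_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    product=attr.get("product", ""),
                )
            )
    # prefer CDS records when both gene and CDS share an ID
    seen: dict[str, GeneRecord] = {}
    for g in genes:
        seen[g.gene_id] = g
    return list(seen.values())


def read_features(path: str | Path) -> list[GeneRecord]:
    """Read GFF3 or the 5-column TSV dialect, sniffing the format."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff-version") or head.count("\t") == 8:
        return _read_features_gff3(path)
    return _read_features_tsv(path)


def translate_cds(replicon_seq: str, gene: GeneRecord) -> str:
    """Translate a CDS with the bacterial code (NCBI table 11)."""
    lo, hi = gene.slice
    cds = replicon_seq[lo:hi]
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return str(Seq(cds).translate(table=11)).rstrip("*")


def read_assembly(
    fasta_path: str | Path,
    features_path: str | Path | None = None,
    proteins_path: str | Path | None = None,
    strain: str | None = None,
) -> GenomeAssembly:
    """Load one strain: replicons in file order, genes, and proteome.

    When ``proteins_path`` is absent but features are given, proteins are
    translated from the CDS coordinates (table 11).
    """
    fasta_path = Path(fasta_path)
    records = read_fasta(fasta_path)
    ids = [rid for rid, _ in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{fasta_path}: duplicate replicon ids {dupes}")
    replicons = [Replicon(id=rid, sequence=seq) for rid, seq in records]

    genes: list[GeneRecord] = []
    proteome: list[ProteinRecord] = []
    if features_path is not None:
        genes = read_features(features_path)
    if proteins_path is not None:
        proteome = [
            ProteinRecord(gene_id=rid, aa_sequence=seq)
            for rid, seq in read_fasta(proteins_path)
        ]
    elif genes:
        by_id = {r.id: r.sequence for r in replicons}
        for g in genes:
            if g.replicon_id in by_id:
                aa = translate_cds(by_id[g.replicon_id], g)
                if aa:
                    proteome.append(ProteinRecord(gene_id=g.gene_id, aa_sequence=aa))
    return GenomeAssembly(
        strain=strain or fasta_path.stem,
        replicons=replicons,
        genes=genes,
        proteome=proteome,
    )


def write_assembly_fasta(assembly: GenomeAssembly, path: str | Path) -> None:
    write_fasta([(r.id, r.sequence) for r in assembly.replicons], path)


# ---------------------------------------------------------------------------
# Matrices

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled square matrix as TSV (round-trips to 1e-9)."""
    if list(matrix.index) != list(matrix.columns):
        raise ValidationError("matrix row and column labels differ")
    matrix.to_csv(path, sep="\t", float_format="%.12g", index_label="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return df


# ---------------------------------------------------------------------------
# Neighbor joining

def build_nj_tree(matrix: pd.DataFrame) -> str:
    """Unrooted NJ tree (newick) from a labeled distance matrix.

    Negative branch lengths from the standard NJ formulas are clamped to 0.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    labels = [str(x) for x in matrix.index]
    if len(labels) < 3:
        raise ValidationError("NJ needs at least 3 taxa")
    values = np.asarray(matrix.values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValidationError("distance matrix is not symmetric")
    if np.any(values < 0) or np.any(np.diag(values) != 0):
        raise ValidationError("distances must be non-negative with zero diagonal")
    tree = nj(DistanceMatrix(values, labels), neg_as_zero=True)
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Config + logging

def load_config(path: str | Path) -> dict[str, str]:
    """Plain-text ``key = value`` config; '#' starts a comment."""
    conf: dict[str, str] = {}
    for lineno, line in enumerate(open(path), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, val = line.split("=", 1)
        conf[key.strip()] = val.strip()
    return conf


def _digest(obj) -> str:
    if isinstance(obj, (str, Path)) and Path(obj).is_file():
        h = hashlib.md5()
        with open(obj, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()[:12]
    return hashlib.md5(repr(obj).encode()).hexdigest()[:12]


@contextmanager
def stage_log(stage: str, inputs=None, **params):
    """One log line per pipeline stage: input digest, params, elapsed."""
    t0 = time.perf_counter()
    yield
    elapsed = time.perf_counter() - t0
    digest = _digest(inputs) if inputs is not None else "-"
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s input=%s %s elapsed=%.2fs", stage, digest, kv, elapsed)
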