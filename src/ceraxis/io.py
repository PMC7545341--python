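"""File formats: expression/design TSV, FASTA, result tables, provenance.

All tabular outputs are TSV with a ``#``-prefixed provenance header
(package version, config hash, seed) so every artifact records how it was
produced; readers skip those lines.  FASTA goes through Biopython.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .containers import ExpressionMatrix, SequenceSet, validate_design
from .targets import normalize_rna


def provenance_header(config_hash: str = "", seed: int | None = None) -> str:
    lines = [f"# ceraxis {__version__}"]
    if config_hash:
        lines.append(f"# config_sha256: {config_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return "\n".join(lines) + "\n"


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def write_tsv(df: pd.DataFrame, path, header: str = "", index: bool = False) -> None:
    path = Path(path)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, lineterminator="\n")
    path.write_text(header + buf.getvalue())


def read_expression_table(path) -> ExpressionMatrix:
    """Read a features x samples TSV: columns ``feature``, ``rna_class``,
    then one column per sample.  Lines starting with ``#`` are provenance."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.columns[0] != "feature" or (len(df.columns) < 3 or df.columns[1] != "rna_class"):
        raise ValueError(
            f"{path}: expected columns 'feature', 'rna_class', <samples...>; "
            f"got {list(df.columns)[:3]}"
        )
    dup = df["feature"][df["feature"].duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2  # header + 1-based
        raise ValueError(f"{path}: duplicate feature id {dup.iloc[0]!r} (line {line})")
    classes = df["rna_class"].unique()
    if len(classes) != 1:
        raise ValueError(f"{path}: expected a single RNA class, found {list(classes)}")
    values = df.drop(columns=["rna_class"]).set_index("feature")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from None
    values.index.name = None
    return ExpressionMatrix(values, str(classes[0]))


def write_expression_table(matrix: ExpressionMatrix, path, header: str = "") -> None:
    df = matrix.values.copy()
    df.insert(0, "rna_class", matrix.rna_class)
    df.insert(0, "feature", df.index)
    write_tsv(df, path, header=header, index=False)


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: expected columns 'sample', 'group'")
    design = pd.Series(df["group"].values, index=df["sample"].values, name="group")
    return validate_design(design)


def write_design(design: pd.Series, path, header: str = "") -> None:
    df = pd.DataFrame({"sample": design.index, "group": design.values})
    write_tsv(df, path, header=header)


def read_fasta(path) -> SequenceSet:
    """Standard FASTA; sequences uppercased with T mapped to U."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        records[rec.id] = normalize_rna(seq, f"record {rec.id!r}")
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=fid, description="") for fid, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_json(obj, path, extra_provenance: dict | None = None) -> None:
    payload = dict(obj)
    if extra_provenance:
        payload["_provenance"] = extra_provenance
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.astype(float)


def write_ct_table(ct: pd.DataFrame, path, header: str = "") -> None:
    df = ct.copy()
    df.insert(0, "sample", df.index)
    write_tsv(df, path, header=header)
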