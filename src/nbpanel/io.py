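"""Readers and writers for the pipeline's file formats.

Sequence input is FASTA or GenBank flat file (via Biopython); trees are
Newick (via scikit-bio); plates and reports are long-format CSV/TSV with
documented columns.  Every report written here starts with ``#`` comment
headers recording the tool version, a config hash and the seed, and is
otherwise byte-stable given the seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from skbio.tree import TreeNode

from . import __version__
from .repertoire import NanobodyRecord

__all__ = [
    "read_sequences",
    "read_plate_csv",
    "write_newick",
    "read_newick",
    "write_report",
    "config_hash",
]


def read_sequences(path: str | Path, format: str = "fasta") -> list[NanobodyRecord]:
    """Read clone nucleotide sequences from FASTA or GenBank flat file.

    Records are returned untranslated (id + nt sequence); annotation
    happens downstream.  Malformed or empty files raise a ``ValueError``
    naming the file / offending entry.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"format must be 'fasta' or 'genbank', got {format!r}")
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), format):
            if len(rec.seq) == 0:
                raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append(NanobodyRecord(clone_id=rec.id, nt_seq=str(rec.seq).upper()))
    except ValueError:
        raise
    except Exception as exc:  # Biopython raises various parse errors
        raise ValueError(f"{path}: malformed {format} input ({exc})") from exc
    if not records:
        raise ValueError(f"{path}: no {format} records found")
    return records


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format plate CSV, skipping ``#`` comment headers."""
    df = pd.read_csv(path, comment="#")
    missing = {"concentration", "a450"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing plate columns {sorted(missing)}")
    return df


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed: int | None, config: dict | None) -> list[str]:
    lines = [f"# nbpanel {__version__}"]
    if config is not None:
        lines.append(f"# config_hash {config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    return lines


def write_report(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    config: dict | None = None,
    index: bool = False,
) -> None:
    """Write a TSV report with provenance comment headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def write_newick(tree: TreeNode, path: str | Path, *, seed: int | None = None,
                 config: dict | None = None) -> None:
    """Write a tree as single-line Newick (with ``#`` provenance headers)."""
    path = Path(path)
    newick = str(tree).strip()
    if not newick.endswith(";"):
        newick += ";"
    with open(path, "w") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        fh.write(newick + "\n")


def read_newick(path: str | Path) -> TreeNode:
    with open(path) as fh:
        text = "".join(ln for ln in fh if not ln.startswith("#")).strip()
    if not text:
        raise ValueError(f"{path}: no Newick payload")
    return TreeNode.read([text])
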