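"""File-format plumbing: FASTA/FASTQ, gene configs, guide sets, manifests."""

from __future__ import annotations

import gzip
import hashlib
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .grna import GuideRNA
from .templates import GeneTemplate


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path) -> list[str]:
    """Read sequences from FASTA or FASTQ (plain or gzip); qualities dropped."""
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]


def read_guides(path) -> list[GuideRNA]:
    """Read a guide-RNA set from FASTA; description kept as annotation."""
    with _open_text(path) as fh:
        return [
            GuideRNA(rec.id, str(rec.seq), rec.description)
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_reads_fasta(path, reads: list[tuple[str, int]], prefix: str = "read") -> None:
    """Write collapsed (sequence, count) reads expanded to one record per read."""
    def records():
        i = 0
        for seq, n in reads:
            for _ in range(n):
                i += 1
                yield SeqRecord(Seq(seq), id=f"{prefix}.{i}", description="")
    with _open_text(path, "wt") as fh:
        SeqIO.write(records(), fh, "fasta")


def write_reads_fastq(path, reads: list[tuple[str, int]], prefix: str = "read", qual: int = 40) -> None:
    """As :func:`write_reads_fasta` but FASTQ with constant quality."""
    def records():
        i = 0
        for seq, n in reads:
            for _ in range(n):
                i += 1
                rec = SeqRecord(Seq(seq), id=f"{prefix}.{i}", description="")
                rec.letter_annotations["phred_quality"] = [qual] * len(seq)
                yield rec
    with _open_text(path, "wt") as fh:
        SeqIO.write(records(), fh, "fastq")


def _resolve_seq(value: str, base: Path) -> str:
    """A template sequence may be inline or a reference to a FASTA file."""
    if set(value.upper()) <= set("ACGTU"):
        return value
    seqs = read_sequences(base / value)
    if len(seqs) != 1:
        raise ValueError(f"expected exactly one sequence in {value}")
    return seqs[0]


def load_gene_config(path) -> GeneTemplate:
    """Load a gene template from a YAML config.

    Keys: gene_name, pre_edited, fully_edited, flank5, flank3, es_offset.
    pre_edited/fully_edited may be inline sequences or FASTA file names
    relative to the config.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return GeneTemplate(
        gene_name=cfg["gene_name"],
        pre_edited=_resolve_seq(cfg["pre_edited"], path.parent),
        fully_edited=_resolve_seq(cfg["fully_edited"], path.parent),
        flank5=cfg["flank5"],
        flank3=cfg["flank3"],
        es_offset=int(cfg.get("es_offset", 1)),
    )


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, inputs=(), seed=None, parameters=None) -> dict:
    """Write a run manifest sufficient to reproduce the outputs byte-for-byte."""
    from . import __version__

    manifest = {
        "software": {"name": "uindel", "version": __version__},
        "seed": seed,
        "parameters": parameters or {},
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
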