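"""FASTA / BED / GTF readers and writers used across the pipeline.

FASTA goes through Bio.SeqIO; interval formats are written directly in
their standard dialects (BED 0-based half-open, GTF 1-based inclusive).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def write_bed(rows, path) -> None:
    """rows: iterables of (contig, start, end, name, score, strand), 0-based half-open."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed(path) -> list[tuple[str, int, int, str, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            while len(f) < 6:
                f.append(".")
            out.append((f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]))
    return out


def write_gtf(rows, path, source: str = "hervtrace") -> None:
    """rows: (contig, feature, start0, end0, strand, attributes-dict); written 1-based."""
    with open(path, "w") as fh:
        for contig, feature, start, end, strand, attrs in rows:
            attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            fh.write(f"{contig}\t{source}\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_str}\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def data_path(name: str) -> Path:
    """Path of a packaged data file."""
    return Path(__file__).parent / "data" / name
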