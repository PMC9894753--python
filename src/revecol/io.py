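"""Readers and writers for the standard formats the pipeline touches."""
from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import encode


def read_fasta(path) -> dict[str, np.ndarray]:
    """FASTA -> dict of encoded sequences (insertion order preserved)."""
    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    from ._seq import decode

    with open(path, "w") as fh:
        for name, arr in seqs.items():
            s = arr if isinstance(arr, str) else decode(np.asarray(arr, dtype=np.uint8))
            fh.write(f">{name}\n")
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def read_gff3(path) -> pd.DataFrame:
    """Gene records from a GFF3 file -> genome, gene_id, start, end, strand
    (1-based inclusive, as in the file)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene_id = attrs.get("locus_tag") or attrs.get("ID", "")
            rows.append((f[0], gene_id, int(f[3]), int(f[4]), f[6]))
    return pd.DataFrame(rows, columns=["genome", "gene_id", "start", "end", "strand"])


def read_fastq_array(path):
    """FASTQ of equal-length reads -> (n x L uint8 array, names). Raises on
    mixed lengths (the dense pipeline assumes Illumina-like reads)."""
    names, seqs = [], []
    with open(path) as fh:
        while True:
            hdr = fh.readline()
            if not hdr:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            names.append(hdr[1:].strip().split()[0])
            seqs.append(encode(seq))
    if not seqs:
        raise ValueError("empty FASTQ")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"reads have mixed lengths {sorted(lengths)}; expected uniform")
    return np.stack(seqs), names
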