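"""File I/O: FASTA and NEXUS alignments, Newick trees.

All round trips are lossless: alignments are strict ACGT matrices and
Newick branch lengths are written with 12 significant digits.
"""

from __future__ import annotations

from pathlib import Path

from phyloppc.simulate import Alignment
from phyloppc.trees import PhyloTree

__all__ = ["write_fasta", "read_fasta", "write_nexus", "read_nexus",
           "write_newick", "read_newick"]


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(aln.taxa):
            fh.write(f">{name}\n{aln.sequence(i)}\n")


def read_fasta(path) -> Alignment:
    from Bio import SeqIO

    taxa, seqs = [], []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq))
    except Exception as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    if not taxa:
        raise ValueError(f"no sequences found in {path}")
    try:
        return Alignment.from_sequences(taxa, seqs)
    except ValueError as exc:
        raise ValueError(_locate_bad_char(path, str(exc))) from exc


def _locate_bad_char(path, message: str) -> str:
    """Best-effort line number for an invalid alignment character."""
    allowed = set("ACGTacgt")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(">"):
                continue
            if any(ch not in allowed for ch in s):
                return f"{message} (file {path}, line {lineno})"
    return f"{message} (file {path})"


def write_nexus(aln: Alignment, path, interleave: bool = False,
                block: int = 60) -> None:
    """Write a NEXUS DATA block, sequential or interleaved."""
    width = max(len(t) for t in aln.taxa) + 2
    lines = ["#NEXUS", "", "BEGIN DATA;",
             f"    DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.n_sites};",
             "    FORMAT DATATYPE=DNA MISSING=? GAP=-"
             + (" INTERLEAVE=YES" if interleave else "") + ";",
             "    MATRIX"]
    if interleave:
        for start in range(0, aln.n_sites, block):
            for i, name in enumerate(aln.taxa):
                chunk = aln.sequence(i)[start:start + block]
                lines.append(f"    {name:<{width}}{chunk}")
            lines.append("")
    else:
        for i, name in enumerate(aln.taxa):
            lines.append(f"    {name:<{width}}{aln.sequence(i)}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus(path) -> Alignment:
    from Bio.Nexus import Nexus

    try:
        nex = Nexus.Nexus(str(path))
    except Exception as exc:
        raise ValueError(f"malformed NEXUS {path}: {exc}") from exc
    taxa = list(nex.taxlabels)
    seqs = [str(nex.matrix[t]) for t in taxa]
    try:
        return Alignment.from_sequences(taxa, seqs)
    except ValueError as exc:
        raise ValueError(_locate_bad_char(path, str(exc))) from exc


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())
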