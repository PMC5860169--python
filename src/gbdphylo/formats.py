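"""Readers and writers for every external format the pipeline touches.

FASTA genomes (one file per genome, id = file name stem), 12-column tabular
local-alignment hits, relaxed square PHYLIP distance matrices (full-length
whitespace-separated labels), Newick trees with integer support values as
internal node labels, and TSV taxonomy / host tables.
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, UsageError, ValidationError

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino_acid"

# IUPAC DNA incl. ambiguity codes; proteins: the 20 standard residues plus X.
_DNA_LETTERS = frozenset("ACGTRYSWKMBDHVN")
_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class GenomeRecord:
    """One genome: a DNA sequence (possibly multi-record) or a proteome.

    ``sequences`` is an ordered list of (record_id, residue string);
    ``n_proteins`` is the companion protein count used by de-duplication.
    """

    genome_id: str
    sequences: list[tuple[str, str]]
    seq_type: str
    n_proteins: int = 0

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def validate(self) -> None:
        if not self.sequences or self.total_length == 0:
            raise ValidationError(f"genome {self.genome_id!r} has no residues")
        letters = _DNA_LETTERS if self.seq_type == NUCLEOTIDE else _AA_LETTERS
        for rid, seq in self.sequences:
            for pos, ch in enumerate(seq.upper()):
                if ch not in letters:
                    raise ValidationError(
                        f"genome {self.genome_id!r}, record {rid!r}: illegal "
                        f"{self.seq_type} residue {ch!r} at position {pos}"
                    )


def read_fasta(path: str | Path, seq_type: str = NUCLEOTIDE) -> GenomeRecord:
    """Read one genome FASTA file; genome id is the file name stem."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    genome = GenomeRecord(
        genome_id=path.stem,
        sequences=records,
        seq_type=seq_type,
        n_proteins=len(records) if seq_type == AMINO_ACID else 0,
    )
    genome.validate()
    return genome


def write_fasta(genome: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in genome.sequences:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment_tab(path: str | Path) -> list:
    """Parse 12-column tabular hits (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore).

    Identities are reconstructed as round(pident/100 * length).  Query
    coordinates (1-based inclusive on input) become 0-based half-open;
    subject coordinates with sstart > send mark the reverse strand and are
    normalized to (min-1, max) with strand "-".
    """
    from .alignment import HSP  # local import to avoid a module cycle

    hsps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            try:
                qid, sid = cols[0], cols[1]
                pident = float(cols[2])
                length = int(cols[3])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bit = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})")
            strand = "+" if sstart <= send else "-"
            s_lo, s_hi = min(sstart, send), max(sstart, send)
            hsps.append(
                HSP(
                    query_id=qid,
                    subject_id=sid,
                    q_start=qstart - 1,
                    q_end=qend,
                    s_start=s_lo - 1,
                    s_end=s_hi,
                    strand=strand,
                    length=length,
                    identities=float(round(pident / 100.0 * length)),
                    raw_score=int(round(bit)),
                    bit_score=bit,
                    evalue=evalue,
                )
            )
    return hsps


def write_alignment_tab(hsps: Iterable, path: str | Path) -> None:
    """Serialize HSPs back to the 12-column tabular dialect."""
    with open(path, "w") as fh:
        for h in hsps:
            pident = 100.0 * h.identities / h.length if h.length else 0.0
            if h.strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{pident:.3f}", h.length,
                        0, 0, h.q_start + 1, h.q_end, ss, se,
                        f"{h.evalue:.3g}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def write_phylip_matrix(labels: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    """Relaxed square PHYLIP: full-length labels, whitespace separated."""
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if values.shape != (n, n):
        raise ValidationError(f"matrix shape {values.shape} does not match {n} labels")
    if np.abs(values - values.T).max(initial=0.0) > 1e-9:
        raise ValidationError("matrix is asymmetric beyond 1e-9")
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for lab, row in zip(labels, values):
            fh.write(lab + "\t" + "\t".join(f"{v:.9f}" for v in row) + "\n")


def read_phylip_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise FormatError(f"{path}: empty file")
        try:
            n = int(header[0])
        except ValueError:
            raise FormatError(f"{path}: first line must be the taxon count")
        labels, rows = [], []
        for lineno in range(n):
            parts = fh.readline().split()
            if len(parts) != n + 1:
                raise FormatError(
                    f"{path}: row {lineno + 1} has {len(parts) - 1} values, expected {n}"
                )
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return labels, np.array(rows)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick; integer branch supports appear as internal node labels."""
    s = tree_to_newick(tree)
    with open(path, "w") as fh:
        fh.write(s + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        support = getattr(node, "support", None)
        if support is not None:
            node.label = str(int(support))
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=False,
        unquoted_underscores=True,
    ).strip()


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse Newick from a path or a literal string; internal integer labels
    become per-node ``support`` attributes."""
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "(" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"Newick parse error: {exc}")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            if re.fullmatch(r"\d+", node.label):
                node.support = int(node.label)
    return tree


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """TSV with header: genome_id, species, genus, subfamily, family.

    Empty strings mark unassigned ranks.  Genome ids must be unique and every
    non-empty species must map to a single (genus, subfamily, family) triple.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["genome_id", "species", "genus", "subfamily", "family"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing taxonomy columns {missing}")
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValidationError(f"duplicate genome ids in taxonomy: {dups}")
    nonempty = df[df["species"] != ""]
    grouped = nonempty.groupby("species")[["genus", "subfamily", "family"]].nunique()
    bad = grouped[(grouped > 1).any(axis=1)].index.tolist()
    if bad:
        raise ValidationError(f"species mapped to multiple higher taxa: {bad}")
    return df[required]


def read_host_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "genome_id" not in df.columns or "host" not in df.columns:
        raise FormatError(f"{path}: host table needs 'genome_id' and 'host' columns")
    return df[["genome_id", "host"]]


def deduplicate_genomes(records: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """Collapse genomes with identical nucleotide sequence (MD5 of the
    concatenated, uppercased sequence); among duplicates keep the one with
    the most protein sequences, ties broken by smallest genome id.
    Output preserves the input order of the survivors."""
    by_digest: dict[str, GenomeRecord] = {}
    order: list[str] = []
    for rec in records:
        digest = hashlib.md5(
            "".join(s.upper() for _, s in rec.sequences).encode()
        ).hexdigest()
        cur = by_digest.get(digest)
        if cur is None:
            by_digest[digest] = rec
            order.append(digest)
        elif rec.n_proteins > cur.n_proteins or (
            rec.n_proteins == cur.n_proteins and rec.genome_id < cur.genome_id
        ):
            by_digest[digest] = rec
    return [by_digest[d] for d in order]
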