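"""Readers/writers for the external formats and the shared record types.

Formats handled here: FASTA (promoter sequences, via Bio.SeqIO), Newick
(guide tree, via dendropy), MEME minimal motif format (known-TFBS database
and discovered-motif export), BedGraph/BigWig (positional histogram track)
and TSV (distance matrix cache).

Coordinates are 0-based half-open everywhere; any 1-based display is a
presentation concern of downstream viewers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file violated its declared format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRecord:
    """One orthologous promoter sequence with its taxon identity.

    ``sequence`` is uppercase DNA over {A,C,G,T,N}; ``source_offset`` is the
    0-based genomic start when known; exactly one record per analysis set
    carries ``is_target``.
    """

    id: str
    sequence: str
    taxon: str = ""
    source_offset: int | None = None
    is_target: bool = False

    def __post_init__(self) -> None:
        if not self.taxon:
            self.taxon = self.id


@dataclass
class GuideTree:
    """A rooted/unrooted tree with branch lengths; leaves match promoter ids."""

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass
class DatabaseMotif:
    name: str
    pwm: np.ndarray  # L x 4, rows sum to 1
    nsites: int = 20

    @property
    def width(self) -> int:
        return self.pwm.shape[0]


@dataclass
class MotifDatabase:
    """Ordered collection of known-TFBS PWMs with a shared background."""

    motifs: list[DatabaseMotif]
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def names(self) -> list[str]:
        return [m.name for m in self.motifs]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read promoters from FASTA; empty file yields an empty list.

    The header token before the first whitespace becomes the record id; a
    second token, when present, is kept as the taxon label. Sequences are
    uppercased and validated against {A,C,G,T,N}.
    """
    records: list[PromoterRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in VALID_BASES:
                raise FormatError(
                    f"record '{rec.id}': invalid character {ch!r} at position {pos}"
                )
        if not seq:
            raise FormatError(f"record '{rec.id}': empty sequence")
        desc_tokens = rec.description.split()
        taxon = desc_tokens[1] if len(desc_tokens) > 1 else rec.id
        records.append(PromoterRecord(id=rec.id, sequence=seq, taxon=taxon))
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    seqrecs = []
    for r in records:
        desc = r.taxon if r.taxon != r.id else ""
        seqrecs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> GuideTree:
    """Read a guide tree; every edge must carry a branch length.

    Distances are the method's input, so a missing branch length is an
    error, as are duplicate leaf labels.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error in {path}: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # the root's own edge may be lengthless
        if edge.length is None:
            raise FormatError(
                "branch length missing on an edge; distances require a fully "
                "lengthed tree"
            )
        if edge.length < 0:
            raise FormatError("negative branch length")
    return GuideTree(tree=tree)


def write_newick(gt: GuideTree, path: str | Path) -> None:
    gt.tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# MEME minimal motif format
#
# Parsed by hand: the round-trip must preserve letter probabilities exactly
# as printed (count-based reconstruction would quantize them), and the
# format-contract errors below need precise positions.

_MEME_HEADER = re.compile(r"MEME\s+version", re.IGNORECASE)


def read_meme_motifs(path: str | Path) -> MotifDatabase:
    """Parse a MEME minimal-format motif file into a :class:`MotifDatabase`.

    Background frequencies are taken from the file's "Background letter
    frequencies" block when present, else uniform 0.25. Each probability row
    must sum to 1 within 1e-3; motif names must be unique; an ALPHABET line
    is required.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not any(_MEME_HEADER.match(ln) for ln in lines[:5]):
        raise FormatError(f"{path}: missing 'MEME version' header")

    alphabet = None
    background = None
    motifs: list[DatabaseMotif] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alphabet = line.split("=", 1)[-1].strip() if "=" in line else line.split()[-1]
        elif line.startswith("Background letter frequencies"):
            i += 1
            freq_tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith(("MOTIF", "ALPHABET")):
                freq_tokens.extend(lines[i].split())
                i += 1
            pairs = dict(zip(freq_tokens[::2], freq_tokens[1::2]))
            try:
                background = np.array([float(pairs[b]) for b in ALPHABET])
            except KeyError as exc:
                raise FormatError(f"{path}: background frequencies incomplete") from exc
            continue
        elif line.startswith("MOTIF"):
            tokens = line.split()
            if len(tokens) < 2:
                raise FormatError(f"{path}: MOTIF line without a name")
            name = tokens[1]
            i += 1
            # find the letter-probability matrix header
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif '{name}' has no probability matrix")
                i += 1
            if i >= n:
                raise FormatError(f"{path}: motif '{name}' has no probability matrix")
            header = lines[i]
            attrs = dict(re.findall(r"(\w+)=\s*(\S+)", header))
            width = int(attrs["w"]) if "w" in attrs else None
            nsites = int(float(attrs.get("nsites", 20)))
            i += 1
            rows: list[list[float]] = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in stripped.split()])
                i += 1
            mat = np.array(rows, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != 4:
                raise FormatError(f"{path}: motif '{name}' matrix is not L x 4")
            if width is not None and mat.shape[0] != width:
                raise FormatError(
                    f"{path}: motif '{name}' declares w={width} but has {mat.shape[0]} rows"
                )
            bad = np.flatnonzero(np.abs(mat.sum(axis=1) - 1.0) > 1e-3)
            if bad.size:
                raise FormatError(
                    f"{path}: motif '{name}' row {bad[0]} sums to "
                    f"{mat[bad[0]].sum():.4f}, not 1"
                )
            motifs.append(DatabaseMotif(name=name, pwm=mat, nsites=nsites))
            continue
        i += 1

    if alphabet is None:
        raise FormatError(f"{path}: missing ALPHABET line")
    names = [m.name for m in motifs]
    dupes = {x for x in names if names.count(x) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate motif names: {sorted(dupes)}")
    if background is None:
        background = np.full(4, 0.25)
    return MotifDatabase(motifs=motifs, background=background)


def write_meme_motifs(db: MotifDatabase, path: str | Path) -> None:
    """Write motifs in MEME minimal format (probabilities at full precision)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, db.background)) + "\n\n"
        )
        for m in db.motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.nsites} E= 0\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BedGraph / BigWig


def _iter_runs(counts: Sequence[int]):
    """Yield (start, end, value) maximal runs of equal value."""
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            yield start, i, counts[start]
            start = i


def write_bedgraph(
    histogram, path: str | Path, chrom: str = "promoter", chrom_offset: int = 0
) -> None:
    """Write the per-position run-support counts as a BedGraph track.

    Intervals are 0-based half-open; runs of equal value are merged into one
    line and zero runs are omitted. ``chrom_offset`` shifts promoter-relative
    positions to genomic ones when the promoter's genomic start is known.
    """
    counts = np.asarray(histogram.counts)
    if counts.size == 0:
        raise ValueError("zero-length histogram")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{chrom}_motif_support"\n')
        for start, end, value in _iter_runs(counts.tolist()):
            if value == 0:
                continue
            fh.write(f"{chrom}\t{start + chrom_offset}\t{end + chrom_offset}\t{value}\n")


def write_bigwig(
    histogram,
    path: str | Path,
    chrom: str = "promoter",
    chrom_offset: int = 0,
    chrom_length: int | None = None,
) -> bool:
    """Write a BigWig track if a writer backend is installed.

    Returns True when written, False when no backend is available (BedGraph
    remains the canonical artifact either way).
    """
    try:
        import pyBigWig
    except ImportError:
        return False
    counts = np.asarray(histogram.counts)
    if counts.size == 0:
        raise ValueError("zero-length histogram")
    length = chrom_length if chrom_length is not None else chrom_offset + counts.size
    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader([(chrom, length)])
        starts, ends, values = [], [], []
        for start, end, value in _iter_runs(counts.tolist()):
            if value == 0:
                continue
            starts.append(start + chrom_offset)
            ends.append(end + chrom_offset)
            values.append(float(value))
        if starts:
            bw.addEntries(
                [chrom] * len(starts), starts, ends=ends, values=values
            )
    finally:
        bw.close()
    return True


def find_target(records: Sequence[PromoterRecord]) -> PromoterRecord:
    """Return the unique target record, erroring on zero or several."""
    targets = [r for r in records if r.is_target]
    if len(targets) != 1:
        raise ValueError(
            f"expected exactly one target promoter, found {len(targets)}"
        )
    return targets[0]
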