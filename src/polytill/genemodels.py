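"""Gene models for homeologous loci and their coordinate systems.

A :class:`GeneModel` holds one gene copy of a homeologous pair as a plus-strand
locus sequence together with its CDS structure.  Three coordinate systems are
used throughout the package:

``locus``
    1-based position within ``locus_seq``.
``anchored`` (ATG-anchored)
    1-based from the A of the start codon; negative values count upstream
    bases and there is no position zero (−1 abuts +1).  This is the
    convention mutation tables are written in.
``cds``
    1-based offset within the concatenated coding sequence (introns spliced
    out).

All intervals are 1-based inclusive.  Reverse-strand genes must be
reverse-complemented before loading; the package stores plus-strand models
only, which removes an entire class of strand bookkeeping errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "HomeologPair",
    "anchored_to_locus",
    "locus_to_anchored",
    "locus_to_cds",
    "cds_to_locus",
    "translate",
    "CoordinateError",
    "write_fasta",
    "read_fasta",
    "write_gff",
    "read_gene_models",
]

_STOP = "*"


class CoordinateError(ValueError):
    """Raised for invalid coordinates (position 0, out-of-bounds, non-CDS)."""


@dataclass
class GeneModel:
    """One gene copy: plus-strand locus sequence plus CDS structure.

    Parameters
    ----------
    gene_id : str
        Unique identifier, also used as the FASTA record id.
    subgenome : str
        Ancestral subgenome label, ``"A"`` or ``"B"``.
    locus_seq : str
        Plus-strand DNA, upstream region included.
    upstream_len : int
        Number of bases 5' of the start codon contained in ``locus_seq``;
        the first CDS base sits at locus position ``upstream_len + 1``.
    cds_intervals : list of (int, int)
        Ordered, non-overlapping 1-based inclusive locus intervals whose
        concatenation is the coding sequence (ATG ... stop).
    """

    gene_id: str
    subgenome: str
    locus_seq: str
    upstream_len: int
    cds_intervals: list[tuple[int, int]]
    notes: str = ""

    def __post_init__(self) -> None:
        self.locus_seq = self.locus_seq.upper()
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.locus_seq)
        if set(self.locus_seq) - set("ACGT"):
            raise ValueError(f"{self.gene_id}: locus sequence is not plain ACGT")
        prev_end = 0
        for lo, hi in self.cds_intervals:
            if not (1 <= lo <= hi <= n):
                raise ValueError(f"{self.gene_id}: CDS interval ({lo},{hi}) out of locus bounds")
            if lo <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or are unsorted")
            prev_end = hi
        cds = self.cds_seq()
        if len(cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length {len(cds)} not a multiple of 3")
        if not cds.startswith("ATG"):
            raise ValueError(f"{self.gene_id}: CDS does not begin with ATG")
        aa = translate(cds)
        if _STOP in aa[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon in reference CDS")
        if self.cds_intervals and self.cds_intervals[0][0] != self.upstream_len + 1:
            raise ValueError(
                f"{self.gene_id}: first CDS base at {self.cds_intervals[0][0]}, "
                f"expected upstream_len+1 = {self.upstream_len + 1}"
            )

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.locus_seq)

    def cds_seq(self) -> str:
        return "".join(self.locus_seq[lo - 1 : hi] for lo, hi in self.cds_intervals)

    def cds_len(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.cds_intervals)

    def protein(self, to_first_stop: bool = False) -> str:
        return translate(self.cds_seq(), to_first_stop=to_first_stop)

    def base_at(self, locus_pos: int) -> str:
        if not 1 <= locus_pos <= len(self):
            raise CoordinateError(f"locus position {locus_pos} outside 1..{len(self)}")
        return self.locus_seq[locus_pos - 1]


@dataclass
class HomeologPair:
    """A pair of homeologous gene copies from the A and B subgenomes.

    ``discriminating_features`` lists the sequence differences (typically
    indels) that gene-specific primers exploit; at least one must exist for
    copy-specific amplification to be validated.
    """

    family_id: str
    copy_a: GeneModel
    copy_b: GeneModel
    discriminating_features: list[tuple[int, str, int]] = field(default_factory=list)

    def copies(self) -> tuple[GeneModel, GeneModel]:
        return self.copy_a, self.copy_b


# -- coordinate conversions -------------------------------------------------


def anchored_to_locus(pos: int, gm: GeneModel) -> int:
    """Map an ATG-anchored position (negative = upstream, no zero) to locus.

    Position +1 is the A of ATG; −1 is the base immediately 5' of it.
    """
    if pos == 0:
        raise CoordinateError("anchored coordinates have no position 0 (-1 abuts +1)")
    locus = gm.upstream_len + pos if pos >= 1 else gm.upstream_len + pos + 1
    if not 1 <= locus <= len(gm):
        raise CoordinateError(
            f"anchored position {pos} maps to locus {locus}, outside 1..{len(gm)}"
        )
    return locus


def locus_to_anchored(pos: int, gm: GeneModel) -> int:
    """Inverse of :func:`anchored_to_locus`."""
    if not 1 <= pos <= len(gm):
        raise CoordinateError(f"locus position {pos} outside 1..{len(gm)}")
    off = pos - gm.upstream_len
    return off if off >= 1 else off - 1


def locus_to_cds(pos: int, gm: GeneModel):
    """Return the 1-based CDS offset of a locus position, or a region label.

    Returns an ``int`` when ``pos`` falls inside a CDS interval; otherwise
    one of the strings ``"upstream"``, ``"intron"`` or ``"downstream"``.
    """
    if not 1 <= pos <= len(gm):
        raise CoordinateError(f"locus position {pos} outside 1..{len(gm)}")
    if pos <= gm.upstream_len:
        return "upstream"
    consumed = 0
    for lo, hi in gm.cds_intervals:
        if pos < lo:
            return "intron"
        if pos <= hi:
            return consumed + (pos - lo + 1)
        consumed += hi - lo + 1
    return "downstream"


def cds_to_locus(cds_pos: int, gm: GeneModel) -> int:
    """Map a 1-based concatenated-CDS offset back to its locus position."""
    if cds_pos < 1:
        raise CoordinateError(f"CDS position must be >= 1, got {cds_pos}")
    consumed = 0
    for lo, hi in gm.cds_intervals:
        width = hi - lo + 1
        if cds_pos <= consumed + width:
            return lo + (cds_pos - consumed - 1)
        consumed += width
    raise CoordinateError(f"CDS position {cds_pos} beyond CDS length {gm.cds_len()}")


def translate(cds_seq: str, to_first_stop: bool = False) -> str:
    """Standard-code translation; stop codons render as ``*``."""
    if len(cds_seq) % 3:
        raise ValueError(f"sequence length {len(cds_seq)} not a multiple of 3")
    if set(cds_seq.upper()) - set("ACGT"):
        raise ValueError("sequence contains non-ACGT characters")
    aa = str(Seq(cds_seq).translate())
    if to_first_stop:
        cut = aa.find(_STOP)
        if cut != -1:
            aa = aa[: cut + 1]
    return aa


# -- I/O: FASTA + GFF3-flavored feature tables ------------------------------


def write_fasta(models: list[GeneModel], path) -> None:
    records = [
        SeqRecord(Seq(gm.locus_seq), id=gm.gene_id, description=f"subgenome={gm.subgenome}")
        for gm in models
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff(models: list[GeneModel], path) -> None:
    """GFF3-style CDS features (1-based inclusive) with upstream_len/subgenome
    carried as gene-level attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            attrs = (
                f"ID={gm.gene_id};upstream_len={gm.upstream_len};"
                f"subgenome={gm.subgenome}"
            )
            fh.write(
                f"{gm.gene_id}\tpolytill\tgene\t1\t{len(gm)}\t.\t+\t.\t{attrs}\n"
            )
            for i, (lo, hi) in enumerate(gm.cds_intervals, 1):
                fh.write(
                    f"{gm.gene_id}\tpolytill\tCDS\t{lo}\t{hi}\t.\t+\t0\t"
                    f"ID={gm.gene_id}.cds{i};Parent={gm.gene_id}\n"
                )


def read_gene_models(fasta_path, gff_path) -> dict[str, GeneModel]:
    """Load gene models from a FASTA + GFF pair written by this package."""
    seqs = read_fasta(fasta_path)
    meta: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            seqid, _, ftype, lo, hi = cols[0], cols[1], cols[2], int(cols[3]), int(cols[4])
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if ftype == "gene":
                meta[seqid] = {
                    "upstream_len": int(attrs["upstream_len"]),
                    "subgenome": attrs.get("subgenome", "A"),
                }
            elif ftype == "CDS":
                cds.setdefault(seqid, []).append((lo, hi))
    models = {}
    for gid, seq in seqs.items():
        if gid not in meta:
            continue
        models[gid] = GeneModel(
            gene_id=gid,
            subgenome=meta[gid]["subgenome"],
            locus_seq=seq,
            upstream_len=meta[gid]["upstream_len"],
            cds_intervals=sorted(cds.get(gid, [])),
        )
    return models
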