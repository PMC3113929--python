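"""In-silico nested, homeolog-specific PCR.

Allotetraploid targets carry two highly similar homeologous copies of each
gene, so screening amplifies in two rounds: an outer round with primers
common to both copies enriches the target, and an inner round with
copy-specific primers (typically anchored on a discriminating indel) yields
a single-copy amplicon.  Primer matching here is exact ungapped alignment by
default — specificity comes from indel-spanning primers, not from
hybridization thermodynamics, which this module deliberately does not model.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .genemodels import GeneModel

__all__ = [
    "Primer",
    "Amplicon",
    "NestedScheme",
    "SpecificityReport",
    "NestingError",
    "find_sites",
    "amplify",
    "nested_amplify",
    "check_specificity",
    "read_primer_table",
    "write_primer_table",
]

MAX_PRODUCT_LEN = 5000  # all realistic TILLING amplicons are < 2.3 kb


class NestingError(ValueError):
    """Inner primers do not bind within the outer product."""


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if not 15 <= len(self.seq) <= 35:
            raise ValueError(f"primer {self.name}: length {len(self.seq)} outside 15-35 nt")
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"primer {self.name}: non-ACGT characters")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: bad orientation {self.orientation!r}")

    def footprint(self) -> str:
        """Plus-strand sequence the primer anneals opposite to."""
        if self.orientation == "forward":
            return self.seq
        return str(Seq(self.seq).reverse_complement())


@dataclass(frozen=True)
class Amplicon:
    gene_id: str
    start: int  # 1-based inclusive, template coordinates
    end: int
    seq: str

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.seq):
            raise ValueError("amplicon coordinates inconsistent with sequence length")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class NestedScheme:
    """Outer (enrichment) and inner (labeled, copy-specific) primer pairs."""

    outer_fwd: Primer
    outer_rev: Primer
    inner_fwd: Primer
    inner_rev: Primer


def _template_seq(template) -> tuple[str, str]:
    if isinstance(template, GeneModel):
        return template.locus_seq, template.gene_id
    return str(template).upper(), ""


def find_sites(primer: Primer, template, max_mismatch: int = 0, anchor_3prime: int = 3) -> list[int]:
    """1-based start positions of the primer's plus-strand footprint.

    Ungapped alignment with at most ``max_mismatch`` mismatches and zero
    mismatches in the ``anchor_3prime`` 3'-terminal bases of the primer.
    For a reverse primer the 3' terminus corresponds to the *left* end of
    the plus-strand footprint.
    """
    if anchor_3prime > len(primer.seq):
        raise ValueError("3' anchor longer than primer")
    pat = primer.footprint()
    seq, _ = _template_seq(template)
    m = len(pat)
    if primer.orientation == "forward":
        anchor_idx = range(m - anchor_3prime, m)
    else:
        anchor_idx = range(0, anchor_3prime)
    anchor_idx = set(anchor_idx)
    hits = []
    if max_mismatch == 0:
        # exact search
        start = 0
        while True:
            i = seq.find(pat, start)
            if i == -1:
                break
            hits.append(i + 1)
            start = i + 1
        return hits
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        mism = 0
        ok = True
        for j in range(m):
            if window[j] != pat[j]:
                if j in anchor_idx:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            hits.append(i + 1)
    return hits


def amplify(template, fwd: Primer, rev: Primer, max_mismatch: int = 0,
            max_product_len: int = MAX_PRODUCT_LEN) -> list[Amplicon]:
    """All products of a primer pair on one template.

    One amplicon per (forward site, downstream reverse site) pair within the
    product-length cap; the product spans from the first base of the forward
    footprint to the last base of the reverse footprint.  No binding is not
    an error: the list is simply empty.
    """
    seq, gid = _template_seq(template)
    fsites = find_sites(fwd, template, max_mismatch=max_mismatch)
    rsites = find_sites(rev, template, max_mismatch=max_mismatch)
    out = []
    for f in fsites:
        f_end = f + len(fwd.seq) - 1
        for r in rsites:
            r_end = r + len(rev.seq) - 1
            if r <= f_end:  # reverse footprint must lie downstream
                continue
            if r_end - f + 1 > max_product_len:
                continue
            out.append(Amplicon(gene_id=gid, start=f, end=r_end, seq=seq[f - 1 : r_end]))
    return out


def nested_amplify(template, outer: tuple[Primer, Primer], inner: tuple[Primer, Primer],
                   max_mismatch: int = 0) -> Amplicon:
    """Inner amplification performed on the outer product.

    Equals direct inner amplification on the full template whenever the
    inner sites are unique.  Template coordinates are preserved in the
    returned amplicon.
    """
    seq, gid = _template_seq(template)
    outer_products = amplify(template, *outer, max_mismatch=max_mismatch)
    if not outer_products:
        raise NestingError("outer primer pair yields no product")
    results = []
    for op in outer_products:
        for inner_prod in amplify(op.seq, inner[0], inner[1], max_mismatch=max_mismatch):
            start = op.start + inner_prod.start - 1
            results.append(Amplicon(gene_id=gid, start=start,
                                    end=start + inner_prod.length - 1, seq=inner_prod.seq))
    if not results:
        raise NestingError("inner primers do not bind within the outer product")
    if len(set((a.start, a.end) for a in results)) > 1:
        raise NestingError("inner primers bind ambiguously within the outer product")
    return results[0]


@dataclass(frozen=True)
class SpecificityReport:
    family_id: str
    products: dict  # gene_id -> list[Amplicon]
    passed: bool

    def amplified_copies(self) -> list[str]:
        return [gid for gid, prods in self.products.items() if prods]


def check_specificity(pair, fwd: Primer, rev: Primer, max_mismatch: int = 0) -> SpecificityReport:
    """PASS iff the inner pair amplifies exactly one copy of a homeolog pair."""
    products = {}
    for gm in pair.copies():
        products[gm.gene_id] = amplify(gm, fwd, rev, max_mismatch=max_mismatch)
    n_amplified = sum(1 for p in products.values() if p)
    return SpecificityReport(family_id=pair.family_id, products=products,
                             passed=n_amplified == 1)


# -- primer table I/O (tab-delimited: name, orientation, sequence) ----------


def write_primer_table(primers: list[Primer], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\torientation\tsequence\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.orientation}\t{p.seq}\n")


def read_primer_table(path) -> list[Primer]:
    primers = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            primers.append(Primer(name=cols[idx["name"]],
                                  orientation=cols[idx["orientation"]],
                                  seq=cols[idx["sequence"]]))
    return primers
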