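"""Degenerate restriction-site mapping, CAPS markers, and Southern counting.

Covers the three restriction-based assays used around a TILLING screen:

* mapping degenerate (IUPAC) recognition sites and digesting linear DNA;
* CAPS (cleaved amplified polymorphic sequence) marker design — a point
  mutation that destroys a site merges two adjacent fragments, one that
  creates a site splits a fragment, and either yields a co-dominant
  PCR-plus-digest genotyping assay;
* Southern-style probe-fragment counting on a two-copy genomic layout,
  with a detectability floor (small fragments run off the gel) and a
  co-migration flag for fragments too similar in size to resolve.

Only top-strand matching is performed; the enzymes modeled here (EcoRI,
HindIII, AseI, and the interrupted palindrome BslI) are all self-reverse-
complementary patterns, so one strand suffices.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "Enzyme",
    "CapsAssay",
    "SouthernLayout",
    "FailedDigestError",
    "BUILTIN_ENZYMES",
    "find_sites",
    "digest",
    "cut_positions",
    "apply_substitution",
    "caps_design",
    "caps_genotype",
    "probe_fragment_count",
]

COMIGRATION_RTOL = 0.05  # fragments within 5% relative size are unresolvable


class FailedDigestError(ValueError):
    """Observed fragment set shows neither diagnostic of a CAPS assay."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with an IUPAC-degenerate recognition string.

    ``cut_offset`` is the number of recognition-site bases 5' of the
    top-strand cut (EcoRI G^AATTC has cut_offset 1; BslI CCNNNNN^NNGG
    has cut_offset 7).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        bad = set(self.recognition.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {bad}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside recognition site")

    def regex(self) -> re.Pattern:
        expanded = "".join(
            f"[{ambiguous_dna_values[c.upper()]}]" if len(ambiguous_dna_values[c.upper()]) > 1
            else ambiguous_dna_values[c.upper()]
            for c in self.recognition
        )
        return re.compile(f"(?=({expanded}))")  # lookahead: overlapping matches


BUILTIN_ENZYMES: dict[str, Enzyme] = {
    "EcoRI": Enzyme("EcoRI", "GAATTC", 1),
    "HindIII": Enzyme("HindIII", "AAGCTT", 1),
    "AseI": Enzyme("AseI", "ATTAAT", 2),
    "BslI": Enzyme("BslI", "CCNNNNNNNGG", 7),
}


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """All 1-based top-strand start positions of the recognition pattern."""
    seq = seq.upper()
    return [m.start() + 1 for m in enzyme.regex().finditer(seq)]


def cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut boundaries: position b means a cut between b and b+1."""
    n = len(seq)
    cuts = []
    for s in find_sites(seq, enzyme):
        b = s + enzyme.cut_offset - 1
        if 0 < b < n:
            cuts.append(b)
    return sorted(set(cuts))


def digest(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment sizes of a complete digest of a linear molecule, in order.

    n cut positions yield n + 1 fragments whose sizes sum to len(seq).
    """
    bounds = [0] + cut_positions(seq, enzyme) + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def apply_substitution(seq: str, offset: int, alt: str) -> str:
    """Return ``seq`` with the base at 1-based ``offset`` replaced by ``alt``."""
    if not 1 <= offset <= len(seq):
        raise ValueError(f"offset {offset} outside sequence")
    return seq[: offset - 1] + alt + seq[offset:]


@dataclass
class CapsAssay:
    """A candidate CAPS genotyping assay for one mutation.

    ``mutant_diagnostic`` / ``wt_diagnostic`` are the largest fragment sizes
    unique to the mutant and wild-type digests (larger fragments are easier
    to score on a gel); the full unique-size lists are retained.
    """

    enzyme: Enzyme | None
    wt_fragments: list[int] = field(default_factory=list)
    mut_fragments: list[int] = field(default_factory=list)
    mutant_diagnostic: int | None = None
    wt_diagnostic: int | None = None
    mutant_only: list[int] = field(default_factory=list)
    wt_only: list[int] = field(default_factory=list)

    @property
    def informative(self) -> bool:
        return self.mutant_diagnostic is not None and self.wt_diagnostic is not None


def caps_design(wt_seq: str, mut_offset: int, alt: str, enzymes=None) -> CapsAssay:
    """Design a CAPS assay discriminating a substitution allele.

    Digests the wild-type and mutant amplicon with each candidate enzyme and
    returns the first assay in which each allele shows at least one fragment
    size the other lacks.  A destroyed site merges two adjacent wild-type
    fragments (the mutant diagnostic is their sum); a created site splits
    one.  When no enzyme discriminates, an uninformative assay (enzyme None)
    is returned rather than raising.
    """
    if enzymes is None:
        enzymes = list(BUILTIN_ENZYMES.values())
    mut_seq = apply_substitution(wt_seq, mut_offset, alt)
    for enz in enzymes:
        wt_frags = digest(wt_seq, enz)
        mut_frags = digest(mut_seq, enz)
        wt_cnt, mut_cnt = Counter(wt_frags), Counter(mut_frags)
        mut_only = sorted((mut_cnt - wt_cnt).elements(), reverse=True)
        wt_only = sorted((wt_cnt - mut_cnt).elements(), reverse=True)
        if mut_only and wt_only:
            return CapsAssay(
                enzyme=enz,
                wt_fragments=wt_frags,
                mut_fragments=mut_frags,
                mutant_diagnostic=mut_only[0],
                wt_diagnostic=wt_only[0],
                mutant_only=mut_only,
                wt_only=wt_only,
            )
    return CapsAssay(enzyme=None)


def caps_genotype(observed_sizes, assay: CapsAssay) -> str:
    """Call wt / het / hom from the fragment sizes of one digested sample.

    The homozygous mutant shows the mutant diagnostic but lacks the
    wild-type diagnostic; a heterozygote shows both.
    """
    if not assay.informative:
        raise ValueError("assay has no diagnostic fragments")
    obs = set(observed_sizes)
    has_mut = assay.mutant_diagnostic in obs
    has_wt = assay.wt_diagnostic in obs
    if has_mut and has_wt:
        return "het"
    if has_mut:
        return "hom"
    if has_wt:
        return "wt"
    raise FailedDigestError("neither diagnostic fragment observed")


@dataclass(frozen=True)
class SouthernLayout:
    """A linear genomic construct carrying both homeologous copies.

    ``probe_spans`` are the 1-based inclusive intervals homologous to the
    probe (a full-length probe from one copy cross-hybridizes to both).
    """

    seq: str
    probe_spans: tuple[tuple[int, int], ...]


def probe_fragment_count(layout: SouthernLayout, enzyme: Enzyme,
                         min_detectable: int = 100, min_overlap: int = 50):
    """Predict the number of probe-visible bands of a genomic digest.

    A fragment is counted when it overlaps a probe-homologous region by at
    least ``min_overlap`` bp and is at least ``min_detectable`` bp long
    (smaller fragments run off the blot).  Counted fragments within 5%
    relative size of each other are flagged as co-migrating — they appear
    "nearly overlapping" on the gel.

    Returns ``(count, sizes, comigrating)`` where ``sizes`` are the counted
    fragment sizes in genomic order and ``comigrating`` lists size pairs too
    close to resolve.
    """
    bounds = [0] + cut_positions(layout.seq, enzyme) + [len(layout.seq)]
    visible = []
    for a, b in zip(bounds, bounds[1:]):
        size = b - a
        if size < min_detectable:
            continue
        frag_lo, frag_hi = a + 1, b
        overlap = max(
            (min(frag_hi, hi) - max(frag_lo, lo) + 1 for lo, hi in layout.probe_spans),
            default=0,
        )
        if overlap >= min_overlap:
            visible.append(size)
    comigrating = [
        (x, y)
        for i, x in enumerate(visible)
        for y in visible[i + 1 :]
        if abs(x - y) / max(x, y) <= COMIGRATION_RTOL
    ]
    return len(visible), visible, comigrating
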