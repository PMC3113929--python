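"""Mutation-effect annotation with codon bookkeeping.

Classifies point mutations and small indels against a gene model:
upstream/intron placement, silent/missense/nonsense calls from wild-type vs
mutant codon translation, start-codon disruption (recording whether any
in-frame downstream ATG could rescue translation), and frameshifts with the
truncated product length found by re-translating the shifted CDS.  Also
provides epitope-interval overlap for allergen work and the EMS spectrum
summary (canonical G:C→A:T transitions vs atypical changes).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genemodels import GeneModel, anchored_to_locus, locus_to_cds, translate

__all__ = [
    "Mutation",
    "Effect",
    "EpitopeMap",
    "ReferenceMismatchError",
    "codon_index",
    "classify",
    "epitope_overlap",
    "spectrum_summary",
    "mutation_from_notation",
    "mutation_to_notation",
    "read_mutation_table",
    "write_effect_table",
]


class ReferenceMismatchError(ValueError):
    """Stated reference allele disagrees with the gene model."""


@dataclass(frozen=True)
class Mutation:
    """A mutation in ATG-anchored coordinates (negative = upstream, no zero).

    For insertions, ``alt`` is the string inserted immediately after
    ``anchored_pos`` and ``ref`` the reference base at that position; for
    deletions, ``ref`` is the deleted string starting at ``anchored_pos``.
    """

    gene_id: str
    anchored_pos: int
    ref: str
    alt: str
    kind: str = "substitution"

    def __post_init__(self):
        if self.kind == "substitution" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("substitution must have single ref and alt bases")
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")


@dataclass(frozen=True)
class Effect:
    effect_class: str  # silent|missense|nonsense|start_loss|frameshift|upstream|intron|downstream
    codon_index: int | None = None
    wt_aa: str | None = None
    mut_aa: str | None = None
    truncated_length: int | None = None
    notes: str = ""


@dataclass(frozen=True)
class EpitopeMap:
    """Named epitopes as closed protein-coordinate intervals."""

    gene_id: str
    epitopes: tuple  # of (label, (start_residue, end_residue))

    def validate(self, protein_length: int) -> None:
        for label, (lo, hi) in self.epitopes:
            if not 1 <= lo <= hi <= protein_length:
                raise ValueError(f"epitope {label}: interval outside protein")


def codon_index(cds_pos: int) -> tuple[int, int]:
    """(codon number, offset 1-3) of a 1-based CDS position."""
    if cds_pos < 1:
        raise ValueError("CDS position must be >= 1")
    codon = math.ceil(cds_pos / 3)
    return codon, cds_pos - 3 * (codon - 1)


def _check_ref(m: Mutation, gm: GeneModel, locus_pos: int) -> None:
    span = len(m.ref) if m.kind == "deletion" else 1
    observed = gm.locus_seq[locus_pos - 1 : locus_pos - 1 + span]
    if observed != m.ref:
        raise ReferenceMismatchError(
            f"{m.gene_id}:{m.anchored_pos}: model has {observed!r}, "
            f"mutation states ref {m.ref!r}")


def _frameshift_effect(m: Mutation, gm: GeneModel, cds_pos: int) -> Effect:
    cds = gm.cds_seq()
    if m.kind == "insertion":
        mut_cds = cds[:cds_pos] + m.alt + cds[cds_pos:]
        delta = len(m.alt)
    else:
        mut_cds = cds[: cds_pos - 1] + cds[cds_pos - 1 + len(m.ref):]
        delta = -len(m.ref)
    codon, _ = codon_index(cds_pos)
    if delta % 3 == 0:
        return Effect("inframe_indel", codon_index=codon,
                      notes=f"in-frame {m.kind} of {abs(delta)} bp")
    mut_cds = mut_cds[: 3 * (len(mut_cds) // 3)]
    aa = translate(mut_cds, to_first_stop=True)
    if aa.endswith("*"):
        trunc = len(aa) - 1
        note = f"frameshift after codon {codon}; premature stop after {trunc} residues"
    else:
        trunc = None
        note = f"frameshift after codon {codon}; no stop before CDS end"
    return Effect("frameshift", codon_index=codon, truncated_length=trunc, notes=note)


def classify(m: Mutation, gm: GeneModel) -> Effect:
    """Predict the consequence of a mutation on its gene model."""
    locus_pos = anchored_to_locus(m.anchored_pos, gm)
    _check_ref(m, gm, locus_pos)
    region = locus_to_cds(locus_pos, gm)
    if region == "upstream":
        return Effect("upstream", notes="5' of the start codon")
    if region in ("intron", "downstream"):
        return Effect(region)
    cds_pos: int = region
    if m.kind != "substitution":
        return _frameshift_effect(m, gm, cds_pos)
    cds = gm.cds_seq()
    codon, offset = codon_index(cds_pos)
    wt_codon = cds[3 * (codon - 1) : 3 * codon]
    mut_codon = wt_codon[: offset - 1] + m.alt + wt_codon[offset:]
    wt_aa, mut_aa = translate(wt_codon), translate(mut_codon)
    if codon == 1 and mut_codon != "ATG":
        mut_cds = cds[: cds_pos - 1] + m.alt + cds[cds_pos:]
        rescue = any(mut_cds[i : i + 3] == "ATG" for i in range(3, len(mut_cds), 3))
        note = ("disrupted start codon; "
                + ("an in-frame downstream ATG exists"
                   if rescue else "no in-frame downstream ATG"))
        return Effect("start_loss", codon_index=1, wt_aa=wt_aa, mut_aa=mut_aa, notes=note)
    if mut_aa == "*" and wt_aa != "*":
        return Effect("nonsense", codon_index=codon, wt_aa=wt_aa, mut_aa=mut_aa,
                      truncated_length=codon - 1,
                      notes=f"premature stop at codon {codon}; "
                            f"{codon - 1} residues before the stop")
    if wt_aa == mut_aa:
        return Effect("silent", codon_index=codon, wt_aa=wt_aa, mut_aa=mut_aa)
    note = "stop codon lost" if wt_aa == "*" else ""
    return Effect("missense", codon_index=codon, wt_aa=wt_aa, mut_aa=mut_aa, notes=note)


def epitope_overlap(e: Effect, emap: EpitopeMap) -> list[str]:
    """Labels of epitopes whose (closed) interval contains the affected codon."""
    if e.codon_index is None:
        raise ValueError("effect has no codon index")
    return [label for label, (lo, hi) in emap.epitopes if lo <= e.codon_index <= hi]


def spectrum_summary(mutations) -> dict:
    """Tally the mutation spectrum and list atypical (non-EMS-like) changes.

    Canonical EMS lesions are G→A and C→T substitutions on the stored
    strand; everything else (other substitutions, indels) is atypical and
    suggests a non-induced origin such as seed-stock impurity.
    """
    counts = Counter({"G>A": 0, "C>T": 0, "other_substitution": 0, "indel": 0})
    atypical = []
    for m in mutations:
        if m.kind != "substitution":
            counts["indel"] += 1
            atypical.append(m)
        elif (m.ref, m.alt) in (("G", "A"), ("C", "T")):
            counts[f"{m.ref}>{m.alt}"] += 1
        else:
            counts["other_substitution"] += 1
            atypical.append(m)
    canonical = counts["G>A"] + counts["C>T"]
    return {"counts": dict(counts), "n_canonical": canonical,
            "n_atypical": len(atypical), "atypical": atypical}


# -- notation and table I/O -------------------------------------------------

_SUB_RE = re.compile(r"^([ACGT])(-?\d+)>([ACGT])$")
_INS_RE = re.compile(r"^([ACGT])(-?\d+)ins([ACGT]+)$")
_DEL_RE = re.compile(r"^([ACGT]+)(-?\d+)del$")


def mutation_to_notation(m: Mutation) -> str:
    if m.kind == "substitution":
        return f"{m.ref}{m.anchored_pos}>{m.alt}"
    if m.kind == "insertion":
        return f"{m.ref}{m.anchored_pos}ins{m.alt}"
    return f"{m.ref}{m.anchored_pos}del"


def mutation_from_notation(gene_id: str, notation: str) -> Mutation:
    """Parse compact notation: ``C145>T``, ``A442insA``, ``ACG-12del``."""
    if (match := _SUB_RE.match(notation)):
        ref, pos, alt = match.groups()
        return Mutation(gene_id, int(pos), ref, alt, "substitution")
    if (match := _INS_RE.match(notation)):
        ref, pos, alt = match.groups()
        return Mutation(gene_id, int(pos), ref, alt, "insertion")
    if (match := _DEL_RE.match(notation)):
        ref, pos = match.groups()
        return Mutation(gene_id, int(pos), ref, "", "deletion")
    raise ValueError(f"cannot parse mutation notation {notation!r}")


def read_mutation_table(path) -> list[Mutation]:
    df = pd.read_csv(path, sep="\t")
    return [mutation_from_notation(r.gene_id, r.change) for r in df.itertuples()]


def write_effect_table(mutations: list[Mutation], genes: dict, path) -> pd.DataFrame:
    rows = []
    for m in mutations:
        eff = classify(m, genes[m.gene_id])
        rows.append({
            "gene_id": m.gene_id,
            "change": mutation_to_notation(m),
            "effect": eff.effect_class,
            "codon": eff.codon_index,
            "wt_aa": eff.wt_aa,
            "mut_aa": eff.mut_aa,
            "truncated_length": eff.truncated_length,
            "notes": eff.notes,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
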