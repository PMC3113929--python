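"""Synthetic data: EMS-mutagenized M2 populations and benchmark gene fixtures.

Two generators live here.

:func:`simulate_m2` draws an M2 population under the standard EMS model:
per M1 plant and locus the induced mutation count is Poisson in the locus
length, canonical mutations are G:C→A:T transitions placed uniformly over
G/C sites, and each (heterozygous) M1 mutation is transmitted to the single
M2 descendant as homozygous/heterozygous/absent with Mendelian 1:2:1
probabilities.  Rare contaminant alleles — pre-existing variants in the
seed stock rather than induced lesions — can be layered on top at fixed
per-individual frequencies.

:func:`benchmark_fixtures` builds a deterministic set of three homeologous gene
pairs (an intronless 2S-albumin-like pair, an intron-bearing vicilin-like
pair, and an intronless desaturase-like pair distinguished by a 19-bp
upstream indel), together with nested primer schemes, a 27-row confirmed
mutation table, and a two-copy genomic layout for Southern fragment
counting.  The sequences are engineered synthetic stand-ins, not database
records: every mutation coordinate, restriction-site configuration and
amplicon length in the fixture set is constructed to hold exactly, and the
builder verifies all of them before returning.
"""

from __future__ import annotations

import functools
import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import insilico_pcr as pcr
from . import restriction
from .genemodels import GeneModel, HomeologPair, anchored_to_locus, translate
from .insilico_pcr import NestedScheme, Primer

logger = logging.getLogger(__name__)

__all__ = [
    "MutagenesisParams",
    "Variant",
    "Individual",
    "Population",
    "simulate_m2",
    "benchmark_fixtures",
    "benchmark_mutation_table",
    "population_from_table",
    "seed_stock_contaminants",
    "random_gene_model",
    "write_genotype_table",
    "BenchmarkFixtures",
    "TREATMENT_04",
    "TREATMENT_12",
]

TREATMENT_04 = "0.4% EMS/12 hr."
TREATMENT_12 = "1.2% EMS/4.5 hr."

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
# random codon pool: sense codons, ATG excluded so start-loss bookkeeping
# ("is there a downstream in-frame ATG?") is exact on fixtures
_RANDOM_POOL = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                if a + b + c not in _STOPS and a + b + c != "ATG"]
# pool whose codons start and end with A/T: concatenations can never form
# CC or GG dinucleotides, keeping engineered BslI sites unique
_SAFE_AT_POOL = [a + b + c for a in "AT" for b in _BASES for c in "AT"
                 if a + b + c not in _STOPS]

_SIX_CUTTERS = ("GAATTC", "AAGCTT", "ATTAAT")  # EcoRI, HindIII, AseI
_FIXTURE_SEED = 180781


class FixtureBuildError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    ref: str
    alt: str
    kind: str  # substitution | insertion | deletion
    zygosity: str  # het | hom


@dataclass
class MutagenesisParams:
    """EMS treatment parameters.

    density
        Expected induced mutations per bp per M1 individual.
    canonical_fraction
        Probability an induced mutation is a G→A / C→T transition.
    contaminant_alleles
        list of (gene_id, anchored_pos, ref, alt, kind, frequency) tuples,
        introduced heterozygously and independently per individual.
    """

    density: float
    canonical_fraction: float = 1.0
    contaminant_alleles: list = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not 0.0 <= self.canonical_fraction <= 1.0:
            raise ValueError("canonical_fraction must be in [0, 1]")
        for c in self.contaminant_alleles:
            if not 0.0 <= c[-1] <= 1.0:
                raise ValueError("contaminant frequency must be in [0, 1]")


@dataclass
class Individual:
    id: str
    genotype: dict = field(default_factory=dict)  # (gene_id, locus_pos) -> Variant
    group: str = "EMS"


@dataclass
class Population:
    individuals: list
    params: MutagenesisParams | None
    loci: list

    def __post_init__(self):
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")

    def __len__(self):
        return len(self.individuals)

    def by_id(self, ind_id: str) -> Individual:
        if not hasattr(self, "_index"):
            self._index = {ind.id: ind for ind in self.individuals}
        return self._index[ind_id]


def simulate_m2(loci: list, n: int, params: MutagenesisParams) -> Population:
    """Simulate ``n`` M2 individuals over the given loci.

    Fully reproducible from ``params.rng_seed``.  A site that would receive
    a second allele within one individual is re-drawn (with a warning), so
    each individual carries at most one alt allele per site.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(params.rng_seed)
    gc_sites = {
        gm.gene_id: np.array([i + 1 for i, b in enumerate(gm.locus_seq) if b in "GC"])
        for gm in loci
    }
    width = max(4, len(str(n)))
    individuals = []
    for i in range(n):
        geno: dict = {}
        for gm in loci:
            L = len(gm)
            k = rng.poisson(params.density * L)
            for _ in range(k):
                # Mendelian transmission of a heterozygous M1 lesion
                u = rng.random()
                if u < 0.25:
                    zyg = "hom"
                elif u < 0.75:
                    zyg = "het"
                else:
                    continue  # lost in segregation
                for _attempt in range(100):
                    if rng.random() < params.canonical_fraction:
                        sites = gc_sites[gm.gene_id]
                        pos = int(sites[rng.integers(len(sites))])
                        ref = gm.locus_seq[pos - 1]
                        alt = "A" if ref == "G" else "T"
                    else:
                        pos = int(rng.integers(1, L + 1))
                        ref = gm.locus_seq[pos - 1]
                        alt = _BASES[int(rng.integers(4))]
                        while alt == ref:
                            alt = _BASES[int(rng.integers(4))]
                    key = (gm.gene_id, pos)
                    if key not in geno:
                        geno[key] = Variant(ref, alt, "substitution", zyg)
                        break
                    warnings.warn(
                        f"double hit at {key} in individual {i}; re-drawing site",
                        stacklevel=2,
                    )
        gm_by_id = {gm.gene_id: gm for gm in loci}
        for gene_id, pos, ref, alt, kind, freq in params.contaminant_alleles:
            if rng.random() < freq:
                locus_pos = anchored_to_locus(pos, gm_by_id[gene_id])
                geno[(gene_id, locus_pos)] = Variant(ref, alt, kind, "het")
        individuals.append(Individual(id=f"M2-{i + 1:0{width}d}", genotype=geno))
    return Population(individuals=individuals, params=params, loci=list(loci))


def seed_stock_contaminants() -> list:
    """Seed-stock contaminant alleles at their observed frequencies.

    A single-base A insertion in the B-copy desaturase (2 carriers / 3420)
    and an A→G reversion in the A copy (3 / 3420), both attributed to
    genetic impurity of the starting seed rather than to the mutagen.
    """
    return [
        ("fad2b", 442, "A", "A", "insertion", 2 / 3420),
        ("fad2a", 448, "A", "G", "substitution", 3 / 3420),
    ]


def write_genotype_table(pop: Population, path) -> None:
    """VCF-like tab-delimited genotype table (one column per individual)."""
    sites = sorted({key for ind in pop.individuals for key in ind.genotype})
    with open(path, "w") as fh:
        cols = "\t".join(ind.id for ind in pop.individuals)
        fh.write(f"CHROM\tPOS\tREF\tALT\t{cols}\n")
        for gene_id, pos in sites:
            variants = [ind.genotype.get((gene_id, pos)) for ind in pop.individuals]
            alts = {v.alt for v in variants if v is not None}
            ref = next(v.ref for v in variants if v is not None)
            for alt in sorted(alts):
                calls = []
                for v in variants:
                    if v is None or v.alt != alt:
                        calls.append("0/0")
                    else:
                        calls.append("1/1" if v.zygosity == "hom" else "0/1")
                fh.write(f"{gene_id}\t{pos}\t{ref}\t{alt}\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# constrained sequence assembly
# ---------------------------------------------------------------------------


class _SeqAssembler:
    """Builds a sequence left to right while excluding forbidden motifs.

    Fixed inserts (primer blocks, engineered codons, restriction sites) may
    contain motifs deliberately; only motifs ending inside newly added
    *random* material are rejected.
    """

    def __init__(self, rng: np.random.Generator, forbidden=()):
        self.rng = rng
        self.forbidden = tuple(forbidden)
        self.maxm = max((len(f) for f in self.forbidden), default=0)
        self.chars: list[str] = []

    def _new_motif(self, k: int) -> bool:
        """Does any forbidden motif end within the last ``k`` characters?"""
        n = len(self.chars)
        lo = max(0, n - (self.maxm + k - 1))
        s = "".join(self.chars[lo:])
        for f in self.forbidden:
            i = s.find(f)
            while i != -1:
                if lo + i + len(f) > n - k:
                    return True
                i = s.find(f, i + 1)
        return False

    def add_random(self, n: int) -> None:
        for _ in range(n):
            for bi in self.rng.permutation(4):
                self.chars.append(_BASES[bi])
                if self._new_motif(1):
                    self.chars.pop()
                else:
                    break
            else:
                raise FixtureBuildError("no base satisfies motif constraints")

    def add_fixed(self, s: str, check: bool = True) -> None:
        self.chars.extend(s)
        if check and self._new_motif(len(s)):
            raise FixtureBuildError(f"fixed insert {s} creates a forbidden motif")

    def add_codons(self, n_codons: int, pool: list[str], engineered: dict[int, str]) -> None:
        for ci in range(1, n_codons + 1):
            codon = engineered.get(ci)
            if codon is not None:
                self.add_fixed(codon, check=False)
                continue
            for pi in self.rng.permutation(len(pool)):
                self.chars.extend(pool[pi])
                if self._new_motif(3):
                    del self.chars[-3:]
                else:
                    break
            else:
                raise FixtureBuildError("no codon satisfies motif constraints")

    def seq(self) -> str:
        return "".join(self.chars)


def random_gene_model(gene_id: str = "toy", n_codons: int = 120, upstream_len: int = 60,
                      downstream_len: int = 60, seed: int = 0,
                      subgenome: str = "A") -> GeneModel:
    """A random intronless gene model — handy for property tests."""
    rng = np.random.default_rng(seed)
    asm = _SeqAssembler(rng)
    asm.add_random(upstream_len)
    asm.add_codons(n_codons, _RANDOM_POOL, {1: "ATG", n_codons: "TAA"})
    asm.add_random(downstream_len)
    cds_start = upstream_len + 1
    return GeneModel(
        gene_id=gene_id,
        subgenome=subgenome,
        locus_seq=asm.seq(),
        upstream_len=upstream_len,
        cds_intervals=[(cds_start, cds_start + 3 * n_codons - 1)],
    )


# ---------------------------------------------------------------------------
# benchmark fixtures
# ---------------------------------------------------------------------------

# engineered codons per fixture gene (1-based codon index -> codon)

_H2_1_CODONS = {
    1: "ATG",
    27: "ACA",   # C at CDS 80
    49: "CTT",   # Leu; C145→T gives Phe
    55: "CGT",   # Arg; G164→A gives His
    62: "GCG",   # G186→A silent (Ala)
    64: "CTG",   # G192→A silent (Leu)
    81: "CTG",   # G at CDS 243
    82: "GCA",   # Ala at residue 82
    119: "ACG",  # G357→A silent (Thr)
    158: "TAA",
}
_DPYSPS = ["GAT", "CCA", "TAT", "TCA", "CCA", "TCA"]  # allergenic epitope motif
_H2_2_CODONS = {
    1: "ATG",
    62: "CGA",  # Arg just before the first epitope motif; G185→A gives Gln
    **{63 + i: c for i, c in enumerate(_DPYSPS)},
    69: "GCA",
    **{70 + i: c for i, c in enumerate(_DPYSPS)},  # D70 in the second motif
    170: "TAA",
}
_H1_1_CODONS = {
    1: "ATG",
    196: "CTG",  # C586→T silent (Leu)
    333: "CGG",  # Arg; C1392→T gives Trp
    405: "CCA",  # Pro; C1609→T gives Leu
    437: "GAA",  # Glu; G1704→A gives Lys
    500: "GAA", 501: "TTC",  # GAATTC: the single EcoRI site of this copy
    575: "TAA",
}
# B-copy vicilin-like gene: six BslI sites engineered into the amplicon.
# The codon-101 site spans the premature-stop codon 102 (CGA); C304→T
# destroys it and merges the flanking 230+63 bp digest fragments into the
# 293 bp mutant-diagnostic CAPS fragment.
_BSLI_BLOCK = {0: "CCA", 1: "ACA", 2: "ACA", 3: "GGT"}
_H1_2_CODONS = {
    1: "ATG",
    **{25 + k: c for k, c in _BSLI_BLOCK.items()},
    101: "ATC", 102: "CGA", 103: "ACA", 104: "TTG", 105: "GAT",
    122: "ATC", 123: "CAT", 124: "ACA", 125: "TTG", 126: "GAT",
    **{192 + k: c for k, c in _BSLI_BLOCK.items()},
    **{275 + k: c for k, c in _BSLI_BLOCK.items()},
    **{342 + k: c for k, c in _BSLI_BLOCK.items()},
    450: "GAA", 451: "TTC",  # EcoRI
    502: "TAA",
}
_FAD2B_CODONS = {
    1: "ATG",
    148: "ACA",  # A at CDS 442 (frameshift insertion point)
    150: "GAT",  # Asp150: the functional-desaturase residue
    189: "TCA",  # C at CDS 566
    240: "CTG",  # C718→T silent
    254: "CCA",  # Pro; C761→T gives Leu
    380: "TAA",
}

# expected BslI geometry on the 1666-bp B-copy amplicon
_BSLI_SITE_STARTS_AMP = [193, 423, 486, 694, 943, 1294]
_BSLI_WT_FRAGMENTS = [199, 230, 63, 208, 249, 351, 366]
_BSLI_MUT_FRAGMENTS = [199, 293, 208, 249, 351, 366]

AMPLICON_LENGTHS = {
    "h1-1": 2211, "h1-2": 1666,
    "h2-1": 1278, "h2-2": 1226,
    "fad2a": 1228, "fad2b": 1221,
}


@dataclass
class BenchmarkFixtures:
    genes: dict
    pairs: dict
    schemes: dict
    amplicons: dict
    mutations: pd.DataFrame
    southern: restriction.SouthernLayout

    def gene_list(self) -> list:
        return [self.genes[g] for g in sorted(self.genes)]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for gid in sorted(self.genes):
            h.update(self.genes[gid].locus_seq.encode())
        h.update(self.southern.seq.encode())
        return h.hexdigest()


def benchmark_mutation_table() -> pd.DataFrame:
    """The 27 confirmed mutations, transcribed in fixture coordinates.

    ``anomalous`` marks the three rows whose stated nucleotide coordinate
    and residue annotation cannot both hold under contiguous 1-based CDS
    numbering; fixtures carry the stated reference base at the stated
    coordinate but the annotated effect is not asserted for them.
    """
    rows = [
        # gene, pos, ref, alt, kind, table class, aa change, group, population, plant
        ("h2-1", 145, "C", "T", "substitution", "missense", "L49F", TREATMENT_04, "05", "20-6", False),
        ("h2-1", 164, "G", "A", "substitution", "missense", "R55H", TREATMENT_04, "05", "37-4", False),
        ("h2-1", 192, "G", "A", "substitution", "silent", "", TREATMENT_04, "05", "37-4", False),
        ("h2-1", 186, "G", "A", "substitution", "silent", "", TREATMENT_04, "07G", "78-4", False),
        ("h2-1", 80, "C", "T", "substitution", "silent", "", TREATMENT_04, "07G", "90-4", True),
        ("h2-1", 357, "G", "A", "substitution", "silent", "", TREATMENT_04, "07JKEMS1", "65", False),
        ("h2-1", 186, "G", "A", "substitution", "silent", "", TREATMENT_04, "08GH", "250", False),
        ("h2-2", 185, "G", "A", "substitution", "missense", "R62Q", TREATMENT_04, "07G", "89-5", False),
        ("h2-2", 3, "G", "A", "substitution", "start_loss", "", TREATMENT_04, "08GH", "2", False),
        ("h1-1", 1392, "C", "T", "substitution", "missense", "R333W", TREATMENT_04, "07G", "95-1", False),
        ("h1-1", 586, "C", "T", "substitution", "silent", "", TREATMENT_04, "07JKEMS1", "99", False),
        ("h1-2", 304, "C", "T", "substitution", "nonsense", "R102*", TREATMENT_04, "07JKEMS1", "133", False),
        ("fad2a", 448, "A", "G", "substitution", "missense", "N150D", TREATMENT_04, "05", "4-3", False),
        ("fad2a", 448, "A", "G", "substitution", "missense", "N150D", TREATMENT_04, "05", "55-4", False),
        ("fad2a", 448, "A", "G", "substitution", "missense", "N150D", TREATMENT_04, "05", "138-10", False),
        ("fad2a", 718, "C", "T", "substitution", "silent", "", TREATMENT_04, "07G", "113-5", False),
        ("fad2a", 761, "C", "T", "substitution", "missense", "P254L", TREATMENT_04, "07JKEMS1", "72", False),
        ("fad2b", 442, "A", "A", "insertion", "frameshift", "", TREATMENT_04, "05", "69-8", False),
        ("fad2b", 442, "A", "A", "insertion", "frameshift", "", TREATMENT_04, "07G", "81-4", False),
        ("fad2b", 566, "C", "T", "substitution", "silent", "", TREATMENT_04, "07JKEMS1", "2", True),
        ("h2-1", 243, "G", "A", "substitution", "missense", "A82T", TREATMENT_12, "06EF", "13-6", True),
        ("h2-1", 192, "G", "A", "substitution", "silent", "", TREATMENT_12, "06LREMS1", "8-4", False),
        ("h2-2", 208, "G", "A", "substitution", "missense", "D70N", TREATMENT_12, "06EF", "23-7", False),
        ("h2-2", 208, "G", "A", "substitution", "missense", "D70N", TREATMENT_12, "06EF", "26-1", False),
        ("h2-2", -315, "G", "A", "substitution", "upstream", "", TREATMENT_12, "06EF", "62-6", False),
        ("h1-1", 1609, "C", "T", "substitution", "missense", "P405L", TREATMENT_12, "06EF", "53-3", False),
        ("h1-1", 1704, "G", "A", "substitution", "missense", "E437K", TREATMENT_12, "06EF", "56-3", False),
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "anchored_pos", "ref", "alt", "kind", "table_class",
                 "aa_change", "group", "population", "plant_id", "anomalous"],
    )


def _build_h2(rng) -> tuple[GeneModel, GeneModel, dict]:
    forbidden = _SIX_CUTTERS
    blocks = _SeqAssembler(rng, forbidden)
    blocks.add_random(25 + 20 + 25)
    s = blocks.seq()
    outer_fwd_block, inner_rev_block, outer_rev_block = s[:25], s[25:45], s[45:70]

    def build_copy(upstream_random2: int, n_codons: int, codons: dict,
                   down_pre: int, down_mid: int, down_post: int, extra=None):
        asm = _SeqAssembler(rng, forbidden)
        asm.add_random(100)
        asm.add_fixed(outer_fwd_block)
        asm.add_random(upstream_random2)
        upstream_len = 125 + upstream_random2
        asm.add_codons(n_codons, _RANDOM_POOL, codons)
        asm.add_random(down_pre)
        asm.add_fixed(inner_rev_block)
        asm.add_random(down_mid)
        asm.add_fixed(outer_rev_block)
        asm.add_random(down_post)
        seq = asm.seq()
        if extra:
            for pos, base in extra.items():
                seq = seq[: pos - 1] + base + seq[pos:]
        return seq, upstream_len

    seq1, up1 = build_copy(175, 158, _H2_1_CODONS, 644, 17, 20)
    gm1 = GeneModel("h2-1", "A", seq1, up1, [(301, 774)])
    seq2, up2 = build_copy(575, 170, _H2_2_CODONS, 156, 14, 25, extra={386: "G"})
    gm2 = GeneModel("h2-2", "B", seq2, up2, [(701, 1210)])

    def scheme(gm):
        return NestedScheme(
            outer_fwd=Primer("h2-outer-f", outer_fwd_block, "forward"),
            outer_rev=Primer("h2-outer-r", _rc(outer_rev_block), "reverse"),
            inner_fwd=Primer(f"{gm.gene_id}-inner-f", gm.locus_seq[160:184], "forward"),
            inner_rev=Primer("h2-inner-r", _rc(inner_rev_block), "reverse"),
        )

    schemes = {"h2-1": scheme(gm1), "h2-2": scheme(gm2)}
    return gm1, gm2, schemes


def _build_h1(rng) -> tuple[GeneModel, GeneModel, dict]:
    forbidden_1 = _SIX_CUTTERS
    forbidden_2 = _SIX_CUTTERS + ("CC", "GG")
    blocks = _SeqAssembler(rng, forbidden_2)  # shared fwd must be CC/GG-free
    blocks.add_random(20)
    shared_fwd = blocks.seq()
    blocks2 = _SeqAssembler(rng, forbidden_1)
    blocks2.add_random(23)
    outer_rev_block = blocks2.seq()

    # copy 1: three exons, 395 bp of intron ahead of the codon-333 region
    asm = _SeqAssembler(rng, forbidden_1)
    asm.add_random(30)
    asm.add_fixed(shared_fwd)
    asm.add_random(100)
    cds_asm = _SeqAssembler(rng, forbidden_1)
    cds_asm.add_codons(575, _RANDOM_POOL, _H1_1_CODONS)
    cds1 = cds_asm.seq()
    intron1 = _SeqAssembler(rng, forbidden_1)
    intron1.add_random(200)
    intron2 = _SeqAssembler(rng, forbidden_1)
    intron2.add_random(9)
    intron2.add_fixed("ATTAAT", check=False)  # AseI, adjacent pair
    intron2.add_random(34)
    intron2.add_fixed("ATTAAT", check=False)
    intron2.add_random(140)
    down = _SeqAssembler(rng, forbidden_1)
    down.add_random(10)
    down.add_fixed(outer_rev_block)
    down.add_random(297)
    seq1 = (asm.seq() + cds1[:600] + intron1.seq() + cds1[600:700]
            + intron2.seq() + cds1[700:] + down.seq())
    gm1 = GeneModel("h1-1", "B", seq1, 150,
                    [(151, 750), (951, 1050), (1246, 2270)])

    # copy 2: CC/GG-free background so the amplicon carries exactly the six
    # engineered BslI sites
    asm2 = _SeqAssembler(rng, forbidden_2)
    asm2.add_random(30)
    asm2.add_fixed(shared_fwd)
    asm2.add_random(100)
    cds2_asm = _SeqAssembler(rng, forbidden_2)
    cds2_asm.add_codons(502, _SAFE_AT_POOL, _H1_2_CODONS)
    cds2 = cds2_asm.seq()
    intron = _SeqAssembler(rng, forbidden_2)
    intron.add_random(150)
    down2 = _SeqAssembler(rng, forbidden_2)
    down2.add_random(94)
    down2.add_fixed(outer_rev_block, check=False)
    down2.add_random(77)
    seq2 = asm2.seq() + cds2[:1000] + intron.seq() + cds2[1000:] + down2.seq()
    gm2 = GeneModel("h1-2", "A", seq2, 150, [(151, 1150), (1301, 1806)])

    def scheme(gm, rev_start, rev_len=20):
        return NestedScheme(
            outer_fwd=Primer("h1-outer-f", shared_fwd, "forward"),
            outer_rev=Primer("h1-outer-r", _rc(outer_rev_block), "reverse"),
            inner_fwd=Primer("h1-inner-f", shared_fwd, "forward"),
            inner_rev=Primer(f"{gm.gene_id}-inner-r",
                             _rc(gm.locus_seq[rev_start - 1 : rev_start - 1 + rev_len]),
                             "reverse"),
        )

    schemes = {"h1-1": scheme(gm1, 2222), "h1-2": scheme(gm2, 1677)}
    return gm1, gm2, schemes


def _build_fad2(rng) -> tuple[GeneModel, GeneModel, dict]:
    forbidden = _SIX_CUTTERS
    asm = _SeqAssembler(rng, forbidden)
    asm.add_random(331)
    asm.add_codons(380, _RANDOM_POOL, _FAD2B_CODONS)
    asm.add_random(129)
    seq_b = asm.seq()
    gm_b = GeneModel("fad2b", "B", seq_b, 331, [(332, 1471)])

    ins = _SeqAssembler(rng, forbidden)
    ins.add_random(19)
    seq_a = seq_b[:252] + ins.seq() + seq_b[252:]
    # A copy: Asn150 (inactive desaturase) instead of the B copy's Asp150
    assert seq_a[797] == "G"
    seq_a = seq_a[:797] + "A" + seq_a[798:]
    gm_a = GeneModel("fad2a", "A", seq_a, 350, [(351, 1490)])

    def primer(name, seq, orientation):
        return Primer(name, seq, orientation)

    rev_inner = primer("fad2-inner-r", _rc(seq_b[1439:1463]), "reverse")
    rev_outer = primer("fad2-outer-r", _rc(seq_b[1471:1495]), "reverse")
    schemes = {
        "fad2a": NestedScheme(
            outer_fwd=primer("fad2a-outer-f", seq_a[234:258], "forward"),
            outer_rev=rev_outer,
            inner_fwd=primer("fad2a-inner-f", seq_a[254:278], "forward"),
            inner_rev=rev_inner,
        ),
        "fad2b": NestedScheme(
            outer_fwd=primer("fad2b-outer-f", seq_b[230:254], "forward"),
            outer_rev=rev_outer,
            inner_fwd=primer("fad2b-inner-f", seq_b[242:266], "forward"),
            inner_rev=rev_inner,
        ),
    }
    return gm_a, gm_b, schemes


def _build_southern(rng, gm1: GeneModel, gm2: GeneModel) -> restriction.SouthernLayout:
    """Two-copy genomic layout with genomic background restriction sites."""
    forbidden = _SIX_CUTTERS

    def flank_left():
        a = _SeqAssembler(rng, forbidden)
        a.add_random(2499); a.add_fixed("GAATTC", check=False)
        a.add_random(94); a.add_fixed("ATTAAT", check=False)
        a.add_random(389); a.add_fixed("AAGCTT", check=False)
        a.add_random(3000)
        return a.seq()

    def spacer():
        a = _SeqAssembler(rng, forbidden)
        a.add_random(1194); a.add_fixed("AAGCTT", check=False)
        a.add_random(1199); a.add_fixed("GAATTC", check=False)
        a.add_random(194); a.add_fixed("ATTAAT", check=False)
        a.add_random(3395)
        return a.seq()

    def flank_right():
        a = _SeqAssembler(rng, forbidden)
        a.add_random(294); a.add_fixed("AAGCTT", check=False)
        a.add_random(3099); a.add_fixed("GAATTC", check=False)
        a.add_random(494); a.add_fixed("ATTAAT", check=False)
        a.add_random(2095)
        return a.seq()

    fl, sp, fr = flank_left(), spacer(), flank_right()
    seq = fl + gm1.locus_seq + sp + gm2.locus_seq + fr
    span1 = (len(fl) + 1, len(fl) + len(gm1))
    span2 = (span1[1] + len(sp) + 1, span1[1] + len(sp) + len(gm2))
    return restriction.SouthernLayout(seq=seq, probe_spans=(span1, span2))


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _verify_fixtures(fx: "BenchmarkFixtures") -> None:
    # amplicon lengths via the nested scheme, and nested == direct inner
    for gid, expected in AMPLICON_LENGTHS.items():
        gm = fx.genes[gid]
        sch = fx.schemes[gid]
        amp = pcr.nested_amplify(gm, (sch.outer_fwd, sch.outer_rev),
                                 (sch.inner_fwd, sch.inner_rev))
        if amp.length != expected:
            raise FixtureBuildError(f"{gid}: amplicon {amp.length} != {expected}")
        direct = pcr.amplify(gm, sch.inner_fwd, sch.inner_rev)
        if len(direct) != 1 or direct[0] != amp:
            raise FixtureBuildError(f"{gid}: nested and direct amplification differ")
        fx.amplicons[gid] = amp
    # copy-specificity of the inner pairs
    for fam, pair in fx.pairs.items():
        for gm in pair.copies():
            sch = fx.schemes[gm.gene_id]
            rep = pcr.check_specificity(pair, sch.inner_fwd, sch.inner_rev)
            if not rep.passed or rep.amplified_copies() != [gm.gene_id]:
                raise FixtureBuildError(f"{gm.gene_id}: inner primers not copy-specific")
    # the common outer pairs co-amplify both copies (the agarose doublet)
    for fam in ("h1", "h2"):
        pair = fx.pairs[fam]
        sch = fx.schemes[pair.copy_a.gene_id]
        for gm in pair.copies():
            if len(pcr.amplify(gm, sch.outer_fwd, sch.outer_rev)) != 1:
                raise FixtureBuildError(f"{fam}: outer pair fails on {gm.gene_id}")
    # reference bases under every mutation row
    for row in fx.mutations.itertuples():
        gm = fx.genes[row.gene_id]
        if gm.base_at(anchored_to_locus(row.anchored_pos, gm)) != row.ref:
            raise FixtureBuildError(
                f"{row.gene_id}:{row.anchored_pos} ref is not {row.ref}")
    # BslI geometry on the B-copy vicilin-like amplicon
    bsl = restriction.BUILTIN_ENZYMES["BslI"]
    amp = fx.amplicons["h1-2"]
    sites = restriction.find_sites(amp.seq, bsl)
    if sites != _BSLI_SITE_STARTS_AMP:
        raise FixtureBuildError(f"BslI sites {sites} != {_BSLI_SITE_STARTS_AMP}")
    if restriction.digest(amp.seq, bsl) != _BSLI_WT_FRAGMENTS:
        raise FixtureBuildError("BslI wild-type digest mismatch")
    mut_off = anchored_to_locus(304, fx.genes["h1-2"]) - amp.start + 1
    mut_seq = restriction.apply_substitution(amp.seq, mut_off, "T")
    if restriction.digest(mut_seq, bsl) != _BSLI_MUT_FRAGMENTS:
        raise FixtureBuildError("BslI mutant digest mismatch")
    # six-cutter occurrences are exactly the engineered ones
    expected_sites = {
        "EcoRI": [2500, 8043, 11000, 16248, 20000],
        "HindIII": [2995, 9795, 16895],
        "AseI": [2600, 7060, 7100, 11200, 20500],
    }
    for name, exp in expected_sites.items():
        got = restriction.find_sites(fx.southern.seq, restriction.BUILTIN_ENZYMES[name])
        if got != exp:
            raise FixtureBuildError(f"{name} sites {got} != {exp}")
    # no in-frame internal ATG in the start-loss fixture gene
    cds = fx.genes["h2-2"].cds_seq()
    if any(cds[i : i + 3] == "ATG" for i in range(3, len(cds), 3)):
        raise FixtureBuildError("h2-2 carries an internal in-frame ATG")
    # sanity: translated products
    for gm in fx.genes.values():
        aa = translate(gm.cds_seq())
        if aa[0] != "M" or aa[-1] != "*":
            raise FixtureBuildError(f"{gm.gene_id}: malformed CDS translation")


@functools.lru_cache(maxsize=1)
def benchmark_fixtures() -> BenchmarkFixtures:
    """Build (deterministically) the benchmark gene pairs and mutation table.

    The builder retries with fresh random substreams if a junction between
    random background and an engineered element happens to create a spurious
    motif; the verification pass at the end guarantees every engineered
    property holds in the returned object.
    """
    last_err = None
    for attempt in range(25):
        rng = np.random.default_rng(_FIXTURE_SEED + attempt)
        try:
            h2_1, h2_2, h2_schemes = _build_h2(rng)
            h1_1, h1_2, h1_schemes = _build_h1(rng)
            fad2a, fad2b, fad2_schemes = _build_fad2(rng)
            pairs = {
                "h2": HomeologPair("h2", copy_a=h2_1, copy_b=h2_2,
                                   discriminating_features=[(-140, "substitution", 176)]),
                "h1": HomeologPair("h1", copy_a=h1_2, copy_b=h1_1,
                                   discriminating_features=[(1527, "substitution", 20)]),
                "fad2": HomeologPair("fad2", copy_a=fad2a, copy_b=fad2b,
                                     discriminating_features=[(-80, "indel", 19)]),
            }
            genes = {gm.gene_id: gm for gm in
                     (h2_1, h2_2, h1_1, h1_2, fad2a, fad2b)}
            southern = _build_southern(rng, h1_1, h1_2)
            fx = BenchmarkFixtures(
                genes=genes,
                pairs=pairs,
                schemes={**h2_schemes, **h1_schemes, **fad2_schemes},
                amplicons={},
                mutations=benchmark_mutation_table(),
                southern=southern,
            )
            _verify_fixtures(fx)
            return fx
        except FixtureBuildError as err:  # pragma: no cover - rare path
            last_err = err
            logger.info("fixture build attempt %d failed: %s", attempt, err)
    raise FixtureBuildError(f"could not build fixtures: {last_err}")


def population_from_table(fx: BenchmarkFixtures | None = None,
                          group_sizes: dict | None = None) -> Population:
    """An M2 population carrying exactly the confirmed-mutation table.

    Each plant named in the table becomes one (heterozygous) carrier in its
    treatment group; all other individuals are wild type.  With the default
    group sizes this is the screened population: 2441 + 979 individuals.
    """
    if fx is None:
        fx = benchmark_fixtures()
    if group_sizes is None:
        group_sizes = {TREATMENT_04: 2441, TREATMENT_12: 979}
    individuals: list[Individual] = []
    index: dict[tuple, Individual] = {}
    counters = {g: 0 for g in group_sizes}
    for g, n in group_sizes.items():
        tag = "A" if g == TREATMENT_04 else "B"
        for i in range(n):
            ind = Individual(id=f"{tag}-{i + 1:04d}", group=g)
            individuals.append(ind)
    by_group = {g: [ind for ind in individuals if ind.group == g] for g in group_sizes}
    for row in fx.mutations.itertuples():
        key = (row.group, row.population, row.plant_id)
        if key not in index:
            index[key] = by_group[row.group][counters[row.group]]
            counters[row.group] += 1
        ind = index[key]
        gm = fx.genes[row.gene_id]
        pos = anchored_to_locus(row.anchored_pos, gm)
        ind.genotype[(row.gene_id, pos)] = Variant(row.ref, row.alt, row.kind, "het")
    return Population(individuals=individuals, params=None, loci=fx.gene_list())
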