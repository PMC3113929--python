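"""The screening engine: pooling, heteroduplex cleavage, detection, deconvolution.

Samples are pooled four-fold in 96-well plates and amplified with nested,
end-labeled primers.  Re-annealing the pooled amplicons forms heteroduplexes
wherever two alleles segregate in a pool; a single-strand-specific nuclease
(CEL1) cleaves at the mismatch, and the two labeled cleavage products appear
in separate detection channels (700 for the 5'-labeled strand, 800 for the
3').  A putative mutation is a pair of fragments, one per channel, whose
sizes sum to the full amplicon length, outside the ~100-bp gel edges that
cannot be scored.  Pool hits are deconvoluted by re-screening each member
alone and mixed 1:1 with wild-type DNA, which also calls zygosity:
heterozygotes are positive either way, homozygotes only in the mixed sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import insilico_pcr as pcr
from .genemodels import locus_to_anchored
from .insilico_pcr import Amplicon
from .popsim import Individual, Population, Variant
from .stats import ScreenTally

__all__ = [
    "Pool",
    "CleavageSignal",
    "DetectionCall",
    "InconsistencyError",
    "make_pools",
    "heteroduplex_sites",
    "cleavage_signals",
    "detect",
    "deconvolute",
    "run_screen",
    "DEFAULT_EDGE",
]

DEFAULT_EDGE = 100  # bp at each gel edge that cannot be scored


class InconsistencyError(RuntimeError):
    """A pool hit that no pool member explains (bookkeeping bug)."""


@dataclass(frozen=True)
class Pool:
    well_id: str
    member_ids: tuple

    def __post_init__(self):
        if not 1 <= len(self.member_ids) <= 4:
            raise ValueError("pools hold 1-4 members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("pool members must be unique")


@dataclass(frozen=True)
class CleavageSignal:
    channel: int  # 700 | 800
    size: float


@dataclass(frozen=True)
class DetectionCall:
    amplicon_id: str
    cut_position: int  # bp from the 5'-labeled end
    source_id: str  # pool well or individual id
    zygosity: str = "unknown"


_ROWS = "ABCDEFGH"


def make_pools(population: Population, pool_size: int = 4) -> list[Pool]:
    """Partition individuals, in input order, into consecutive pools.

    Wells are labeled plate-major: plate 1 fills A1..A12, B1..B12, ... H12
    before plate 2 begins.  The last pool may be smaller than ``pool_size``.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    pools = []
    inds = population.individuals
    for k, start in enumerate(range(0, len(inds), pool_size)):
        plate, well = divmod(k, 96)
        row, col = divmod(well, 12)
        pools.append(Pool(
            well_id=f"{plate + 1}-{_ROWS[row]}{col + 1}",
            member_ids=tuple(ind.id for ind in inds[start : start + pool_size]),
        ))
    return pools


def _haplotype_alleles(members: list[Individual], gene_id: str, site: int,
                       include_wt: bool) -> set:
    """Distinct alleles present among the pooled amplicon haplotypes at a site."""
    alleles = set()
    for ind in members:
        var = ind.genotype.get((gene_id, site))
        if var is None:
            alleles.add(("ref", ""))
        else:
            alleles.add((var.kind, var.alt))
            if var.zygosity == "het":
                alleles.add(("ref", ""))
    if include_wt:
        alleles.add(("ref", ""))
    return alleles


def _signal_site(pos: int, var: Variant) -> int:
    """Locus position of the first changed base of the mismatch bubble."""
    if var.kind == "insertion":
        return pos + 1
    return pos


def heteroduplex_sites(members: list[Individual], gene_id: str, amplicon: Amplicon,
                       include_wt: bool = False) -> list[int]:
    """Locus positions within the amplicon where >= 2 distinct alleles segregate.

    Heterozygous members contribute both alleles, homozygous mutants only
    the alt allele; ``include_wt`` adds reference haplotypes, modeling a
    1:1 mix with wild-type DNA.  A homozygote screened alone is invisible —
    every duplex is a perfect homoduplex.
    """
    candidate_sites = {}
    for ind in members:
        for (gid, pos), var in ind.genotype.items():
            if gid != gene_id:
                continue
            site = _signal_site(pos, var)
            if amplicon.start <= site <= amplicon.end:
                candidate_sites.setdefault(pos, site)
    cleavable = []
    for pos, site in candidate_sites.items():
        if len(_haplotype_alleles(members, gene_id, pos, include_wt)) >= 2:
            cleavable.append(site)
    return sorted(set(cleavable))


def cleavage_signals(site: int, amplicon: Amplicon, size_noise: float = 0.0,
                     rng: np.random.Generator | None = None) -> tuple[CleavageSignal, CleavageSignal]:
    """Dual-channel fragment sizes for one cleaved site.

    The 5'-labeled strand reports the distance d from the amplicon start,
    the 3'-labeled strand its complement L − d; the two always sum to the
    full product length.
    """
    if not amplicon.start <= site <= amplicon.end:
        raise ValueError(f"site {site} outside amplicon {amplicon.start}..{amplicon.end}")
    d = site - amplicon.start + 1
    L = amplicon.length
    a, b = float(d), float(L - d)
    if size_noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        a = round(a + rng.normal(0, size_noise))
        b = round(b + rng.normal(0, size_noise))
    return CleavageSignal(700, a), CleavageSignal(800, b)


def detect(signals: list[CleavageSignal], L: int, edge: int = DEFAULT_EDGE,
           amplicon_id: str = "", source_id: str = "") -> list[DetectionCall]:
    """Apply the both-channels-sum rule with edge exclusion.

    One call per (700-size a, 800-size b) pair with a + b = L and
    edge < a < L − edge; unpaired signals are ignored.  Calls at mirrored
    positions d and L − d co-migrate pairwise on a gel and are flagged with
    a warning, since real gels cannot establish the pairing.
    """
    if edge < 0:
        raise ValueError("edge must be >= 0")
    sizes700 = {int(s.size) for s in signals if s.channel == 700 and float(s.size).is_integer()}
    sizes800 = {int(s.size) for s in signals if s.channel == 800 and float(s.size).is_integer()}
    calls = []
    for a in sorted(sizes700):
        if (L - a) in sizes800 and edge < a < L - edge:
            calls.append(DetectionCall(amplicon_id=amplicon_id, cut_position=a,
                                       source_id=source_id))
    positions = {c.cut_position for c in calls}
    mirrored = sorted(d for d in positions if (L - d) in positions and d < L - d)
    if mirrored:
        warnings.warn(
            f"co-migrating symmetric cut positions {mirrored} in {amplicon_id or 'amplicon'}; "
            "gel fragment pairing is ambiguous", stacklevel=2)
    return calls


def deconvolute(pool_hit: DetectionCall, members: list[Individual], gene_id: str,
                amplicon: Amplicon) -> list[tuple[str, str]]:
    """Identify which pool members carry the variant behind a pool hit.

    Each member is re-screened alone and mixed 1:1 with wild type: positive
    in both → heterozygous; positive only mixed → homozygous.  Raises
    :class:`InconsistencyError` when no member explains the hit.
    """
    site = amplicon.start + pool_hit.cut_position - 1
    carriers = []
    for ind in members:
        alone = site in heteroduplex_sites([ind], gene_id, amplicon, include_wt=False)
        mixed = site in heteroduplex_sites([ind], gene_id, amplicon, include_wt=True)
        if alone and mixed:
            carriers.append((ind.id, "het"))
        elif mixed:
            carriers.append((ind.id, "hom"))
    if not carriers:
        raise InconsistencyError(
            f"pool {pool_hit.source_id}: no member explains the hit at "
            f"cut position {pool_hit.cut_position}")
    return carriers


def run_screen(population: Population, genes: dict, schemes: dict,
               pool_size: int = 4, edge: int = DEFAULT_EDGE,
               size_noise: float = 0.0, rng_seed: int = 0):
    """Run the full screen: amplify, pool, cleave, detect, deconvolute.

    Returns ``(records, tally)`` where ``records`` is a DataFrame with one
    confirmed row per (individual, gene, site) and ``tally`` the
    :class:`~polytill.stats.ScreenTally` feeding frequency estimation.
    """
    rng = np.random.default_rng(rng_seed)
    amplicons = {}
    for gid, gm in genes.items():
        sch = schemes[gid]
        amplicons[gid] = pcr.nested_amplify(
            gm, (sch.outer_fwd, sch.outer_rev), (sch.inner_fwd, sch.inner_rev))
    pools = make_pools(population, pool_size)
    rows = []
    for pool in pools:
        members = [population.by_id(mid) for mid in pool.member_ids]
        for gid, amp in amplicons.items():
            sites = heteroduplex_sites(members, gid, amp)
            if not sites:
                continue
            signals = []
            for site in sites:
                signals.extend(cleavage_signals(site, amp, size_noise, rng))
            calls = detect(signals, amp.length, edge=edge,
                           amplicon_id=gid, source_id=pool.well_id)
            for call in calls:
                site = amp.start + call.cut_position - 1
                for ind_id, zyg in deconvolute(call, members, gid, amp):
                    ind = population.by_id(ind_id)
                    # the cut site may sit one base 3' of an insertion point
                    var = ind.genotype.get((gid, site))
                    pos = site
                    if var is None:
                        var = ind.genotype.get((gid, site - 1))
                        pos = site - 1
                    rows.append({
                        "individual": ind_id,
                        "group": ind.group,
                        "gene_id": gid,
                        "locus_pos": pos,
                        "anchored_pos": locus_to_anchored(pos, genes[gid]),
                        "ref": var.ref,
                        "alt": var.alt,
                        "kind": var.kind,
                        "zygosity": zyg,
                        "pool_well": pool.well_id,
                        "cut_position": call.cut_position,
                    })
    records = pd.DataFrame(
        rows,
        columns=["individual", "group", "gene_id", "locus_pos", "anchored_pos",
                 "ref", "alt", "kind", "zygosity", "pool_well", "cut_position"],
    ).drop_duplicates(subset=["individual", "gene_id", "locus_pos"]).reset_index(drop=True)
    tally = tally_from_records(records, population, amplicons)
    return records, tally


def tally_from_records(records: pd.DataFrame, population: Population,
                       amplicons: dict) -> ScreenTally:
    group_order = list(dict.fromkeys(ind.group for ind in population.individuals))
    group_sizes = {g: sum(1 for ind in population.individuals if ind.group == g)
                   for g in group_order}
    groups = []
    for g in group_order:
        sub = records[records["group"] == g] if len(records) else records
        counts = {gid: int((sub["gene_id"] == gid).sum()) if len(records) else 0
                  for gid in amplicons}
        groups.append((g, group_sizes[g], counts))
    return ScreenTally(
        amplicons=[(gid, amp.length) for gid, amp in sorted(amplicons.items())],
        groups=groups,
    )


def write_confirmed_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
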