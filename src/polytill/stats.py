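"""Mutation-frequency estimation with gel-edge correction.

The screening-effort statistic is kb/SNP: kilobases effectively screened
per confirmed mutation,

    kb/SNP = sum_g (L_g - 200) * N / n / 1000,

where L_g are the amplicon lengths, N the individuals screened (each
screened for every amplicon), and n the confirmed mutation count.  200 bp
is subtracted per amplicon because the ~100-bp regions at the top and
bottom of the gel image cannot be scored.  Reported values are rounded to
the nearest integer kb with the exact bp value retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ScreenTally",
    "FrequencyReport",
    "DensityEstimate",
    "EDGE_CORRECTION_BP",
    "effective_bp",
    "kb_per_snp",
    "table1_report",
]

EDGE_CORRECTION_BP = 200  # 100 bp excluded at each amplicon end


def effective_bp(L: int) -> int:
    """Effectively screened bases of one amplicon: L − 200."""
    if L <= EDGE_CORRECTION_BP:
        raise ValueError(
            f"amplicon of {L} bp has no screenable interior "
            f"(needs > {EDGE_CORRECTION_BP} bp)")
    return L - EDGE_CORRECTION_BP


@dataclass(frozen=True)
class DensityEstimate:
    """A kb/SNP mutation-density estimate."""

    bp_per_snp: float | None
    kb_per_snp: int | None  # rounded to nearest integer kb
    n_mutations: int
    n_individuals: int
    effective_bp_per_individual: int

    @property
    def defined(self) -> bool:
        return self.bp_per_snp is not None


def kb_per_snp(effective_bp_per_individual: int, n_individuals: int,
               n_mutations: int) -> DensityEstimate:
    """Density from totals; zero mutations gives an undefined (NA) estimate."""
    if n_mutations < 0 or n_individuals < 0:
        raise ValueError("counts must be non-negative")
    if n_mutations == 0:
        return DensityEstimate(None, None, 0, n_individuals,
                               effective_bp_per_individual)
    bp = effective_bp_per_individual * n_individuals / n_mutations
    return DensityEstimate(
        bp_per_snp=bp,
        kb_per_snp=int(round(bp / 1000)),
        n_mutations=n_mutations,
        n_individuals=n_individuals,
        effective_bp_per_individual=effective_bp_per_individual,
    )


@dataclass
class ScreenTally:
    """Per-amplicon lengths and per-group screening results.

    amplicons
        list of (gene_id, amplicon length in bp).
    groups
        list of (group label, individuals screened, {gene_id: confirmed
        mutation count}).
    """

    amplicons: list = field(default_factory=list)
    groups: list = field(default_factory=list)

    def __post_init__(self):
        for _, L in self.amplicons:
            effective_bp(L)  # validates L > 200
        for _, n, counts in self.groups:
            if n < 0 or any(c < 0 for c in counts.values()):
                raise ValueError("screened/mutation counts must be >= 0")

    @property
    def effective_bp_per_individual(self) -> int:
        return sum(effective_bp(L) for _, L in self.amplicons)

    @property
    def total_bp_per_individual(self) -> int:
        return sum(L for _, L in self.amplicons)

    def group_labels(self) -> list:
        return [g for g, _, _ in self.groups]

    def n_individuals(self, groups=None) -> int:
        return sum(n for g, n, _ in self.groups if groups is None or g in groups)

    def n_mutations(self, groups=None, genes=None) -> int:
        total = 0
        for g, _, counts in self.groups:
            if groups is not None and g not in groups:
                continue
            for gid, c in counts.items():
                if genes is None or gid in genes:
                    total += c
        return total

    def density(self, groups=None, n_mutations=None) -> DensityEstimate:
        """kb/SNP over the selected groups.

        ``n_mutations`` overrides the tallied count — e.g. to estimate the
        density of canonical G:C→A:T transitions only, pass the filtered
        count from :func:`polytill.annotate.spectrum_summary`.
        """
        n = self.n_mutations(groups) if n_mutations is None else n_mutations
        return kb_per_snp(self.effective_bp_per_individual,
                          self.n_individuals(groups), n)


@dataclass
class FrequencyReport:
    table: pd.DataFrame
    per_group: dict  # group label -> DensityEstimate
    overall: DensityEstimate


def table1_report(tally: ScreenTally) -> FrequencyReport:
    """Amplicon-by-group summary: lengths, counts, totals, and kb/SNP rows."""
    labels = tally.group_labels()
    rows = []
    for gid, L in tally.amplicons:
        row = {"gene": gid, "amplicon_bp": L, "screened_bp": effective_bp(L)}
        for g, _, counts in tally.groups:
            row[g] = counts.get(gid, 0)
        row["total"] = sum(counts.get(gid, 0) for _, _, counts in tally.groups)
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        totals = {"gene": "Total",
                  "amplicon_bp": tally.total_bp_per_individual,
                  "screened_bp": tally.effective_bp_per_individual}
        for g in labels:
            totals[g] = tally.n_mutations([g])
        totals["total"] = tally.n_mutations()
        screened = {"gene": "Plants Screened", "amplicon_bp": None, "screened_bp": None,
                    **{g: tally.n_individuals([g]) for g in labels},
                    "total": tally.n_individuals()}
        per_group = {g: tally.density([g]) for g in labels}
        overall = tally.density()
        kbrow = {"gene": "kb/SNP", "amplicon_bp": None, "screened_bp": None,
                 **{g: per_group[g].kb_per_snp for g in labels},
                 "total": overall.kb_per_snp}
        table = pd.concat([table, pd.DataFrame([totals, screened, kbrow])],
                          ignore_index=True)
    else:
        per_group, overall = {}, kb_per_snp(0 if not tally.amplicons else
                                            tally.effective_bp_per_individual, 0, 0)
    return FrequencyReport(table=table, per_group=per_group, overall=overall)
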