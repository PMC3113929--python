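"""Model/Results interface over the screening pipeline.

:class:`TillingScreen` bundles a population, gene models and nested primer
schemes the way a statistical model bundles data and design; ``fit()`` runs
the in-silico screen and returns a :class:`TillingScreenResults` carrying
the confirmed-mutation table, the per-group tallies, kb/SNP density
estimates with their Poisson sampling scatter, the mutation-spectrum
breakdown, and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import annotate, celscreen, stats
from .popsim import BenchmarkFixtures, Population, benchmark_fixtures

__all__ = ["TillingScreen", "TillingScreenResults"]


class TillingScreen:
    """An in-silico TILLING screen of a population over a set of gene targets.

    Parameters
    ----------
    population : Population
        M2 individuals with genotypes (simulated or transcribed).
    genes : dict[str, GeneModel]
        Targets, keyed by gene id.
    schemes : dict[str, NestedScheme]
        Nested primer scheme per gene.
    pool_size : int
        Individuals per screening well (4 in the standard protocol).
    edge : int
        Unscorable bp at each gel edge (drives the L − 200 correction).
    """

    def __init__(self, population: Population, genes: dict, schemes: dict,
                 pool_size: int = 4, edge: int = celscreen.DEFAULT_EDGE,
                 size_noise: float = 0.0):
        self.population = population
        self.genes = dict(genes)
        self.schemes = dict(schemes)
        self.pool_size = pool_size
        self.edge = edge
        self.size_noise = size_noise

    @classmethod
    def from_fixtures(cls, population: Population, fx: BenchmarkFixtures | None = None,
                      **kwargs) -> "TillingScreen":
        if fx is None:
            fx = benchmark_fixtures()
        return cls(population, fx.genes, fx.schemes, **kwargs)

    def fit(self, rng_seed: int = 0) -> "TillingScreenResults":
        records, tally = celscreen.run_screen(
            self.population, self.genes, self.schemes,
            pool_size=self.pool_size, edge=self.edge,
            size_noise=self.size_noise, rng_seed=rng_seed)
        return TillingScreenResults(model=self, records=records, tally=tally)


@dataclass
class TillingScreenResults:
    model: TillingScreen
    records: pd.DataFrame
    tally: stats.ScreenTally

    # -- estimates ----------------------------------------------------------

    def density(self, groups=None, canonical_only: bool = False) -> stats.DensityEstimate:
        n = None
        if canonical_only:
            n = self.spectrum()["n_canonical"]
        return self.tally.density(groups=groups, n_mutations=n)

    def density_se_kb(self) -> float | None:
        """Poisson standard error of the overall kb/SNP estimate (delta method)."""
        est = self.density()
        if not est.defined:
            return None
        return est.bp_per_snp / math.sqrt(est.n_mutations) / 1000

    def spectrum(self) -> dict:
        muts = [annotate.Mutation(r.gene_id, r.anchored_pos, r.ref, r.alt, r.kind)
                for r in self.records.itertuples()]
        return annotate.spectrum_summary(muts)

    def effects(self) -> pd.DataFrame:
        rows = []
        for r in self.records.itertuples():
            m = annotate.Mutation(r.gene_id, r.anchored_pos, r.ref, r.alt, r.kind)
            eff = annotate.classify(m, self.model.genes[r.gene_id])
            rows.append({
                "individual": r.individual, "gene_id": r.gene_id,
                "change": annotate.mutation_to_notation(m),
                "zygosity": r.zygosity, "effect": eff.effect_class,
                "codon": eff.codon_index, "wt_aa": eff.wt_aa, "mut_aa": eff.mut_aa,
            })
        return pd.DataFrame(rows)

    def frequency_report(self) -> stats.FrequencyReport:
        return stats.table1_report(self.tally)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        rep = self.frequency_report()
        spec = self.spectrum()
        overall = self.density()
        lines = [
            "In-silico TILLING screen",
            "=" * 64,
            f"Individuals screened: {self.tally.n_individuals()}  "
            f"(pool size {self.model.pool_size}, edge {self.model.edge} bp)",
            f"Amplicons: {len(self.tally.amplicons)}  "
            f"({self.tally.total_bp_per_individual} bp; "
            f"{self.tally.effective_bp_per_individual} bp effective/individual)",
            "",
            rep.table.to_string(index=False),
            "",
            f"Confirmed mutations: {len(self.records)} "
            f"({spec['n_canonical']} canonical G:C->A:T, "
            f"{spec['n_atypical']} atypical)",
        ]
        if overall.defined:
            se = self.density_se_kb()
            lines.append(
                f"Overall density: 1 SNP/{overall.kb_per_snp} kb "
                f"({overall.bp_per_snp:,.0f} bp; Poisson SE ~{se:,.0f} kb)")
            canon = self.density(canonical_only=True)
            if canon.defined:
                lines.append(
                    f"Canonical-only density: 1 SNP/{canon.kb_per_snp} kb")
        else:
            lines.append("Overall density: undefined (no confirmed mutations)")
        return "\n".join(lines)
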