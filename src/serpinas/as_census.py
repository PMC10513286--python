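"""Alternative-splicing census: terminal-diversity counts per gene,
localization classes, AS / multi-domain / non-AS partition, and attribution
of total protein/domain diversity to AS, gene duplication and domain
duplication.

Unit rule: an AS gene (C-terminal AS, single domain) contributes its count of
distinct C-terminal forms; a multi-domain gene contributes its domain count;
every remaining gene — presumed to have arisen by gene duplication —
contributes one unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import phylo_stats
from .gene_models import GeneModel

log = logging.getLogger(__name__)

SET_AS = "AS"
SET_MULTIDOMAIN = "MULTIDOMAIN"
SET_NONAS = "NONAS"


class CensusValidationError(ValueError):
    """Raised when a gene claims both C-terminal AS and multiple domains."""


def count_terminal_as(gene: GeneModel) -> tuple:
    """Number of distinct first-20-aa and last-50-aa sequences among a
    gene's isoforms — the operational definition of N- and C-terminal AS
    event counts."""
    if not gene.isoforms:
        raise ValueError(f"gene {gene.id} has no isoforms")
    n = len({iso.n_terminus_key for iso in gene.isoforms})
    c = len({iso.c_terminus_key for iso in gene.isoforms})
    return n, c


def classify_localization(gene: GeneModel) -> str:
    """extracellular / intracellular / both / unknown from signal-peptide
    calls over the gene's distinct N-terminal forms."""
    calls = {}
    for iso in gene.isoforms:
        if iso.has_signal_peptide is not None:
            calls.setdefault(iso.n_terminus_key, set()).add(iso.has_signal_peptide)
    if not calls:
        return "unknown"
    flat = set().union(*calls.values())
    if flat == {True}:
        return "extracellular"
    if flat == {False}:
        return "intracellular"
    return "both"


def build_census(genes, validate: bool = True) -> pd.DataFrame:
    """One row per gene: AS counts, localization, domain count and set
    label.  Genes with both C-terminal AS and multiple domains violate the
    observed mutual exclusivity and raise :class:`CensusValidationError`
    (they are flagged, never silently reassigned)."""
    rows = []
    conflicts = []
    for gene in genes:
        n_as, c_as = count_terminal_as(gene)
        if c_as > 1 and gene.domain_count > 1:
            conflicts.append(gene.id)
            label = "CONFLICT"
        elif gene.domain_count > 1:
            label = SET_MULTIDOMAIN
        elif c_as > 1:
            label = SET_AS
        else:
            label = SET_NONAS
        rows.append(
            dict(
                gene_id=gene.id,
                species=gene.species,
                genus=gene.genus,
                lifestyle=gene.lifestyle,
                n_as_count=n_as,
                c_as_count=c_as,
                localization=classify_localization(gene),
                domain_count=gene.domain_count,
                set_label=label,
            )
        )
    if conflicts and validate:
        raise CensusValidationError(
            "genes with both C-terminal AS and multiple domains: "
            + ", ".join(conflicts)
        )
    return pd.DataFrame(rows)


@dataclass
class DiversityAttribution:
    total_units: int
    as_units: int
    gd_units: int
    domain_units: int

    @property
    def shares(self) -> tuple:
        t = self.total_units
        return (self.as_units / t, self.gd_units / t, self.domain_units / t)

    def shares_pct(self, digits: int = 1) -> tuple:
        """Percentages with half-up rounding at the given precision."""
        return tuple(round_half_up(100.0 * s, digits) for s in self.shares)


def round_half_up(x: float, digits: int = 1) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def attribute_diversity(census: pd.DataFrame) -> DiversityAttribution:
    """Exact integer bookkeeping of protein/domain units per source."""
    if (census["set_label"] == "CONFLICT").any():
        bad = census.loc[census.set_label == "CONFLICT", "gene_id"].tolist()
        raise CensusValidationError(f"unresolved AS/multi-domain conflicts: {bad}")
    as_units = int(census.loc[census.set_label == SET_AS, "c_as_count"].sum())
    gd_units = int((census.set_label == SET_NONAS).sum())
    domain_units = int(
        census.loc[census.set_label == SET_MULTIDOMAIN, "domain_count"].sum()
    )
    return DiversityAttribution(
        total_units=as_units + gd_units + domain_units,
        as_units=as_units,
        gd_units=gd_units,
        domain_units=domain_units,
    )


def clade_summary(census: pd.DataFrame) -> dict:
    """Headline percentages for the clade: share of genes with C-terminal AS,
    with N-terminal AS, with either, and per-gene means of the AS and
    multi-domain sets."""
    n = len(census)
    as_rows = census[census.set_label == SET_AS]
    md_rows = census[census.set_label == SET_MULTIDOMAIN]
    n_term = census[census.n_as_count > 1]
    either = census[(census.n_as_count > 1) | (census.c_as_count > 1)]
    out = {
        "n_genes": n,
        "pct_c_terminal_as": round_half_up(
            100.0 * int((census.c_as_count > 1).sum()) / n) if n else float("nan"),
        "pct_n_terminal_as": round_half_up(100.0 * len(n_term) / n) if n else float("nan"),
        "pct_any_terminal_as": round_half_up(100.0 * len(either) / n) if n else float("nan"),
        "n_both_localization": int((n_term.localization == "both").sum()),
        "mean_variants_per_as_gene": float(as_rows.c_as_count.mean()) if len(as_rows) else float("nan"),
        "mean_domains_per_multidomain_gene": float(md_rows.domain_count.mean()) if len(md_rows) else float("nan"),
    }
    return out


def species_summary(census: pd.DataFrame) -> pd.DataFrame:
    """Per-species table: gene copy number, % C-terminal-AS genes, mean
    C-terminal AS count, and total protein/domain units.  Totals cross-check
    against :func:`attribute_diversity`."""
    def units(row):
        if row.set_label == SET_AS:
            return row.c_as_count
        if row.set_label == SET_MULTIDOMAIN:
            return row.domain_count
        return 1

    work = census.copy()
    work["units"] = work.apply(units, axis=1)
    grouped = work.groupby("species", sort=True)
    out = grouped.agg(
        copy_number=("gene_id", "count"),
        n_as_genes=("set_label", lambda s: int((s == SET_AS).sum())),
        mean_c_as=("c_as_count", "mean"),
        total_units=("units", "sum"),
        lifestyle=("lifestyle", "first"),
    ).reset_index()
    out["pct_as_genes"] = 100.0 * out.n_as_genes / out.copy_number
    return out


def lifestyle_comparison(species_table: pd.DataFrame) -> dict:
    """Compare parasitoid vs nonparasitoid species on total units, copy
    number, %AS genes and mean AS counts with two-sided Mann-Whitney U
    tests.  Species of unknown lifestyle are excluded (count logged)."""
    known = species_table[species_table.lifestyle.isin(["parasitoid", "nonparasitoid"])]
    dropped = len(species_table) - len(known)
    if dropped:
        log.info("lifestyle_comparison: %d unknown-lifestyle species excluded", dropped)
    groups = {k: v for k, v in known.groupby("lifestyle")}
    for name in ("parasitoid", "nonparasitoid"):
        if name not in groups or len(groups[name]) == 0:
            raise ValueError(f"lifestyle group {name!r} is empty")
    para, non = groups["parasitoid"], groups["nonparasitoid"]
    out = {"n_parasitoid": len(para), "n_nonparasitoid": len(non),
           "n_unknown_excluded": dropped, "metrics": {}}
    for metric in ("total_units", "copy_number", "pct_as_genes", "mean_c_as"):
        test = phylo_stats.mann_whitney_u(para[metric].values, non[metric].values)
        out["metrics"][metric] = {
            "parasitoid_median": float(para[metric].median()),
            "nonparasitoid_median": float(non[metric].median()),
            "difference": float(para[metric].median() - non[metric].median()),
            "W": test.statistic,
            "p_value": test.p_value,
        }
    return out
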