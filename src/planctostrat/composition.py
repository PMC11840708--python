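"""Target-phylum filtering, per-rank ASV composition tables and per-sample
relative abundances.

Composition tables count ASVs (not reads) per taxon label at a rank, with
unknown labels pooled under the reserved "Unknown" row; percentages use one
decimal, rounded half away from zero. Relative abundance divides the reads
assigned to each target-phylum taxon by the total reads of the sample
(computed on the unfiltered table) and multiplies by 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import RANKS, AsvTable, RankedTaxonomy

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "Unknown"


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionTable:
    """ASV counts and percentages per taxon label at one rank."""

    rank: str
    rows: tuple[tuple[str, int, float], ...]  # (taxon_label, n_asvs, pct_asvs)
    platform: str = ""

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        total_pct = sum(r[2] for r in self.rows)
        if self.rows and not 99.5 <= total_pct <= 100.5:
            raise ValueError(f"percentages sum to {total_pct}, outside [99.5, 100.5]")

    @property
    def total_asvs(self) -> int:
        return sum(r[1] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows), columns=["taxon", "n_asvs", "pct_asvs"]
        ).assign(rank=self.rank, platform=self.platform)

    def pct_of(self, taxon: str) -> float:
        for label, _, pct in self.rows:
            if label == taxon:
                return pct
        raise KeyError(taxon)


def filter_phylum(
    table: AsvTable,
    taxonomy: Mapping[str, RankedTaxonomy],
    phylum_label: str,
) -> tuple[AsvTable, tuple[int, int]]:
    """Restrict an ASV table to one phylum; returns (subset, (n_target, n_total)).

    An entirely absent phylum yields an empty table with a warning, not an
    error: downstream stages decide how to handle it.
    """
    for aid in table.asv_ids:
        if aid not in taxonomy:
            raise ValueError(f"ASV {aid!r} has no taxonomy")
    keep = [a for a in table.asv_ids if taxonomy[a].label_at("phylum") == phylum_label]
    if not keep:
        logger.warning("phylum %r absent from the table", phylum_label)
    return table.subset_asvs(keep), (len(keep), table.n_asvs)


def rank_composition(
    asv_taxonomies: Sequence[RankedTaxonomy],
    rank: str,
    platform: str = "",
) -> CompositionTable:
    """Tabulate ASV counts and percentages per taxon label at one rank.

    ASVs unknown at the rank fall under "Unknown" (listed last); labelled
    taxa are ordered by decreasing ASV count, then alphabetically.
    """
    if not asv_taxonomies:
        raise ValueError("empty taxonomy list")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    counts: dict[str, int] = {}
    for tax in asv_taxonomies:
        label = tax.label_at(rank) or UNKNOWN_LABEL
        counts[label] = counts.get(label, 0) + 1
    total = len(asv_taxonomies)
    labelled = sorted(
        ((l, n) for l, n in counts.items() if l != UNKNOWN_LABEL),
        key=lambda t: (-t[1], t[0]),
    )
    ordered = labelled + ([(UNKNOWN_LABEL, counts[UNKNOWN_LABEL])]
                          if UNKNOWN_LABEL in counts else [])
    rows = tuple(
        (label, n, round_half_away(100.0 * n / total, 1)) for label, n in ordered
    )
    return CompositionTable(rank=rank, rows=rows, platform=platform)


def relative_abundance(
    table: AsvTable,
    taxonomy: Mapping[str, RankedTaxonomy],
    rank: str,
    phylum_label: str = "Planctomycetota",
) -> pd.DataFrame:
    """Per-sample relative abundance (%) of each target-phylum taxon at a rank.

    The denominator is the total reads of the sample in the UNfiltered table,
    so per-sample values sum to the phylum's total relative abundance.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    totals = table.counts.sum(axis=1)
    zero = [table.sample_ids[i] for i in range(table.n_samples) if totals[i] == 0]
    if zero:
        raise ValueError(f"sample(s) with zero total reads: {zero}")

    target_idx: dict[str, list[int]] = {}
    for j, aid in enumerate(table.asv_ids):
        tax = taxonomy.get(aid)
        if tax is None:
            raise ValueError(f"ASV {aid!r} has no taxonomy")
        if tax.label_at("phylum") != phylum_label:
            continue
        label = tax.label_at(rank) or UNKNOWN_LABEL
        target_idx.setdefault(label, []).append(j)

    taxa = sorted(t for t in target_idx if t != UNKNOWN_LABEL)
    if UNKNOWN_LABEL in target_idx:
        taxa.append(UNKNOWN_LABEL)
    data = {
        taxon: 100.0 * table.counts[:, idx].sum(axis=1) / totals
        for taxon, idx in ((t, target_idx[t]) for t in taxa)
    }
    return pd.DataFrame(data, index=pd.Index(table.sample_ids, name="sample_id"))


def plot_relative_abundance(ra: pd.DataFrame, path, title: str = "") -> None:
    """Minimal stacked-bar rendering of a relative-abundance table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = ra.plot.bar(stacked=True, figsize=(9, 4), width=0.8)
    ax.set_ylabel("relative abundance (%)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()
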