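"""Marker-panel assembly: sequence panel, systematic chip, GWAS augmentation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import GenomeMap

__all__ = [
    "MarkerPanel",
    "build_sequence_panel",
    "build_chip_panel",
    "augment_panel",
]


@dataclass
class MarkerPanel:
    """An ordered subset of genome-map loci identified by locus id."""

    locus_ids: np.ndarray
    label: str

    def __post_init__(self):
        self.locus_ids = np.asarray(self.locus_ids, dtype=np.int64)
        if len(np.unique(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("panel locus ids must be unique")

    def __len__(self) -> int:
        return len(self.locus_ids)

    def indices_in(self, genome_map: GenomeMap) -> np.ndarray:
        """Row positions of the panel loci within ``genome_map`` (genome order)."""
        lookup = pd.Series(
            np.arange(len(genome_map)), index=genome_map.locus_ids
        )
        return np.sort(lookup.loc[self.locus_ids].to_numpy())


def _order_by_position(genome_map: GenomeMap, locus_ids: np.ndarray) -> np.ndarray:
    t = genome_map.table.set_index("locus_id").loc[locus_ids]
    cls_rank = (t["cls"] == "QTN").to_numpy().astype(int)  # SNP before QTN at ties
    order = np.lexsort((locus_ids, cls_rank, t["pos"].to_numpy(), t["chrom"].to_numpy()))
    return np.asarray(locus_ids)[order]


def build_sequence_panel(genome_map: GenomeMap, label: str = "SEQ") -> MarkerPanel:
    """All SNPs and QTN merged in genome order (ties: SNP first, then id)."""
    ids = genome_map.locus_ids
    pos_key = genome_map.table[["chrom", "pos"]].apply(tuple, axis=1)
    if pos_key.duplicated().any():
        warnings.warn("duplicate genome positions; tie-broken by (class, locus_id)")
    return MarkerPanel(_order_by_position(genome_map, ids), label)


def build_chip_panel(
    genome_map: GenomeMap, step: int = 10, label: str = "CHIP50K"
) -> MarkerPanel:
    """Every ``step``-th SNP in genome order, starting at the first; QTN excluded."""
    if step < 1:
        raise ValueError("step must be >= 1")
    snp_ids = genome_map.locus_ids[genome_map.snp_mask]
    return MarkerPanel(snp_ids[::step], label)


def augment_panel(
    chip: MarkerPanel,
    assoc,
    mode: str,
    v: int | None = None,
    genome_map: GenomeMap | None = None,
    label: str | None = None,
) -> MarkerPanel:
    """Union of a chip with GWAS-selected variants.

    mode="TOP": the ``v`` variants with the smallest p-values, irrespective of
    significance (p ties broken by genome position).  mode="SIG": every
    variant past the scan's significance threshold.
    """
    table = assoc.table
    if mode.upper() in ("TOP", "TOPV"):
        if v is None:
            raise ValueError("TOPv mode requires v")
        if v > len(table):
            raise ValueError(f"v={v} exceeds {len(table)} tested variants")
        order = np.lexsort(
            (table["pos"].to_numpy(), table["chrom"].to_numpy(), table["p"].to_numpy())
        )
        extra = table["locus_id"].to_numpy()[order[:v]]
        label = label or f"{chip.label}_TOP{v}"
    elif mode.upper() == "SIG":
        extra = table.loc[table["significant"], "locus_id"].to_numpy()
        label = label or f"{chip.label}_SIG"
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    union = np.unique(np.concatenate([chip.locus_ids, extra]))
    if genome_map is not None:
        union = _order_by_position(genome_map, union)
    return MarkerPanel(union, label)
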