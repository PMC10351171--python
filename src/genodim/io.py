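"""Readers and writers for the pipeline's on-disk formats.

Pedigrees, phenotypes and trait architectures are whitespace/tab-delimited
text; genotypes go to PLINK-text (.ped/.map, alleles coded 1/2) or VCF with
the genetic position carried in the map / INFO.  VCF reading uses cyvcf2.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simpop import GenomeMap, Population

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "read_phenotypes",
    "write_effects",
    "read_effects",
    "write_plink",
    "read_plink",
    "write_vcf",
    "read_vcf",
    "write_panel",
    "read_panel",
    "save_grm",
    "load_grm",
]

PED_COLUMNS = ["id", "sire", "dam", "generation", "sex"]


def write_pedigree(pop: Population, path) -> None:
    df = pop.pedigree[PED_COLUMNS]
    df.to_csv(path, sep=" ", header=False, index=False)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=PED_COLUMNS)


def write_phenotypes(phen, path) -> None:
    phen.table[["id", "phenotype", "tbv"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_effects(arch, path) -> None:
    pd.DataFrame({"locus_id": arch.qtn_ids, "beta": arch.beta}).to_csv(
        path, sep="\t", index=False
    )


def read_effects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _bp(pos_morgans: np.ndarray) -> np.ndarray:
    # 1 Morgan ~ 100 Mb gives unique-ish integer coordinates at any scale
    return np.rint(np.asarray(pos_morgans) * 1e8).astype(np.int64) + 1


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------


def write_plink(pop: Population, prefix, ids=None, loci=None) -> None:
    """Write <prefix>.ped / <prefix>.map for the given animals and loci."""
    gmap = pop.genome_map
    loci = np.arange(len(gmap)) if loci is None else np.asarray(loci)
    table = gmap.table.iloc[loci]
    mapdf = pd.DataFrame(
        {
            "chrom": table["chrom"].to_numpy(),
            "name": ["loc" + str(i) for i in table["locus_id"]],
            "cm": table["pos"].to_numpy(),
            "bp": _bp(table["pos"].to_numpy()),
        }
    )
    mapdf.to_csv(str(prefix) + ".map", sep="\t", header=False, index=False)

    ped = pop.pedigree.set_index("id")
    if ids is None:
        ids = pop.ids
    rows = pop.rows_of(ids)
    haps = pop.haplotypes[rows][:, :, loci]
    alleles = (haps + 1).astype("U1")  # 0/1 -> "1"/"2"
    with open(str(prefix) + ".ped", "w") as fh:
        for k, animal in enumerate(ids):
            rec = ped.loc[animal]
            head = [
                "0",
                str(animal),
                str(rec["sire"]),
                str(rec["dam"]),
                str(rec["sex"]),
                "-9",
            ]
            pairs = [a + " " + b for a, b in zip(alleles[k, 0], alleles[k, 1])]
            fh.write(" ".join(head + pairs) + "\n")


def read_plink(prefix):
    """Return (ids, dosage matrix, GenomeMap) from PLINK-text files."""
    mapdf = pd.read_csv(
        str(prefix) + ".map",
        sep=r"\s+",
        header=None,
        names=["chrom", "name", "cm", "bp"],
    )
    gmap = GenomeMap(
        pd.DataFrame(
            {
                "chrom": mapdf["chrom"],
                "pos": mapdf["cm"].astype(float),
                "locus_id": [int(n[3:]) for n in mapdf["name"]],
                "cls": "SNP",
            }
        )
    )
    ids, genos = [], []
    with open(str(prefix) + ".ped") as fh:
        for line in fh:
            parts = line.split()
            ids.append(int(parts[1]))
            allele = np.array(parts[6:], dtype="U1").astype(int) - 1
            genos.append(allele[0::2] + allele[1::2])
    return np.array(ids), np.array(genos, dtype=np.int16), gmap


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(pop: Population, path, ids=None, loci=None) -> None:
    """Minimal phased VCF 4.2; genetic position stored as INFO CM."""
    gmap = pop.genome_map
    loci = np.arange(len(gmap)) if loci is None else np.asarray(loci)
    table = gmap.table.iloc[loci]
    if ids is None:
        ids = pop.ids
    rows = pop.rows_of(ids)
    haps = pop.haplotypes[rows][:, :, loci]
    bp = _bp(table["pos"].to_numpy())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position, Morgans">\n')
        fh.write('##INFO=<ID=CLS,Number=1,Type=String,Description="Locus class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(table["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in ids)
            + "\n"
        )
        for j, (_, rec) in enumerate(table.iterrows()):
            gts = "\t".join(
                f"{haps[k, 0, j]}|{haps[k, 1, j]}" for k in range(len(ids))
            )
            fh.write(
                f"{rec['chrom']}\t{bp[j]}\tloc{rec['locus_id']}\tA\tC\t.\t.\t"
                f"CM={rec['pos']:.8g};CLS={rec['cls']}\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Return (ids, haplotypes (n,2,L), GenomeMap) from a VCF file."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array([int(s) for s in vcf.samples])
    chroms, poss, locus_ids, clss, haps = [], [], [], [], []
    for v in vcf:
        chroms.append(int(v.CHROM))
        cm = v.INFO.get("CM")
        poss.append(float(cm) if cm is not None else (v.POS - 1) / 1e8)
        locus_ids.append(int(v.ID[3:]) if v.ID and v.ID.startswith("loc") else len(locus_ids))
        clss.append(v.INFO.get("CLS") or "SNP")
        g = np.array(v.genotypes)[:, :2]
        haps.append(g)
    vcf.close()
    hap = np.stack(haps, axis=2).astype(np.int8)  # (n, 2, L)
    gmap = GenomeMap(
        pd.DataFrame(
            {"chrom": chroms, "pos": poss, "locus_id": locus_ids, "cls": clss}
        )
    )
    return ids, hap, gmap


# ---------------------------------------------------------------------------
# panels and relationship matrices
# ---------------------------------------------------------------------------


def write_panel(panel, path) -> None:
    with open(path, "w") as fh:
        for i in panel.locus_ids:
            fh.write(f"{i}\n")


def read_panel(path, label: str = "PANEL"):
    from .panels import MarkerPanel

    ids = np.loadtxt(path, dtype=np.int64, ndmin=1)
    return MarkerPanel(locus_ids=ids, label=label)


def save_grm(grm, path) -> None:
    """Dense binary container (npz) with an animal-id index."""
    ids = grm.ids if grm.ids is not None else np.arange(grm.matrix.shape[0])
    np.savez_compressed(
        path, matrix=grm.matrix, ids=ids, kind=np.array(grm.kind)
    )


def load_grm(path):
    from .dimensionality import GRM

    with np.load(path, allow_pickle=False) as z:
        return GRM(matrix=z["matrix"], kind=str(z["kind"]), ids=z["ids"])


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
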