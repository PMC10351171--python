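"""Breeding-value estimation: pedigree BLUP and single-step genomic BLUP.

The combined relationship inverse adds a genomic correction for the
genotyped block on top of the pedigree inverse:
H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1], with G blended as 0.95 G + 0.05 A22
to guarantee invertibility.  Variance components are taken as known (the
simulated values), so only their ratio enters the mixed-model equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .dimensionality import GRM, build_grm_vanraden
from .panels import MarkerPanel
from .simpop import PhenotypeSet, Population

__all__ = [
    "PedigreeRelationship",
    "EvaluationResult",
    "build_A",
    "blend_G",
    "build_Hinv",
    "solve_mme",
    "run_prediction_scenario",
]


class PedigreeError(ValueError):
    pass


@dataclass
class PedigreeRelationship:
    """Numerator relationships over an (ordered) evaluation pedigree."""

    A: np.ndarray
    ids: np.ndarray

    def submatrix(self, ids) -> np.ndarray:
        lookup = pd.Series(np.arange(len(self.ids)), index=self.ids)
        idx = lookup.loc[np.asarray(ids)].to_numpy()
        return self.A[np.ix_(idx, idx)]

    def indices_of(self, ids) -> np.ndarray:
        lookup = pd.Series(np.arange(len(self.ids)), index=self.ids)
        return lookup.loc[np.asarray(ids)].to_numpy()


def build_A(pedigree: pd.DataFrame) -> PedigreeRelationship:
    """Wright's numerator relationship matrix by the recursive tabular method.

    ``pedigree`` needs columns id, sire, dam and must be topologically
    ordered; parent id 0 means unknown, and a nonzero parent that is not
    listed earlier is an error.  Unknown parents are unrelated base animals;
    inbreeding accumulates via a_ii = 1 + 0.5 a_sd.
    """
    ids = pedigree["id"].to_numpy()
    sire = pedigree["sire"].to_numpy()
    dam = pedigree["dam"].to_numpy()
    n = len(ids)
    row = {0: -1}
    for k, i in enumerate(ids):
        if i in row:
            raise PedigreeError(f"duplicate animal id {i}")
        row[i] = k
    A = np.zeros((n, n))
    for k in range(n):
        s = sire[k]
        d = dam[k]
        if s != 0 and s == d:
            raise PedigreeError(f"animal {ids[k]} is selfed (sire == dam == {s})")
        si = row.get(s, None)
        di = row.get(d, None)
        if s != 0 and (si is None or si >= k):
            raise PedigreeError(f"sire {s} of {ids[k]} not listed earlier")
        if d != 0 and (di is None or di >= k):
            raise PedigreeError(f"dam {d} of {ids[k]} not listed earlier")
        si = -1 if s == 0 else si
        di = -1 if d == 0 else di
        rel = np.zeros(k)
        if si >= 0:
            rel += 0.5 * A[si, :k]
        if di >= 0:
            rel += 0.5 * A[di, :k]
        A[k, :k] = rel
        A[:k, k] = rel
        inb = 0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[k, k] = 1.0 + inb
    return PedigreeRelationship(A=A, ids=ids)


def blend_G(G: GRM, A22: np.ndarray, weight: float = 0.05) -> GRM:
    """(1 - weight) * G + weight * A22."""
    A22 = np.asarray(A22, dtype=float)
    if A22.shape != G.matrix.shape:
        raise ValueError(
            f"dimension mismatch: G is {G.matrix.shape}, A22 is {A22.shape}"
        )
    return GRM(
        matrix=(1.0 - weight) * G.matrix + weight * A22,
        kind=G.kind,
        allele_freqs=G.allele_freqs,
        ids=G.ids,
    )


def _inv_or_raise(M: np.ndarray, name: str) -> np.ndarray:
    try:
        return linalg.inv(M, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"{name} is singular") from exc


def build_Hinv(
    Ainv: np.ndarray,
    Ginv: np.ndarray | None,
    A22inv: np.ndarray | None,
    genotyped_index: np.ndarray,
) -> np.ndarray:
    """A^-1 plus the genotyped-block correction G^-1 - A22^-1."""
    H = np.array(Ainv, dtype=float, copy=True)
    idx = np.asarray(genotyped_index, dtype=int)
    if idx.size == 0:
        return H
    if Ginv is None or A22inv is None:
        raise ValueError("genotyped animals present but G^-1/A22^-1 missing")
    H[np.ix_(idx, idx)] += Ginv - A22inv
    return H


@dataclass
class EvaluationResult:
    """Solutions of the mixed-model equations for every pedigree animal."""

    ids: np.ndarray
    gebv: np.ndarray
    mu: float
    model: str = "ssgblup"
    panel_label: str | None = None
    training_label: str | None = None

    def gebv_of(self, ids) -> np.ndarray:
        s = pd.Series(self.gebv, index=self.ids)
        return s.loc[np.asarray(ids)].to_numpy()


def solve_mme(
    y: np.ndarray,
    record_index: np.ndarray,
    Kinv: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    ids: np.ndarray | None = None,
    model: str = "ssgblup",
) -> EvaluationResult:
    """Solve [1'1 1'Z; Z'1 Z'Z + lambda*Kinv] [mu; u] = [1'y; Z'y].

    ``record_index`` maps each record to its animal's position in ``Kinv``.
    Returns solutions for all animals, phenotyped or not.
    """
    if sigma_u2 <= 0 or sigma_e2 < 0:
        raise ValueError("variances must be positive (sigma_e2 >= 0)")
    y = np.asarray(y, dtype=float)
    record_index = np.asarray(record_index, dtype=int)
    n_anim = Kinv.shape[0]
    lam = sigma_e2 / sigma_u2
    counts = np.bincount(record_index, minlength=n_anim).astype(float)
    zty = np.bincount(record_index, weights=y, minlength=n_anim)

    C = np.empty((n_anim + 1, n_anim + 1))
    C[0, 0] = len(y)
    C[0, 1:] = counts
    C[1:, 0] = counts
    C[1:, 1:] = np.diag(counts) + lam * Kinv
    rhs = np.concatenate([[y.sum()], zty])
    sol = linalg.solve(C, rhs, assume_a="sym", check_finite=False)
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError("mixed-model equations produced non-finite solutions")
    resid = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1.0)
    if resid > 1e-8:
        raise np.linalg.LinAlgError(f"MME solve residual too large: {resid:.2e}")
    if ids is None:
        ids = np.arange(n_anim)
    return EvaluationResult(
        ids=np.asarray(ids), gebv=sol[1:], mu=float(sol[0]), model=model
    )


def run_prediction_scenario(
    population: Population,
    phenotypes: PhenotypeSet,
    panel: MarkerPanel,
    training_ids: np.ndarray,
    test_ids: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    model: str = "ssgblup",
    eval_generations=None,
    blend_weight: float = 0.05,
    training_label: str | None = None,
) -> EvaluationResult:
    """Full evaluation for one panel / training set / model combination.

    Builds the evaluation pedigree (default: phenotyped generations), the
    genomic block over training + test animals on the requested panel, the
    combined relationship inverse, and solves the mixed-model equations with
    training phenotypes only.
    """
    training_ids = np.asarray(training_ids)
    test_ids = np.asarray(test_ids)
    if np.intersect1d(training_ids, test_ids).size > 0:
        raise ValueError("training and test sets overlap")

    ped = population.pedigree
    if eval_generations is None:
        eval_generations = np.unique(phenotypes.table["generation"])
    mask = ped["generation"].isin(list(eval_generations))
    eval_ped = ped.loc[mask, ["id", "sire", "dam"]].copy()
    known = set(eval_ped["id"].to_numpy().tolist())
    for col in ("sire", "dam"):
        vals = eval_ped[col].to_numpy()
        eval_ped[col] = np.where(np.isin(vals, list(known)), vals, 0)

    A = build_A(eval_ped)
    Ainv = _inv_or_raise(A.A, "A")

    if model.lower() == "pblup":
        Kinv = Ainv
    elif model.lower() == "ssgblup":
        geno_ids = np.concatenate([training_ids, test_ids])
        loci = panel.indices_in(population.genome_map)
        Xg = population.genotypes(ids=geno_ids, loci=loci)
        n_train = len(training_ids)
        freqs = Xg[:n_train].mean(axis=0) / 2.0
        G = build_grm_vanraden(Xg, freqs=freqs, ids=geno_ids)
        A22 = A.submatrix(geno_ids)
        Gb = blend_G(G, A22, weight=blend_weight)
        Ginv = _inv_or_raise(Gb.matrix, "blended G")
        A22inv = _inv_or_raise(A22, "A22")
        Kinv = build_Hinv(Ainv, Ginv, A22inv, A.indices_of(geno_ids))
    else:
        raise ValueError(f"unknown model {model!r}")

    y = phenotypes.phenotypes_of(training_ids)
    rec_idx = A.indices_of(training_ids)
    result = solve_mme(
        y, rec_idx, Kinv, sigma_u2, sigma_e2, ids=A.ids, model=model.lower()
    )
    result.panel_label = panel.label
    result.training_label = training_label
    return result
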