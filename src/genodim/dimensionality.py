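"""Genomic relationship matrices, eigen-profiles, and sample sizing.

The central quantity is the number of largest eigenvalues of a genomic
relationship matrix needed to explain x% of its variance.  That count is
used both as a measure of the dimensionality of genomic information and as
the size of nested discovery/training subsets of genotyped animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_rng

__all__ = [
    "GRM",
    "EigenProfile",
    "SelectionSet",
    "build_grm_vanraden",
    "build_grm_centered_scan",
    "eigen_profile",
    "eigen_profile_from_genotypes",
    "n_eigen_for_pct",
    "predicted_dimensionality",
    "make_selection_sets",
]


@dataclass
class GRM:
    """Symmetric PSD relationship matrix over a set of animals."""

    matrix: np.ndarray
    kind: str  # "VANRADEN1" | "CENTERED_SCAN"
    allele_freqs: np.ndarray | None = None
    ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_grm_vanraden(genotypes: np.ndarray, freqs: np.ndarray | None = None,
                       ids=None) -> GRM:
    """G = MM' / (2 Σ p_i (1 - p_i)), M centered by twice the allele frequency.

    Frequencies default to the current (supplied) genotypes.
    """
    X = np.asarray(genotypes, dtype=float)
    if freqs is None:
        freqs = X.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0.0:
        raise ZeroDivisionError("all loci monomorphic: VanRaden denominator is zero")
    M = X - 2.0 * freqs
    return GRM(matrix=(M @ M.T) / denom, kind="VANRADEN1", allele_freqs=freqs,
               ids=None if ids is None else np.asarray(ids))


def build_grm_centered_scan(genotypes: np.ndarray, ids=None) -> GRM:
    """Mean-centered cross-product averaged over loci:
    G = (1/n_s) Σ_i (x_i - x̄_i 1)(x_i - x̄_i 1)'."""
    X = np.asarray(genotypes, dtype=float)
    n_s = X.shape[1]
    if n_s < 1:
        raise ValueError("need at least one locus")
    M = X - X.mean(axis=0)
    return GRM(matrix=(M @ M.T) / n_s, kind="CENTERED_SCAN",
               ids=None if ids is None else np.asarray(ids))


@dataclass
class EigenProfile:
    """Descending eigenvalues with cumulative variance fractions."""

    eigenvalues: np.ndarray
    trace: float = field(init=False)
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self):
        ev = np.sort(np.asarray(self.eigenvalues, dtype=float))[::-1]
        self.eigenvalues = ev
        self.trace = float(ev.sum())
        if self.trace <= 0:
            raise ValueError("eigen profile has non-positive trace")
        self.cumulative = np.cumsum(ev) / self.trace

    @property
    def rank(self) -> int:
        tol = 1e-10 * max(self.trace, 1.0)
        return int(np.sum(self.eigenvalues > tol))


def eigen_profile(grm: GRM, sym_tol: float = 1e-8) -> EigenProfile:
    """Eigenvalues of a GRM, sorted descending; tiny negatives clipped to 0."""
    A = np.asarray(grm.matrix, dtype=float)
    scale = max(np.abs(A).max(), 1.0)
    if not np.allclose(A, A.T, atol=sym_tol * scale):
        raise ValueError("matrix is not symmetric within tolerance")
    ev = np.linalg.eigvalsh((A + A.T) / 2.0)
    clip = 1e-8 * max(ev.max(), 0.0) if ev.size else 0.0
    ev = np.where(ev < clip, np.maximum(ev, 0.0), ev)
    ev[np.abs(ev) < clip] = 0.0
    return EigenProfile(ev)


def eigen_profile_from_genotypes(genotypes: np.ndarray) -> EigenProfile:
    """Profile of the genotype cross-product centered by current allele
    frequencies, via the smaller-dimension Gram matrix (equivalent to squaring
    the singular values of the centered matrix).

    Cumulative fractions are invariant to the overall scaling of the matrix,
    so this profile stands in for any centered GRM over the same data.
    """
    X = np.asarray(genotypes, dtype=float)
    M = X - X.mean(axis=0)  # column mean = 2 * current allele frequency
    n, m = M.shape
    gram = M @ M.T if n <= m else M.T @ M
    ev = np.linalg.eigvalsh((gram + gram.T) / 2.0)
    ev = np.clip(ev, 0.0, None)
    full = np.zeros(n)
    k = min(n, m)
    full[:k] = np.sort(ev)[::-1][:k]
    return EigenProfile(full)


def n_eigen_for_pct(profile: EigenProfile, x: float) -> int:
    """Smallest k such that the top-k eigenvalues explain >= x% of the trace."""
    if not (0.0 < x <= 100.0):
        raise ValueError("x must be in (0, 100]")
    if x == 100.0:
        return profile.rank
    target = x / 100.0
    return int(np.searchsorted(profile.cumulative, target - 1e-12) + 1)


def predicted_dimensionality(ne: float, length_morgans: float):
    """Heuristic eigen counts from effective size and genome length:
    (Ne·L, 2Ne·L, 4Ne·L, Me=4Ne·L) for the 90/95/98% levels and the number
    of independent chromosome segments."""
    if ne < 0 or length_morgans < 0:
        raise ValueError("ne and genome length must be non-negative")
    nel = ne * length_morgans
    return nel, 2.0 * nel, 4.0 * nel, 4.0 * nel


@dataclass
class SelectionSet:
    """A role-labelled animal subset for one dimensionality level."""

    role: str  # "discovery" | "training" | "test"
    eigx_label: str  # "EIG50" ... "EIG99" | "ALL"
    ids: np.ndarray

    def __len__(self):
        return len(self.ids)


def make_selection_sets(
    genotyped: pd.DataFrame,
    profile: EigenProfile | None,
    x_levels,
    scheme: str = "distinct",
    rng=None,
    include_all: bool = True,
) -> list[SelectionSet]:
    """Split genotyped animals into test / discovery / training subsets.

    ``genotyped`` needs columns id and generation.  The test set is the whole
    final generation.  The rest is shuffled once; with scheme="distinct" it is
    halved into a discovery pool and a training pool, with scheme="same" a
    single pool serves both roles.  For each x in ``x_levels`` the subset size
    is the eigen count at x% and subsets are nested by construction (prefixes
    of the shuffled pool).
    """
    rng = as_rng(rng)
    if scheme not in ("distinct", "same"):
        raise ValueError("scheme must be 'distinct' or 'same'")
    gen = genotyped["generation"].to_numpy()
    ids = genotyped["id"].to_numpy()
    last = gen.max()
    test_ids = ids[gen == last]
    pool = ids[gen != last]
    pool = pool[rng.permutation(len(pool))]
    if scheme == "distinct":
        half = len(pool) // 2
        pools = {"discovery": pool[:half], "training": pool[half : 2 * half]}
    else:
        pools = {"discovery": pool, "training": pool}

    sets = [SelectionSet("test", "ALL", np.sort(test_ids))]
    levels = list(x_levels)
    if levels and profile is None:
        raise ValueError("x_levels given but no eigen profile")
    for role, p in pools.items():
        for x in levels:
            k = n_eigen_for_pct(profile, x)
            if k > len(p):
                raise ValueError(
                    f"EIG{x} needs {k} animals but the {role} pool has {len(p)}"
                )
            sets.append(SelectionSet(role, f"EIG{x:g}", p[:k].copy()))
        if include_all:
            sets.append(SelectionSet(role, "ALL", p.copy()))
    return sets
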