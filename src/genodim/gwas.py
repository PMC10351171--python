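"""Mixed-model association scan and variance-explained accounting.

The scan follows the two-stage approximation used by fast mixed-model GWAS
tools: the variance ratio of the null model (no marker term) is estimated
once by REML via a single spectral decomposition of the relationship matrix,
and every variant is then tested by generalized least squares with that
covariance held fixed.  An exact per-variant GLS (full covariance solve) is
kept in the test suite as the independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dimensionality import GRM
from .simpop import GenomeMap

__all__ = [
    "VarianceComponents",
    "AssocResult",
    "HitCounts",
    "reml_null",
    "assoc_scan",
    "bonferroni_threshold",
    "classify_hits",
    "qtn_pct_var",
    "total_var_explained",
    "loess_smooth",
    "sample_size_for_var",
]


class RemlError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    loglik: float
    boundary: bool = False
    degenerate: bool = False

    @property
    def h2(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else float("nan")

    @property
    def delta(self) -> float:
        """Residual-to-additive variance ratio."""
        return self.sigma_e2 / self.sigma_u2 if self.sigma_u2 > 0 else float("inf")


def _reml_profile(delta_log: float, lam: np.ndarray, yt: np.ndarray,
                  Xt: np.ndarray, logdet_xx: float) -> tuple[float, float]:
    """Profile REML log-likelihood in log(delta); returns (logL, sigma_u2)."""
    delta = math.exp(delta_log)
    n, p = Xt.shape
    w = lam + delta
    wi = 1.0 / w
    XtW = Xt * wi[:, None]
    xwx = Xt.T @ XtW
    beta = np.linalg.solve(xwx, XtW.T @ yt)
    r = yt - Xt @ beta
    s = float(np.sum(r * r * wi))
    if s <= 0.0:
        return -np.inf, 0.0
    sigma_u2 = s / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(xwx)
    ll = -0.5 * (
        (n - p) * math.log(2.0 * math.pi * sigma_u2)
        + (n - p)
        + float(np.sum(np.log(w)))
        + logdet_xwx
        - logdet_xx
    )
    return ll, sigma_u2


def reml_null(
    y: np.ndarray,
    grm: GRM,
    X: np.ndarray | None = None,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
    n_grid: int = 40,
) -> VarianceComponents:
    """REML variance components of y = Xb + u + e with u ~ N(0, G sigma_u2).

    One eigendecomposition of G, then a 1-D optimization of the profiled
    likelihood over the variance ratio (grid pre-scan + bounded Brent).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    if np.var(y) == 0.0:
        return VarianceComponents(0.0, 0.0, -np.inf, degenerate=True)
    lam, U = np.linalg.eigh((grm.matrix + grm.matrix.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_xx = np.linalg.slogdet(X.T @ X)

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([_reml_profile(d, lam, yt, Xt, logdet_xx)[0] for d in grid])
    if not np.any(np.isfinite(lls)):
        raise RemlError("REML likelihood not finite anywhere on the search grid")
    i = int(np.argmax(lls))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda d: -_reml_profile(d, lam, yt, Xt, logdet_xx)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RemlError(f"REML optimizer failed: {res.message}")
    ll, sigma_u2 = _reml_profile(res.x, lam, yt, Xt, logdet_xx)
    delta = math.exp(res.x)
    boundary = res.x <= lo + 1e-6 or res.x >= hi - 1e-6
    return VarianceComponents(
        sigma_u2=sigma_u2,
        sigma_e2=sigma_u2 * delta,
        loglik=ll,
        boundary=boundary,
    )


@dataclass
class AssocResult:
    """Per-variant scan output plus the significance threshold used."""

    table: pd.DataFrame  # locus_id, chrom, pos, beta, se, p, is_qtn, significant
    threshold: float

    def __len__(self):
        return len(self.table)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def assoc_scan(
    y: np.ndarray,
    genotypes: np.ndarray,
    grm: GRM,
    vc: VarianceComponents,
    genome_map: GenomeMap | None = None,
    locus_ids=None,
    alpha: float = 0.05,
) -> AssocResult:
    """Per-variant GLS with fixed covariance sigma_u2*G + sigma_e2*I.

    Wald test on the marker effect with a t reference, df = n - 2.  The
    residual scale is re-estimated per variant, so only the variance *ratio*
    from ``vc`` matters.  Monomorphic variants get beta = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(genotypes, dtype=float)
    n, m = X.shape
    if n != len(y):
        raise ValueError("phenotype/genotype dimension mismatch")
    lam, U = np.linalg.eigh((grm.matrix + grm.matrix.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    # weights proportional to the variance along each eigenvector
    if vc.sigma_u2 <= 0:
        w = np.ones(n)
    else:
        w = lam + vc.delta
    sw = 1.0 / np.sqrt(w)
    yt = (U.T @ y) * sw
    ct = (U.T @ np.ones(n)) * sw
    Xt = (U.T @ X) * sw[:, None]

    cc = float(ct @ ct)
    cy = float(ct @ yt)
    yy = float(yt @ yt)
    cx = ct @ Xt
    xy = yt @ Xt
    xx = np.einsum("ij,ij->j", Xt, Xt)

    det = cc * xx - cx**2
    ok = det > 1e-12 * max(cc, 1.0) * np.maximum(xx, 1e-300)
    det_safe = np.where(ok, det, 1.0)
    beta = (cc * xy - cx * cy) / det_safe
    beta0 = (xx * cy - cx * xy) / det_safe
    rss = yy - beta0 * cy - beta * xy
    df = n - 2
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(np.maximum(sigma2 * cc / det_safe, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        # se == 0 with a nonzero effect is a perfect fit, not a null result
        tval = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta = np.where(ok, beta, 0.0)
    se = np.where(ok, se, np.nan)
    p = np.where(ok, p, 1.0)

    if locus_ids is None:
        locus_ids = np.arange(m)
    locus_ids = np.asarray(locus_ids)
    if genome_map is not None:
        info = genome_map.table.set_index("locus_id").loc[locus_ids]
        chrom = info["chrom"].to_numpy()
        pos = info["pos"].to_numpy()
        is_qtn = (info["cls"] == "QTN").to_numpy()
    else:
        chrom = np.zeros(m, dtype=int)
        pos = np.arange(m, dtype=float)
        is_qtn = np.zeros(m, dtype=bool)
    threshold = bonferroni_threshold(alpha, m)
    table = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chrom": chrom,
            "pos": pos,
            "beta": beta,
            "se": se,
            "p": p,
            "is_qtn": is_qtn,
            "significant": p < threshold,
        }
    )
    return AssocResult(table=table, threshold=threshold)


@dataclass
class HitCounts:
    n_significant_qtn: int
    n_significant_snp: int


def classify_hits(assoc: AssocResult) -> HitCounts:
    """A QTN counts as identified only if its own variant is significant."""
    t = assoc.table
    sig = t["significant"]
    return HitCounts(
        n_significant_qtn=int((sig & t["is_qtn"]).sum()),
        n_significant_snp=int((sig & ~t["is_qtn"]).sum()),
    )


def qtn_pct_var(p_freq: float, beta: float, sigma_u2: float) -> float:
    """Fraction of additive variance from one QTN: 2 p q beta^2 / sigma_u2."""
    if not (0.0 < p_freq < 1.0):
        raise ValueError("allele frequency must be in (0, 1)")
    if sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be positive")
    return 2.0 * p_freq * (1.0 - p_freq) * beta**2 / sigma_u2


def total_var_explained(
    assoc: AssocResult, arch, freqs: np.ndarray, freq_locus_ids=None
) -> float:
    """Sum of per-QTN variance fractions over significantly identified QTN,
    using the true simulated effects and the supplied cohort frequencies.

    ``freqs`` is aligned with ``freq_locus_ids`` (default: the architecture's
    QTN ids).  QTN fixed in the cohort contribute nothing.
    """
    if freq_locus_ids is None:
        freq_locus_ids = arch.qtn_ids
    fmap = pd.Series(np.asarray(freqs), index=np.asarray(freq_locus_ids))
    beta = pd.Series(arch.beta, index=arch.qtn_ids)
    t = assoc.table
    hit_ids = t.loc[t["significant"] & t["is_qtn"], "locus_id"].to_numpy()
    total = 0.0
    for lid in hit_ids:
        pfreq = float(fmap.loc[lid])
        if 0.0 < pfreq < 1.0:
            total += qtn_pct_var(pfreq, float(beta.loc[lid]), arch.sigma_u2)
    return total


# ---------------------------------------------------------------------------
# sample-size estimation from a (n, %var) curve
# ---------------------------------------------------------------------------


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights (loess-style)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    q = max(int(math.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(len(x_eval))
    for k, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        h = np.sort(d)[q - 1]
        if h == 0.0:
            out[k] = y[d == 0].mean()
            continue
        w = (1.0 - np.minimum(d / h, 1.0) ** 3) ** 3
        used = w > 0
        deg = min(degree, used.sum() - 1)
        coeffs = np.polyfit(x[used] - x0, y[used], deg, w=np.sqrt(w[used]))
        out[k] = coeffs[-1]
    return out


def sample_size_for_var(
    curve_n: np.ndarray,
    curve_pct: np.ndarray,
    target_pct: float,
    span: float = 0.75,
    degree: int = 2,
    grid_points: int = 512,
) -> float:
    """Smallest sample size whose smoothed variance-explained curve reaches
    ``target_pct``: loess fit of pct on n, inverted by linear interpolation on
    a dense fitted grid."""
    curve_n = np.asarray(curve_n, dtype=float)
    curve_pct = np.asarray(curve_pct, dtype=float)
    if len(curve_n) < 4:
        raise ValueError("need at least 4 curve points")
    order = np.argsort(curve_n)
    curve_n, curve_pct = curve_n[order], curve_pct[order]
    grid = np.linspace(curve_n[0], curve_n[-1], grid_points)
    fitted = loess_smooth(curve_n, curve_pct, grid, span=span, degree=degree)
    above = fitted >= target_pct
    if not above.any():
        raise ValueError(
            f"target {target_pct} exceeds the fitted maximum {fitted.max():.4g}"
        )
    j = int(np.argmax(above))
    if j == 0:
        return float(grid[0])
    # linear interpolation between the bracketing grid points
    f0, f1 = fitted[j - 1], fitted[j]
    if f1 == f0:
        return float(grid[j])
    frac = (target_pct - f0) / (f1 - f0)
    return float(grid[j - 1] + frac * (grid[j] - grid[j - 1]))
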