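"""Back-transformed SNP effects and their standardized tests.

Marker effects come from the linear transformation g_hat = Z' G^-1 a_hat of
the GBLUP breeding values; because G = ZZ', the reconstruction Z g_hat =
a_hat holds as an algebraic identity.  Each effect is tested against its own
estimation variance (SNP_ej = g_hat_j / sqrt(Var(g_hat_j))) or against its
prediction error variance (SNP_epj = g_hat_j / sqrt(sigma2_g -
Var(g_hat_j))); two-sided p-values use the standard normal reference,
p = 2 (1 - Phi(|stat|)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import MarkerMap
from .grm import GRM, StandardizedMarkerMatrix
from .mixedmodel import REMLFit

UNTESTABLE_REL_FLOOR = 1e-12  # var_ghat below this fraction of sigma2_g


@dataclass
class SnpEffectEstimates:
    """Per-marker effect estimates with variance and PEV diagonals."""

    ghat: np.ndarray
    var_ghat: np.ndarray
    sigma2_g: float

    def __post_init__(self):
        tol = 1e-8 * max(self.sigma2_g, 1.0)
        if np.any(self.var_ghat < -tol):
            raise ValueError("negative Var(g_hat_j) beyond tolerance")
        if np.any(self.var_ghat > self.sigma2_g + max(1e-8, tol)):
            raise ValueError("Var(g_hat_j) exceeds sigma2_g beyond tolerance")
        self.var_ghat = np.clip(self.var_ghat, 0.0, None)

    @property
    def pev_ghat(self) -> np.ndarray:
        """PEV(g_hat_j) = sigma2_g - Var(g_hat_j)."""
        return self.sigma2_g - self.var_ghat


class _GInvZCache:
    """Cache of B = G^-1 Z, shared by the back-transformation and the
    variance diagonal (reusable across traits on the same genotypes)."""

    def __init__(self, G: GRM, Z: StandardizedMarkerMatrix):
        _check_provenance(G, Z)
        self.G, self.Z = G, Z
        self.B = G.solve(Z.Z)  # (n, m)


def _check_provenance(G: GRM, Z: StandardizedMarkerMatrix) -> None:
    if G.m_divisor is not None and G.m_divisor != Z.m_divisor:
        raise ValueError("G and Z provenance mismatch (m_divisor differs)")
    if G.p is not None and not np.array_equal(G.p, Z.p):
        raise ValueError("G and Z provenance mismatch (frequency vectors differ)")


def backtransform(ahat: np.ndarray, G: GRM, Z: StandardizedMarkerMatrix,
                  cache: _GInvZCache | None = None) -> np.ndarray:
    """g_hat = Z' G^-1 a_hat."""
    cache = cache or _GInvZCache(G, Z)
    return cache.B.T @ np.asarray(ahat, dtype=float)


def var_ghat_diag(Z: StandardizedMarkerMatrix, G: GRM, var_ahat: np.ndarray,
                  cache: _GInvZCache | None = None,
                  full_matrix_cap: int = 5000) -> np.ndarray:
    """diag(Z' G^-1 Var(a_hat) G^-1 Z) without forming the m x m matrix.

    With B = G^-1 Z the j-th element is b_j' Var(a_hat) b_j, accumulated
    column-wise; the factor B is cached and reusable across traits.
    ``full_matrix_cap`` guards any caller asking for the dense m x m form.
    """
    cache = cache or _GInvZCache(G, Z)
    B = cache.B
    if var_ahat.shape != (B.shape[0], B.shape[0]):
        raise ValueError("Var(a_hat) not conformable with G")
    return np.einsum("ij,ij->j", B, var_ahat @ B)


def var_ghat_full(Z: StandardizedMarkerMatrix, G: GRM, var_ahat: np.ndarray,
                  full_matrix_cap: int = 5000) -> np.ndarray:
    """Dense m x m Var(g_hat); refuses to materialize above the cap."""
    if Z.n_markers > full_matrix_cap:
        raise MemoryError(
            f"m = {Z.n_markers} exceeds full-matrix cap {full_matrix_cap}; "
            "use var_ghat_diag")
    B = _GInvZCache(G, Z).B
    return B.T @ var_ahat @ B


def snp_effect_estimates(fit: REMLFit, G: GRM,
                         Z: StandardizedMarkerMatrix) -> SnpEffectEstimates:
    """Back-transform a single-GRM fit into per-marker estimates.

    sigma2_g equals the REML additive variance sigma2_a of the animal model
    (the marker- and animal-level models are equivalent under G = ZZ').
    """
    cache = _GInvZCache(G, Z)
    ghat = backtransform(fit.ahat, G, Z, cache=cache)
    va = fit.var_ahat
    if va is None:
        from .mixedmodel import var_ahat as _va
        va = _va(fit, G)
    vg = var_ghat_diag(Z, G, va, cache=cache)
    return SnpEffectEstimates(ghat=ghat, var_ghat=vg, sigma2_g=fit.vc.sigma2_a)


def snp_ej(est: SnpEffectEstimates) -> tuple[np.ndarray, np.ndarray]:
    """SNP_ej = g_hat_j / sqrt(Var(g_hat_j)) with an untestable mask.

    Markers whose estimation variance is numerically zero (below
    ``UNTESTABLE_REL_FLOOR * sigma2_g``) are flagged untestable (NaN
    statistic, mask False) instead of producing infinities.
    """
    floor = UNTESTABLE_REL_FLOOR * est.sigma2_g
    testable = est.var_ghat > floor
    stat = np.full(est.ghat.shape, np.nan)
    stat[testable] = est.ghat[testable] / np.sqrt(est.var_ghat[testable])
    return stat, testable


def snp_epj(est: SnpEffectEstimates) -> tuple[np.ndarray, np.ndarray]:
    """SNP_epj = g_hat_j / sqrt(sigma2_g - Var(g_hat_j))."""
    pev = est.pev_ghat
    testable = pev > 0
    stat = np.full(est.ghat.shape, np.nan)
    stat[testable] = est.ghat[testable] / np.sqrt(pev[testable])
    return stat, testable


def pvalues(statistics: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values, p = 2 (1 - Phi(|stat|)); NaN passes through."""
    s = np.asarray(statistics, dtype=float)
    out = np.full(s.shape, np.nan)
    ok = np.isfinite(s)
    out[ok] = 2.0 * stats.norm.sf(np.abs(s[ok]))
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance level alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def scan_table(fit: REMLFit, G: GRM, Z: StandardizedMarkerMatrix,
               markers: MarkerMap) -> pd.DataFrame:
    """Genome-scan table: effects, variances, both statistics, p-values.

    The reconstruction identity Z g_hat = a_hat is asserted on every scan.
    """
    est = snp_effect_estimates(fit, G, Z)
    recon = Z.Z @ est.ghat
    scale = max(float(np.max(np.abs(fit.ahat))), 1e-12)
    err = float(np.max(np.abs(recon - fit.ahat))) / scale
    if err > 1e-8:
        raise FloatingPointError(
            f"back-transformation failed reconstruction (rel err {err:.2e})")
    ej, ok_ej = snp_ej(est)
    epj, ok_epj = snp_epj(est)
    p_ej, p_epj = pvalues(ej), pvalues(epj)
    reason = np.where(ok_ej, "", "degenerate_var")
    reason = np.where(ok_epj | ok_ej, reason, "degenerate_var_and_pev")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p_ej)
    return pd.DataFrame({
        "snp_id": markers.snp_id,
        "chromosome": markers.chromosome,
        "position_mb": markers.position_mb,
        "ghat": est.ghat,
        "var_ghat": est.var_ghat,
        "pev_ghat": est.pev_ghat,
        "snp_ej": ej,
        "snp_epj": epj,
        "pvalue_ej": p_ej,
        "pvalue_epj": p_epj,
        "neglog10_p": neglog,
        "untestable_reason": reason,
    })
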