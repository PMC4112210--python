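"""One-SNP-at-a-time mixed-model association scan (EMMA style).

For each marker the fixed part is [X, dosage_j] and the polygenic background
is the animal effect with covariance G sigma2_a.  In ``p3d`` mode the
variance components are estimated once under the null model and reused for
every marker (the EMMAX / P3D approximation); ``exact`` mode re-estimates
the ratio per marker.  Both modes rotate y, X and the dosages by the
eigenvectors of N G N' once, so each marker costs a small GLS solve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .geno_io import GenotypeMatrix
from .grm import GRM
from .mixedmodel import _LOG2PI, DesignData, reml_fit
from .snptests import pvalues


def emma_scan(data: DesignData, G: GRM, geno: GenotypeMatrix,
              mode: str = "p3d") -> pd.DataFrame:
    """Single-marker mixed-model scan.

    Returns one row per marker: effect, standard error, Wald statistic and
    its two-sided normal p-value, aligned with the genome-scan table for
    direct joining.  Markers with zero dosage variance among phenotyped
    animals are flagged untestable.
    """
    if mode not in ("p3d", "exact"):
        raise ValueError(f"unknown scan mode {mode!r}")
    idx = data.animal_indices(G.n)
    K = G.G[np.ix_(idx, idx)]
    d, U = linalg.eigh(0.5 * (K + K.T))
    d = np.clip(d, 0.0, None)
    yt = U.T @ data.y
    Xt = U.T @ data.X
    Dt = U.T @ geno.dosage[idx]          # rotated dosages, (n_obs, m)
    n, p = Xt.shape

    null = reml_fit(data, G, compute_pev=False)
    gamma0 = (null.vc.sigma2_a / null.vc.sigma2_e
              if null.vc.sigma2_e > 0 else np.inf)

    dos = geno.dosage[idx]
    testable = dos.std(axis=0) > 0

    m = geno.n_markers
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)

    def _gls(j, gamma):
        w = gamma * d + 1.0
        Xj = np.column_stack([Xt, Dt[:, j]])
        Xw = Xj / w[:, None]
        A = Xj.T @ Xw
        b = Xw.T @ yt
        coef = linalg.solve(A, b, assume_a="pos")
        r = yt - Xj @ coef
        q = float(r @ (r / w))
        s_e = q / (n - p - 1)
        cov = linalg.inv(A) * s_e
        return coef[-1], np.sqrt(cov[-1, -1]), q, w

    def _profile_negll(log_gamma, j):
        gamma = np.exp(log_gamma)
        Xj = np.column_stack([Xt, Dt[:, j]])
        w = gamma * d + 1.0
        Xw = Xj / w[:, None]
        A = Xj.T @ Xw
        sign, logdetA = np.linalg.slogdet(A)
        coef = linalg.solve(A, Xw.T @ yt, assume_a="pos")
        r = yt - Xj @ coef
        q = float(r @ (r / w))
        k = n - p - 1
        s_e = q / k
        return 0.5 * (k * (_LOG2PI + np.log(s_e) + 1.0)
                      + np.sum(np.log(w)) + logdetA)

    for j in np.where(testable)[0]:
        gamma = gamma0
        if mode == "exact":
            res = optimize.minimize_scalar(
                _profile_negll, args=(j,), bounds=(-25.0, 25.0),
                method="bounded", options={"xatol": 1e-6})
            gamma = float(np.exp(res.x))
        beta[j], se[j], *_ = _gls(j, gamma)

    wald = beta / se
    return pd.DataFrame({
        "snp_id": geno.markers.snp_id,
        "chromosome": geno.markers.chromosome,
        "position_mb": geno.markers.position_mb,
        "effect": beta,
        "se": se,
        "wald": wald,
        "pvalue": pvalues(wald),
        "untestable_reason": np.where(testable, "", "constant_dosage"),
    })
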