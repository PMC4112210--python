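"""Standardized marker matrix Z and genomic relationship matrices.

The GRM follows the allele-frequency standardization G = ZZ' with
z_ij = (m_ij - 2 p_j) / sqrt(m_divisor * 2 p_j (1 - p_j)), the divisor
normally being the number of markers so that E[diag(G)] = 1 when the
frequencies match the population.  Segment GRMs (G1) are rescaled by their
own marker count; the complement GRM (G2) is formed by subtracting the
segment columns of the *full-m scaled* Z, so the two scalings deliberately
differ — the bridge identity Z_s Z_s' = (m_seg/m) G1 connects them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .geno_io import GenotypeMatrix


@dataclass
class StandardizedMarkerMatrix:
    Z: np.ndarray                 # (n, m)
    p: np.ndarray                 # frequencies used for centring/scaling
    m_divisor: int                # marker count inside the scaling denominator
    snp_id: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_markers(self) -> int:
        return self.Z.shape[1]

    def marker_indices(self, snp_ids) -> np.ndarray:
        if self.snp_id is None:
            raise ValueError("Z carries no marker ids")
        lookup = {s: i for i, s in enumerate(self.snp_id)}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"markers absent from Z: {missing[:5]}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)


@dataclass
class GRM:
    """Genomic relationship matrix with its standardization provenance."""

    G: np.ndarray
    p: np.ndarray | None = None
    m_divisor: int | None = None
    epsilon: float = 0.0
    marker_ids: np.ndarray | None = None
    sample_ids: np.ndarray | None = None
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor, cached; raises LinAlgError if singular."""
        if self._chol is None:
            self._chol = linalg.cholesky(self.G, lower=True)
        return self._chol

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached symmetric eigendecomposition (ascending eigenvalues)."""
        if self._eig is None:
            d, U = linalg.eigh(0.5 * (self.G + self.G.T))
            self._eig = (d, U)
        return self._eig

    def solve(self, B: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
        """G^+ B via the cached eigendecomposition.

        GRMs built with in-sample or founder frequencies are routinely
        rank-deficient (centred Z has the ones vector in its null space), so
        the solve is a pseudoinverse with eigenvalues below
        ``rcond * lambda_max`` truncated.  For right-hand sides in the
        column space of G — breeding values and their covariances always
        are — this is exact; for full-rank G it coincides with the
        Cholesky solve.
        """
        d, U = self.eigendecomposition()
        cut = rcond * float(d[-1]) if d[-1] > 0 else np.inf
        inv_d = np.where(d > cut, 1.0 / np.where(d > cut, d, 1.0), 0.0)
        return U @ (inv_d[:, None] * (U.T @ B)) if B.ndim == 2 else \
            U @ (inv_d * (U.T @ B))


def standardize(M: GenotypeMatrix | np.ndarray, p: np.ndarray,
                m_divisor: int | None = None,
                snp_id: np.ndarray | None = None) -> StandardizedMarkerMatrix:
    """Centre and scale dosages into Z.

    Requires complete dosages and 0 < p_j < 1 for every marker (monomorphic
    markers must be removed by QC before this point).
    """
    if isinstance(M, GenotypeMatrix):
        if snp_id is None:
            snp_id = np.asarray(M.markers.snp_id)
        M = M.dosage
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if M.ndim != 2 or p.shape != (M.shape[1],):
        raise ValueError("dosage matrix and frequency vector are misaligned")
    if np.isnan(M).any():
        raise ValueError("standardize requires imputed (complete) dosages")
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = np.where((p <= 0.0) | (p >= 1.0))[0]
        raise ValueError(f"monomorphic markers reached standardization "
                         f"(indices {bad[:5].tolist()}); run QC first")
    if m_divisor is None:
        m_divisor = M.shape[1]
    if m_divisor < 1:
        raise ValueError("m_divisor must be a positive marker count")
    scale = np.sqrt(m_divisor * 2.0 * p * (1.0 - p))
    Z = (M - 2.0 * p) / scale
    return StandardizedMarkerMatrix(Z=Z, p=p, m_divisor=int(m_divisor), snp_id=snp_id)


def compute_grm(Z: StandardizedMarkerMatrix,
                sample_ids: np.ndarray | None = None) -> GRM:
    """G = ZZ' with provenance recorded."""
    if not np.all(np.isfinite(Z.Z)):
        raise ValueError("Z contains non-finite entries")
    G = Z.Z @ Z.Z.T
    G = 0.5 * (G + G.T)  # enforce exact symmetry
    return GRM(G=G, p=Z.p, m_divisor=Z.m_divisor, marker_ids=Z.snp_id,
               sample_ids=sample_ids)


def segment_grm(M: GenotypeMatrix | np.ndarray, p: np.ndarray,
                segment_idx: np.ndarray,
                snp_id: np.ndarray | None = None) -> GRM:
    """GRM from the segment's markers only, with its own segment-size divisor."""
    segment_idx = np.asarray(segment_idx, dtype=int)
    if segment_idx.size == 0:
        raise ValueError("segment is empty")
    if isinstance(M, GenotypeMatrix):
        snp_id = np.asarray(M.markers.snp_id)
        M = M.dosage
    Zs = standardize(M[:, segment_idx], np.asarray(p)[segment_idx],
                     m_divisor=segment_idx.size,
                     snp_id=None if snp_id is None else np.asarray(snp_id)[segment_idx])
    return compute_grm(Zs)


def complement_grm(G: GRM, Z: StandardizedMarkerMatrix,
                   segment_idx: np.ndarray) -> GRM:
    """G2 = G - Z_s Z_s' where Z_s keeps the full-m scaling of Z.

    ``G`` must have been built from ``Z`` (provenance check on divisor and p).
    An empty segment returns G unchanged.
    """
    if G.m_divisor != Z.m_divisor or (G.p is not None and
                                      not np.array_equal(G.p, Z.p)):
        raise ValueError("G was not built from the supplied Z (provenance mismatch)")
    segment_idx = np.asarray(segment_idx, dtype=int)
    if segment_idx.size == 0:
        return GRM(G=G.G.copy(), p=G.p, m_divisor=G.m_divisor,
                   sample_ids=G.sample_ids)
    if segment_idx.max() >= Z.n_markers or segment_idx.min() < 0:
        raise ValueError("segment indices out of range for Z")
    Zs = Z.Z[:, segment_idx]
    G2 = G.G - Zs @ Zs.T
    G2 = 0.5 * (G2 + G2.T)
    return GRM(G=G2, p=G.p, m_divisor=G.m_divisor, sample_ids=G.sample_ids)


def segment_bridge(G1: GRM, m_seg: int, m_total: int) -> np.ndarray:
    """Full-m-scaled segment kernel (m_seg/m) * G1 == Z_s Z_s'."""
    return (m_seg / m_total) * G1.G


def regularize(G: GRM, epsilon: float) -> GRM:
    """Return G + epsilon * I (epsilon recorded in provenance)."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if epsilon == 0:
        return G
    return GRM(G=G.G + epsilon * np.eye(G.n), p=G.p, m_divisor=G.m_divisor,
               epsilon=G.epsilon + epsilon, marker_ids=G.marker_ids,
               sample_ids=G.sample_ids)


def auto_regularize(G: GRM, rel_epsilon: float = 1e-6) -> GRM:
    """Regularize only when G is (numerically) singular.

    A Cholesky can succeed on a matrix whose smallest eigenvalue is at
    round-off scale (e.g. G built with in-sample frequencies has the ones
    vector in its null space), so the check is on the smallest eigenvalue:
    if lambda_min < rel_epsilon * mean(diag G), enough is added to the
    diagonal to lift it to that floor.
    """
    scale = float(np.mean(np.diag(G.G)))
    lam_min = float(linalg.eigh(G.G, eigvals_only=True,
                                subset_by_index=[0, 0])[0])
    floor = rel_epsilon * scale
    if lam_min >= floor:
        return G
    eps = floor - min(lam_min, 0.0)
    import logging
    logging.getLogger(__name__).info(
        "GRM near-singular (lambda_min=%.3e); regularizing with epsilon=%.3e",
        lam_min, eps)
    return regularize(G, eps)


def write_grm(G: GRM, path, meta_path=None) -> None:
    """Persist as TSV at full double precision with a sidecar metadata file."""
    import pandas as pd

    ids = (G.sample_ids if G.sample_ids is not None
           else np.array([f"s{i}" for i in range(G.n)], dtype=object))
    df = pd.DataFrame(G.G, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.17g")
    if meta_path is not None:
        import json
        with open(meta_path, "w") as fh:
            json.dump({"m_divisor": G.m_divisor, "epsilon": G.epsilon,
                       "p": None if G.p is None else G.p.tolist()}, fh)


def read_grm(path, meta_path=None) -> GRM:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    meta = {}
    if meta_path is not None:
        import json
        with open(meta_path) as fh:
            meta = json.load(fh)
    p = meta.get("p")
    return GRM(G=df.to_numpy(), sample_ids=df.index.to_numpy(dtype=object),
               m_divisor=meta.get("m_divisor"), epsilon=meta.get("epsilon", 0.0),
               p=None if p is None else np.asarray(p, dtype=float))
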