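"""Plasmode permutation study of the type-I error of the SNP tests.

One chromosome's genotype block is reshuffled so its SNPs become truly
null while the rest of the genome (and hence the heritability) is left
intact.  Two scenarios: ``LD_rows`` permutes whole rows of the block (one
joint permutation, preserving within-block LD), ``LE_columns`` permutes
each block column independently (destroying LD).  The phenotype is never
permuted.  Per replicate the GRM is rebuilt from the permuted matrix, the
animal model refitted by REML, and the block SNPs' p-values collected; the
summary reports empirical type-I error and a QQ table whose envelope comes
from uniform U(0,1) reference replicates of the same shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix
from .grm import compute_grm, standardize
from .mixedmodel import DesignData, reml_fit
from .snptests import pvalues, snp_effect_estimates, snp_ej, snp_epj

logger = logging.getLogger(__name__)

SCENARIOS = ("LD_rows", "LE_columns")


@dataclass
class PlasmodeConfig:
    target_chromosome: str
    scenario: str = "LE_columns"
    n_reps: int = 200
    statistic: str = "ej"              # primary statistic for the QQ table
    alphas: tuple[float, ...] = (0.05, 0.01)
    rng_seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.statistic not in ("ej", "epj"):
            raise ValueError("statistic must be 'ej' or 'epj'")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class PlasmodeResult:
    config: PlasmodeConfig
    pvalues_ej: np.ndarray             # (n_kept_reps, n_block)
    pvalues_epj: np.ndarray
    h2: np.ndarray                     # per-replicate REML heritability
    n_failed: int

    def pmatrix(self, statistic: str | None = None) -> np.ndarray:
        stat = statistic or self.config.statistic
        return self.pvalues_ej if stat == "ej" else self.pvalues_epj

    def type1_error(self, alpha: float, statistic: str | None = None) -> float:
        """Fraction of null SNP tests with p < alpha, pooled over replicates."""
        return float(np.mean(self.pmatrix(statistic) < alpha))

    def type1_table(self) -> pd.DataFrame:
        rows = [{"alpha": a, "statistic": s,
                 "empirical_size": self.type1_error(a, s)}
                for a in self.config.alphas for s in ("ej", "epj")]
        return pd.DataFrame(rows)

    def qq_table(self, statistic: str | None = None) -> pd.DataFrame:
        """Expected vs observed -log10 p quantiles with a 95% envelope from
        U(0,1) reference replicates of identical shape."""
        P = self.pmatrix(statistic)
        n_reps, n_block = P.shape
        obs_sorted = np.sort(P, axis=1)
        observed = obs_sorted.mean(axis=0)
        expected = np.arange(1, n_block + 1) / (n_block + 1)
        rng = np.random.default_rng([int(self.config.rng_seed), 2**20])
        ref = np.sort(rng.random((n_reps, n_block)), axis=1)
        lo = np.quantile(ref, 0.025, axis=0)
        hi = np.quantile(ref, 0.975, axis=0)
        return pd.DataFrame({
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(observed),
            "envelope_lo_neglog10": -np.log10(hi),
            "envelope_hi_neglog10": -np.log10(lo),
        })


def permute_block_rows(geno: GenotypeMatrix, block_idx: np.ndarray,
                       rng: np.random.Generator) -> GenotypeMatrix:
    """Apply one joint row permutation to all block columns (LD preserved)."""
    block_idx = np.asarray(block_idx, dtype=int)
    if block_idx.size == 0:
        raise ValueError("block is empty")
    perm = rng.permutation(geno.n_samples)
    dosage = geno.dosage.copy()
    dosage[:, block_idx] = geno.dosage[np.ix_(perm, block_idx)]
    return GenotypeMatrix(geno.samples, geno.markers, dosage)


def permute_block_columns(geno: GenotypeMatrix, block_idx: np.ndarray,
                          rng: np.random.Generator) -> GenotypeMatrix:
    """Independent row permutation per block column (drives the block to LE)."""
    block_idx = np.asarray(block_idx, dtype=int)
    if block_idx.size == 0:
        raise ValueError("block is empty")
    dosage = geno.dosage.copy()
    for j in block_idx:
        dosage[:, j] = geno.dosage[rng.permutation(geno.n_samples), j]
    return GenotypeMatrix(geno.samples, geno.markers, dosage)


def run_plasmode(geno: GenotypeMatrix, data: DesignData,
                 config: PlasmodeConfig,
                 max_failure_fraction: float = 0.10) -> PlasmodeResult:
    """Run the permutation study.

    ``geno`` must be complete (imputed).  Each replicate draws an
    independent substream from (seed, replicate), permutes the target
    chromosome's block, recomputes allele frequencies and the GRM from the
    permuted matrix, refits the animal model by REML, and records both
    standardized statistics' p-values for the block SNPs.
    """
    if geno.missing_mask.any():
        raise ValueError("plasmode requires an imputed genotype matrix")
    chrom = str(config.target_chromosome)
    block_idx = np.where(geno.markers.chromosome.astype(str) == chrom)[0]
    if block_idx.size == 0:
        raise ValueError(f"chromosome {chrom!r} not present in marker map")
    permute = (permute_block_rows if config.scenario == "LD_rows"
               else permute_block_columns)

    rows_ej, rows_epj, h2s = [], [], []
    n_failed = 0
    for rep in range(config.n_reps):
        rng = np.random.default_rng([int(config.rng_seed), rep])
        perm_geno = permute(geno, block_idx, rng)
        try:
            p = perm_geno.dosage.mean(axis=0) / 2.0
            Z = standardize(perm_geno, p)
            G = compute_grm(Z)
            fit = reml_fit(data, G)
            est = snp_effect_estimates(fit, G, Z)
            ej, _ = snp_ej(est)
            epj, _ = snp_epj(est)
            rows_ej.append(pvalues(ej[block_idx]))
            rows_epj.append(pvalues(epj[block_idx]))
            h2s.append(fit.vc.h2)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            n_failed += 1
            logger.warning("plasmode replicate %d failed: %s", rep, exc)
        if (rep + 1) % 20 == 0:
            logger.info("plasmode: %d/%d replicates done", rep + 1,
                        config.n_reps)
    if n_failed > max_failure_fraction * config.n_reps:
        raise RuntimeError(
            f"{n_failed}/{config.n_reps} plasmode replicates failed")
    return PlasmodeResult(config=config,
                          pvalues_ej=np.asarray(rows_ej),
                          pvalues_epj=np.asarray(rows_epj),
                          h2=np.asarray(h2s), n_failed=n_failed)
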