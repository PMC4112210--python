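"""High-level helpers chaining the editing, GRM, fit and scan steps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import (GenotypeMatrix, SampleTable, founder_allele_freqs,
                      mean_impute, qc_filter)
from .grm import GRM, StandardizedMarkerMatrix, compute_grm, standardize
from .mixedmodel import DesignData, REMLFit, reml_fit
from .snptests import scan_table


@dataclass
class ScanPipelineResult:
    geno: GenotypeMatrix
    p: np.ndarray
    Z: StandardizedMarkerMatrix
    G: GRM
    data: DesignData
    fit: REMLFit
    scan: pd.DataFrame


def build_design(geno: GenotypeMatrix, phenotypes: pd.DataFrame,
                 trait: str = "trait",
                 covariate_cols: tuple = ("sex",)) -> DesignData:
    """DesignData for phenotyped-and-genotyped samples (intercept + covs)."""
    pos = {s: i for i, s in enumerate(geno.samples)}
    ph = phenotypes[phenotypes.index.isin(pos) if phenotypes.index.name == "sample_id"
                    else phenotypes["sample_id"].isin(pos)]
    ids = (ph.index if ph.index.name == "sample_id"
           else ph["sample_id"]).to_numpy()
    obs_idx = np.array([pos[s] for s in ids])
    cols = [np.ones(len(ph))]
    cols += [ph[c].to_numpy(float) for c in covariate_cols if c in ph.columns]
    return DesignData(y=ph[trait].to_numpy(float),
                      X=np.column_stack(cols), obs_idx=obs_idx)


def run_scan(geno: GenotypeMatrix, samples: SampleTable,
             phenotypes: pd.DataFrame, trait: str = "trait",
             covariate_cols: tuple = ("sex",), maf_min: float = 0.01,
             max_marker_missing: float = 0.10,
             max_sample_missing: float = 0.10) -> ScanPipelineResult:
    """QC -> founder frequencies -> impute -> GRM -> REML -> scan table."""
    geno, _report = qc_filter(geno, maf_min=maf_min,
                              max_marker_missing=max_marker_missing,
                              max_sample_missing=max_sample_missing)
    p = founder_allele_freqs(geno, samples)
    keep = (p > 0) & (p < 1)
    if not keep.all():
        geno = geno.subset(marker_idx=np.where(keep)[0])
        p = p[keep]
    geno = mean_impute(geno, p)
    Z = standardize(geno, p)
    G = compute_grm(Z, sample_ids=geno.samples)
    data = build_design(geno, phenotypes, trait=trait,
                        covariate_cols=covariate_cols)
    fit = reml_fit(data, G)
    scan = scan_table(fit, G, Z, geno.markers)
    return ScanPipelineResult(geno=geno, p=p, Z=Z, G=G, data=data, fit=fit,
                              scan=scan)
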