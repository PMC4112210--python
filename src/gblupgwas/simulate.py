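"""Synthetic F2-cross generator for end-to-end testing of the scan pipeline.

Emulates a two-line resource population: a handful of line-A sires and
line-B dams (founders, F0), an F1 generation from A x B matings, and an F2
generation from F1 x F1 matings avoiding full-sib pairs where possible.
Founder haplotypes come from a first-order Markov chain whose stationary
allele frequencies follow a Beta distribution (drawn separately per line,
so the lines diverge) and whose adjacent-marker correlation is ``ld_rho``.
Meiosis uses Haldane's model: a Poisson number of crossovers at one
expected crossover per 100 Mb.  The phenotype is additive: a configurable
number of QTL (or an explicit list), a sex fixed effect, and a residual
variance chosen so the realized heritability matches ``h2_target`` in
expectation.  Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, MarkerMap, SampleTable
from .mixedmodel import DesignData


@dataclass
class SimConfig:
    n_founders_a: int = 4
    n_founders_b: int = 15
    n_f1: int = 40
    n_f2: int = 300
    chromosomes: tuple = (("1", 100.0, 400), ("2", 100.0, 400))
    ld_rho: float = 0.6
    freq_beta_params: tuple[float, float] = (2.0, 2.0)
    n_qtl: int = 30
    qtl: list[tuple[str, float]] | None = None   # explicit (snp_id, effect)
    qtl_effect_sd: float = 1.0
    h2_target: float = 0.42
    sex_effect: float = 1.0
    intercept: float = 10.0
    crossover_per_mb: float = 0.01               # Haldane, 1 per 100 Mb
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must lie in (0, 1)")
        for name, length, m in self.chromosomes:
            if length <= 0 or m < 1:
                raise ValueError(
                    f"bad chromosome definition {(name, length, m)}")


@dataclass
class SimOutput:
    geno: GenotypeMatrix                 # all generations, no missing calls
    samples: SampleTable                 # founder flag, sex, generation
    phenotypes: pd.DataFrame             # F2 records: sample_id, trait, sex
    truth: dict                          # qtl table, tbv, realized h2, sigma2_e

    def design(self) -> DesignData:
        """DesignData for the phenotyped animals (intercept + sex)."""
        ph = self.phenotypes
        pos = {s: i for i, s in enumerate(self.geno.samples)}
        obs_idx = np.array([pos[s] for s in ph["sample_id"]])
        X = np.column_stack([np.ones(len(ph)), ph["sex"].to_numpy(float)])
        return DesignData(y=ph["trait"].to_numpy(float), X=X, obs_idx=obs_idx)


def _marker_map(config: SimConfig) -> MarkerMap:
    ids, chroms, pos = [], [], []
    for name, length_mb, m in config.chromosomes:
        # evenly spaced 1-based bp positions across the chromosome
        bp = np.round(np.linspace(1, length_mb * 1e6, m)).astype(int)
        ids += [f"snp_{name}_{j}" for j in range(m)]
        chroms += [str(name)] * m
        pos += bp.tolist()
    return MarkerMap(np.asarray(ids, dtype=object),
                     np.asarray(chroms, dtype=object),
                     np.asarray(pos, dtype=int))


def _markov_haplotypes(n_hap: int, freqs: np.ndarray, rho: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Binary haplotypes with stationary frequencies ``freqs`` and adjacent
    correlation ``rho`` from a first-order Markov chain (transitions clipped
    into [0, 1], which slightly attenuates LD at extreme frequencies)."""
    m = len(freqs)
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        p_prev, p_cur = freqs[j - 1], freqs[j]
        delta = rho * np.sqrt(p_cur * (1 - p_cur))
        p11 = np.clip(p_cur + delta * np.sqrt((1 - p_prev) / p_prev), 0, 1)
        p01 = np.clip(p_cur - delta * np.sqrt(p_prev / (1 - p_prev)), 0, 1)
        prob = np.where(H[:, j - 1] == 1, p11, p01)
        H[:, j] = rng.random(n_hap) < prob
    return H


def sim_founder_haplotypes(config: SimConfig,
                           rng: np.random.Generator) -> dict:
    """Per-line founder haplotype pools, one (2*n_founders, m) block per line."""
    a, b = config.freq_beta_params
    pools = {"A": [], "B": []}
    for line, n_f in (("A", config.n_founders_a), ("B", config.n_founders_b)):
        per_chrom = []
        for name, length_mb, m in config.chromosomes:
            freqs = np.clip(rng.beta(a, b, size=m), 0.02, 0.98)
            per_chrom.append(_markov_haplotypes(2 * n_f, freqs, config.ld_rho, rng))
        pools[line] = per_chrom
    return pools


def _meiosis(hap_pair: list[np.ndarray], config: SimConfig,
             rng: np.random.Generator) -> list[np.ndarray]:
    """One gamete per chromosome from a parent's two haplotypes (Haldane)."""
    gamete = []
    for (name, length_mb, m), (h0, h1) in zip(config.chromosomes, hap_pair):
        pos_mb = np.linspace(0, length_mb, m)
        n_x = rng.poisson(config.crossover_per_mb * length_mb)
        phase = int(rng.integers(2))
        if n_x == 0:
            gamete.append((h0 if phase == 0 else h1).copy())
            continue
        xpos = np.sort(rng.uniform(0, length_mb, size=n_x))
        # phase flips at each crossover position
        flips = np.searchsorted(xpos, pos_mb, side="right")
        current = (phase + flips) % 2
        gamete.append(np.where(current == 0, h0, h1).copy())
    return gamete


def _split_pool(pool_line: list[np.ndarray], n_ind: int) -> list:
    """Turn a per-chromosome haplotype block into per-individual pairs."""
    inds = []
    for i in range(n_ind):
        inds.append([(chrom[2 * i], chrom[2 * i + 1]) for chrom in pool_line])
    return inds


def sim_cross(haplotypes: dict, config: SimConfig,
              rng: np.random.Generator) -> tuple[GenotypeMatrix, SampleTable]:
    """Breed F1 (A x B) and F2 (F1 x F1, avoiding full sibs) genotypes."""
    founders_a = _split_pool(haplotypes["A"], config.n_founders_a)
    founders_b = _split_pool(haplotypes["B"], config.n_founders_b)

    def mate(p1, p2):
        g1, g2 = _meiosis(p1, config, rng), _meiosis(p2, config, rng)
        return [(a, b) for a, b in zip(g1, g2)]

    f1, f1_parents = [], []
    for _ in range(config.n_f1):
        i = int(rng.integers(config.n_founders_a))
        j = int(rng.integers(config.n_founders_b))
        f1.append(mate(founders_a[i], founders_b[j]))
        f1_parents.append((i, j))

    f2 = []
    n_f1 = len(f1)
    for _ in range(config.n_f2):
        for _attempt in range(20):
            i, j = rng.integers(n_f1, size=2)
            if i != j and f1_parents[i] != f1_parents[j]:
                break
        else:
            i, j = rng.integers(n_f1, size=2)
            if i == j:
                j = (i + 1) % n_f1
        f2.append(mate(f1[int(i)], f1[int(j)]))

    ids, gen, rows = [], [], []
    for tag, group in (("F0A", founders_a), ("F0B", founders_b),
                       ("F1", f1), ("F2", f2)):
        for k, ind in enumerate(group):
            ids.append(f"{tag}_{k}")
            gen.append(tag[:2])
            rows.append(np.concatenate([h0.astype(float) + h1
                                        for h0, h1 in ind]))
    dosage = np.asarray(rows, dtype=float)
    mm = _marker_map(config)
    geno = GenotypeMatrix(np.asarray(ids, dtype=object), mm, dosage)
    sex = rng.integers(2, size=len(ids))
    frame = pd.DataFrame({
        "founder": [g == "F0" for g in gen],
        "generation": gen,
        "sex": sex,
    }, index=pd.Index(ids, name="sample_id"))
    return geno, SampleTable(frame)


def sim_phenotype(geno: GenotypeMatrix, samples: SampleTable,
                  config: SimConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, dict]:
    """Additive phenotype for the F2 animals with realized-h2 calibration."""
    is_f2 = (samples.frame["generation"] == "F2").to_numpy()
    f2_idx = np.where(is_f2)[0]
    if config.qtl is not None:
        qtl_ids = [q for q, _ in config.qtl]
        qtl_idx = geno.marker_indices(qtl_ids)
        effects = np.array([e for _, e in config.qtl], dtype=float)
    else:
        maf_f2 = np.minimum.reduce([
            geno.dosage[f2_idx].mean(axis=0) / 2,
            1 - geno.dosage[f2_idx].mean(axis=0) / 2])
        candidates = np.where(maf_f2 > 0.05)[0]
        if len(candidates) < config.n_qtl:
            candidates = np.arange(geno.n_markers)
        qtl_idx = np.sort(rng.choice(candidates, size=config.n_qtl,
                                     replace=False))
        effects = rng.normal(0.0, config.qtl_effect_sd, size=config.n_qtl)
    centred = geno.dosage[:, qtl_idx] - geno.dosage[f2_idx][:, qtl_idx].mean(axis=0)
    tbv = centred @ effects
    var_g = float(np.var(tbv[f2_idx]))
    if var_g == 0:
        raise ValueError("zero genetic variance: h2 target unreachable")
    sigma2_e = var_g * (1.0 - config.h2_target) / config.h2_target
    sex = samples.frame["sex"].to_numpy()
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=geno.n_samples)
    y = config.intercept + config.sex_effect * sex + tbv + e
    phen = pd.DataFrame({
        "sample_id": geno.samples[f2_idx],
        "trait": y[f2_idx],
        "sex": sex[f2_idx],
    })
    truth = {
        "qtl": pd.DataFrame({"snp_id": geno.markers.snp_id[qtl_idx],
                             "marker_idx": qtl_idx, "effect": effects}),
        "tbv": pd.Series(tbv, index=geno.samples),
        "sigma2_g": var_g,
        "sigma2_e": sigma2_e,
        "realized_h2": var_g / (var_g + sigma2_e),
    }
    return phen, truth


def simulate(config: SimConfig | None = None,
             seed: int | None = None) -> SimOutput:
    """Full pipeline: founder haplotypes -> cross -> phenotype."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    pools = sim_founder_haplotypes(config, rng)
    geno, samples = sim_cross(pools, config, rng)
    phen, truth = sim_phenotype(geno, samples, config, rng)
    return SimOutput(geno=geno, samples=samples, phenotypes=phen, truth=truth)


def write_files(sim: SimOutput, outdir) -> dict:
    """Write dosage-tsv, map, sample table, phenotypes and truth as TSVs."""
    import os

    from .geno_io import write_dosage_tsv, write_marker_map

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(outdir, "genotypes.tsv"),
        "map": os.path.join(outdir, "map.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "qtl": os.path.join(outdir, "truth_qtl.tsv"),
        "tbv": os.path.join(outdir, "truth_tbv.tsv"),
    }
    write_dosage_tsv(sim.geno, paths["genotypes"])
    write_marker_map(sim.geno.markers, paths["map"])
    sf = sim.samples.frame.copy()
    sf["founder"] = sf["founder"].astype(int)
    sf.to_csv(paths["samples"], sep="\t")
    sim.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    sim.truth["qtl"].to_csv(paths["qtl"], sep="\t", index=False)
    sim.truth["tbv"].rename("tbv").to_csv(paths["tbv"], sep="\t",
                                          index_label="sample_id")
    return paths
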