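"""Genotype, map and phenotype I/O plus data editing.

Dosages are counts of the reference allele (0/1/2) with missing values
carried as NaN until :func:`mean_impute` replaces them by twice the
reference-allele frequency.  Editing follows the usual SNP-chip pipeline:
drop unmapped markers, drop high-missingness samples, drop high-missingness
markers, drop low-MAF markers — in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_CODES = {"NA", "N/A", "-9", "", "NAN", "nan", "NaN", "na"}


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


@dataclass(frozen=True)
class MarkerMap:
    """Physical marker map: id, chromosome label, 1-based bp position."""

    snp_id: np.ndarray        # str array, unique
    chromosome: np.ndarray    # str array
    position_bp: np.ndarray   # int array, -1 encodes "unmapped"

    def __post_init__(self):
        ids = np.asarray(self.snp_id, dtype=object)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate snp_ids in marker map")
        if np.any(np.asarray(self.position_bp) < -1):
            raise ValueError("marker positions must be non-negative (-1 = unmapped)")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def position_mb(self) -> np.ndarray:
        """Positions in Mb, derived at full precision (never rounded)."""
        return np.asarray(self.position_bp, dtype=float) / 1e6

    @property
    def mapped(self) -> np.ndarray:
        return np.asarray(self.position_bp) >= 0

    def subset(self, idx) -> "MarkerMap":
        return MarkerMap(
            snp_id=np.asarray(self.snp_id)[idx],
            chromosome=np.asarray(self.chromosome)[idx],
            position_bp=np.asarray(self.position_bp)[idx],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(
            snp_id=df["snp_id"].astype(str).to_numpy(),
            chromosome=df["chromosome"].astype(str).to_numpy(),
            position_bp=df["position_bp"].astype(int).to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_id, "chromosome": self.chromosome,
             "position_bp": self.position_bp}
        )


@dataclass
class GenotypeMatrix:
    """n x m allele-dosage matrix with a marker map.

    ``dosage`` is float with NaN for missing calls; values lie in [0, 2].
    """

    samples: np.ndarray          # str array of sample ids, length n
    markers: MarkerMap           # length m
    dosage: np.ndarray           # (n, m) float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        with np.errstate(invalid="ignore"):
            if np.any((self.dosage < 0) | (self.dosage > 2)):
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        s = slice(None) if sample_idx is None else sample_idx
        m = slice(None) if marker_idx is None else marker_idx
        return GenotypeMatrix(
            samples=self.samples[s],
            markers=self.markers if marker_idx is None else self.markers.subset(m),
            dosage=self.dosage[s][:, m] if marker_idx is not None else self.dosage[s],
        )

    def marker_indices(self, snp_ids) -> np.ndarray:
        """Positions of the given snp_ids in this matrix (error if absent)."""
        lookup = {s: i for i, s in enumerate(self.markers.snp_id)}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"markers not present in genotype matrix: {missing[:5]}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: founder flag and fixed-effect covariates."""

    frame: pd.DataFrame  # indexed by sample_id; column 'founder' boolean

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample_ids in sample table")
        if "founder" not in self.frame.columns:
            raise ValueError("sample table requires a 'founder' column")

    @property
    def founders(self) -> np.ndarray:
        return self.frame.index[self.frame["founder"].astype(bool)].to_numpy()


@dataclass
class QCReport:
    """Tally of markers/samples removed by each editing rule."""

    n_samples_in: int
    n_markers_in: int
    markers_unmapped: int = 0
    samples_missingness: int = 0
    markers_missingness: int = 0
    markers_maf: int = 0
    n_samples_out: int = 0
    n_markers_out: int = 0

    def validate(self) -> None:
        if self.n_samples_in - self.samples_missingness != self.n_samples_out:
            raise AssertionError("sample QC tally does not balance")
        removed = self.markers_unmapped + self.markers_missingness + self.markers_maf
        if self.n_markers_in - removed != self.n_markers_out:
            raise AssertionError("marker QC tally does not balance")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("markers_unmapped", self.markers_unmapped),
            ("samples_missingness", self.samples_missingness),
            ("markers_missingness", self.markers_missingness),
            ("markers_maf", self.markers_maf),
            ("n_samples_in", self.n_samples_in),
            ("n_samples_out", self.n_samples_out),
            ("n_markers_in", self.n_markers_in),
            ("n_markers_out", self.n_markers_out),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_marker_map(path) -> MarkerMap:
    """Read a TSV marker map with columns snp_id, chromosome, position_bp."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chromosome": str})
    required = {"snp_id", "chromosome", "position_bp"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(f"marker map needs columns {sorted(required)}")
    df["position_bp"] = df["position_bp"].fillna(-1).astype(int)
    return MarkerMap.from_frame(df)


def read_phenotypes(path, trait: str | None = None) -> pd.DataFrame:
    """Read the phenotype/covariate TSV, indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    if trait is not None and trait not in df.columns:
        raise GenotypeParseError(f"trait column {trait!r} absent from {path}")
    return df


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    if "founder" in df.columns:
        df["founder"] = df["founder"].astype(int).astype(bool)
    return SampleTable(df)


def _parse_dosage_token(tok: str) -> float:
    t = tok.strip()
    if t in MISSING_CODES:
        return np.nan
    try:
        v = float(t)
    except ValueError as exc:
        raise GenotypeParseError(f"unparseable dosage value {tok!r}") from exc
    if v == -9:
        return np.nan
    return v


def _read_dosage_table(path, id_cols: int, skip_extra: int = 0) -> tuple[list, list, np.ndarray]:
    """Shared row-wise parser for dosage-tsv / plink-raw style tables."""
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise GenotypeParseError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t") if "\t" in header else header.split()
        snp_ids = cols[id_cols + skip_extra:]
        samples, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t") if "\t" in line else line.split()
            if len(parts) != len(cols):
                raise GenotypeParseError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {len(cols)}"
                )
            samples.append(parts[id_cols - 1])
            rows.append([_parse_dosage_token(t) for t in parts[id_cols + skip_extra:]])
    if not samples:
        raise GenotypeParseError(f"{path}: no sample rows")
    return samples, snp_ids, np.asarray(rows, dtype=float)


def _strip_raw_suffix(name: str) -> str:
    # PLINK --recode A appends _<counted allele> to each SNP column
    if "_" in name and len(name.rsplit("_", 1)[1]) <= 2:
        return name.rsplit("_", 1)[0]
    return name


def read_genotypes(path, fmt: str = "dosage-tsv",
                   marker_map: MarkerMap | None = None) -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    Formats: ``dosage-tsv`` (header of snp_ids, first column sample_id),
    ``plink-raw`` (PLINK 1.9 ``--recode A``), ``plink-bed`` (binary triplet;
    ``path`` is the .bed file or the shared prefix).  NA / -9 / blank are
    missing.  Sample and marker order are preserved from the file.
    """
    if fmt == "dosage-tsv":
        samples, snp_ids, dosage = _read_dosage_table(path, id_cols=1)
    elif fmt == "plink-raw":
        # FID IID PAT MAT SEX PHENOTYPE then one column per SNP
        samples, snp_ids, dosage = _read_dosage_table(path, id_cols=2, skip_extra=4)
        snp_ids = [_strip_raw_suffix(s) for s in snp_ids]
    elif fmt == "plink-bed":
        return _read_plink_bed(path, marker_map)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")

    if marker_map is not None:
        order = {s: i for i, s in enumerate(marker_map.snp_id)}
        try:
            idx = np.array([order[s] for s in snp_ids])
        except KeyError as exc:
            raise GenotypeParseError(f"marker {exc} absent from marker map") from exc
        mm = marker_map.subset(idx)
    else:
        m = len(snp_ids)
        mm = MarkerMap(np.asarray(snp_ids, dtype=object),
                       np.asarray(["0"] * m, dtype=object),
                       np.full(m, -1, dtype=int))
    return GenotypeMatrix(np.asarray(samples, dtype=object), mm, dosage)


_BED_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])  # 2-bit codes 00,01,10,11


def _read_plink_bed(path, marker_map: MarkerMap | None) -> GenotypeMatrix:
    """Minimal decoder for the PLINK 1 binary triplet (SNP-major .bed)."""
    import os

    prefix = str(path)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"snp_id": str, "chrom": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise GenotypeParseError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != 0x01:
        raise GenotypeParseError(f"{prefix}.bed: only SNP-major layout supported")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise GenotypeParseError(f"{prefix}.bed: truncated ({body.size} body bytes)")
    codes = body.reshape(m, bytes_per_snp)[:, :, None] >> (2 * np.arange(4)[None, None, :])
    codes = (codes & 0b11).reshape(m, -1)[:, :n]
    # .bed counts the A1 allele; dosage is the count of the reference (A1) allele
    dosage = _BED_DOSAGE[codes].T  # (n, m)
    mm = MarkerMap(bim["snp_id"].to_numpy(dtype=object),
                   bim["chrom"].to_numpy(dtype=object),
                   bim["pos"].astype(int).to_numpy())
    if marker_map is not None:
        pos = {s: i for i, s in enumerate(marker_map.snp_id)}
        idx = np.array([pos[s] for s in mm.snp_id if s in pos])
        if len(idx) == len(mm):
            mm = marker_map.subset(idx)
    return GenotypeMatrix(fam["iid"].to_numpy(dtype=object), mm, dosage)


# ---------------------------------------------------------------------------
# writers (used by the simulator and the CLI)
# ---------------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(map(str, geno.markers.snp_id)) + "\n")
        for i, s in enumerate(geno.samples):
            row = ["%g" % v if np.isfinite(v) else "NA" for v in geno.dosage[i]]
            fh.write(str(s) + "\t" + "\t".join(row) + "\n")


def write_plink_raw(geno: GenotypeMatrix, path) -> None:
    """Write a PLINK 1.9 --recode A style file (counted allele suffix _A)."""
    with open(path, "w") as fh:
        head = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        head += [f"{s}_A" for s in geno.markers.snp_id]
        fh.write(" ".join(head) + "\n")
        for i, s in enumerate(geno.samples):
            row = [str(s), str(s), "0", "0", "0", "-9"]
            row += ["%g" % v if np.isfinite(v) else "NA" for v in geno.dosage[i]]
            fh.write(" ".join(row) + "\n")


def write_marker_map(mm: MarkerMap, path) -> None:
    mm.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# editing
# ---------------------------------------------------------------------------

def qc_filter(geno: GenotypeMatrix, maf_min: float = 0.01,
              max_marker_missing: float = 0.10,
              max_sample_missing: float = 0.10,
              drop_unmapped: bool = True) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the editing rules in order: unmapped markers, sample
    missingness, marker missingness, MAF (computed on remaining samples).

    Comparisons are strict: a marker/sample is removed iff its missing
    fraction exceeds the threshold, a marker iff its MAF is strictly below
    ``maf_min``.  Monomorphic markers fall under the MAF rule (MAF 0).
    """
    if geno.n_markers == 0 or geno.n_samples == 0:
        raise ValueError("qc_filter requires a non-empty genotype matrix")
    report = QCReport(n_samples_in=geno.n_samples, n_markers_in=geno.n_markers)

    if drop_unmapped:
        keep = geno.markers.mapped
        report.markers_unmapped = int((~keep).sum())
        geno = geno.subset(marker_idx=np.where(keep)[0])

    miss = geno.missing_mask
    if geno.n_markers:
        frac_sample = miss.mean(axis=1)
        keep_s = frac_sample <= max_sample_missing
        report.samples_missingness = int((~keep_s).sum())
        geno = geno.subset(sample_idx=np.where(keep_s)[0])

    miss = geno.missing_mask
    if geno.n_samples:
        frac_marker = miss.mean(axis=0)
        keep_m = frac_marker <= max_marker_missing
        report.markers_missingness = int((~keep_m).sum())
        geno = geno.subset(marker_idx=np.where(keep_m)[0])

    if geno.n_markers and geno.n_samples:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(geno.dosage, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        keep_m = maf >= maf_min
        report.markers_maf = int((~keep_m).sum())
        geno = geno.subset(marker_idx=np.where(keep_m)[0])

    report.n_samples_out = geno.n_samples
    report.n_markers_out = geno.n_markers
    report.validate()
    if geno.n_markers == 0:
        raise ValueError("genotype matrix empty after QC")
    return geno, report


def founder_allele_freqs(geno: GenotypeMatrix, samples: SampleTable) -> np.ndarray:
    """Reference-allele frequencies from the founder generation.

    p_j = (sum of founder dosages at j) / (2 x non-missing founder calls at j).
    Falls back to all samples (with a warning) when no founder is flagged.
    """
    founders = samples.founders
    in_geno = np.isin(geno.samples.astype(str), founders.astype(str))
    if not in_geno.any():
        logger.warning("no flagged founders among genotyped samples; "
                       "using all samples for allele frequencies")
        in_geno = np.ones(geno.n_samples, dtype=bool)
    d = geno.dosage[in_geno]
    n_called = np.sum(~np.isnan(d), axis=0)
    if np.any(n_called == 0):
        bad = geno.markers.snp_id[n_called == 0]
        raise ValueError(f"markers with no non-missing founder call: {list(bad[:5])}")
    return np.nansum(d, axis=0) / (2.0 * n_called)


def mean_impute(geno: GenotypeMatrix, p: np.ndarray) -> GenotypeMatrix:
    """Replace each missing call at marker j by its expected dosage 2 p_j."""
    p = np.asarray(p, dtype=float)
    if p.shape != (geno.n_markers,):
        raise ValueError(f"frequency vector length {p.shape} does not match "
                         f"{geno.n_markers} markers")
    if not geno.missing_mask.any():
        return geno
    dosage = geno.dosage.copy()
    fill = np.broadcast_to(2.0 * p, dosage.shape)
    dosage[np.isnan(dosage)] = fill[np.isnan(dosage)]
    return GenotypeMatrix(geno.samples, geno.markers, dosage)
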