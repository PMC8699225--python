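"""Genotype/phenotype I/O, marker filtering and dosage recodings.

Genotypes are held as an individuals x markers matrix of allele dosages
(count of alternate-allele copies, ``0..ploidy``), the standard numeric
coding for biallelic SNPs in polyploids.  Missing entries are ``NaN``
until :func:`impute_missing` replaces them with marker means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_META_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


def _default_marker_meta(marker_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": list(marker_ids),
            "chrom": "0",
            "pos": np.arange(1, len(marker_ids) + 1),
            "ref": "A",
            "alt": "B",
        }
    )


@dataclass
class DosageMatrix:
    """Individuals x markers allele-dosage panel with marker metadata.

    Parameters
    ----------
    values
        ``(n, m)`` float array; non-missing entries are dosages in
        ``[0, ploidy]`` (integers before imputation), missing is ``NaN``.
    ploidy
        Number of allele copies per locus (>= 2).
    sample_ids
        Ordered individual labels, unique.
    marker_meta
        Per-marker table with columns ``id, chrom, pos, ref, alt``
        (1-based VCF positions preserved verbatim).
    """

    values: np.ndarray
    ploidy: int
    sample_ids: list[str]
    marker_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D individuals x markers array")
        if self.ploidy < 2:
            raise ValueError("ploidy must be >= 2")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.marker_meta is None:
            self.marker_meta = _default_marker_meta(
                [f"M{i + 1:05d}" for i in range(self.values.shape[1])]
            )
        self.marker_meta = self.marker_meta.reset_index(drop=True)
        missing_cols = set(MARKER_META_COLUMNS) - set(self.marker_meta.columns)
        if missing_cols:
            raise ValueError(f"marker_meta missing columns: {sorted(missing_cols)}")
        if len(self.marker_meta) != self.values.shape[1]:
            raise ValueError("marker_meta length does not match number of markers")
        if self.marker_meta["id"].duplicated().any():
            raise ValueError("marker ids must be unique")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (obs.min() < 0 or obs.max() > self.ploidy):
            raise ValueError(f"dosages must lie in [0, {self.ploidy}]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return self.marker_meta["id"].tolist()

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency: mean dosage / ploidy."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.values, axis=0) / self.ploidy

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def take_samples(self, index: Sequence[int]) -> "DosageMatrix":
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index, :].copy(),
            sample_ids=[self.sample_ids[i] for i in index],
            marker_meta=self.marker_meta.copy(),
        )

    def take_markers(self, index: Sequence[int]) -> "DosageMatrix":
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[:, index].copy(),
            sample_ids=list(self.sample_ids),
            marker_meta=self.marker_meta.iloc[index].reset_index(drop=True),
        )

    def centered(self) -> np.ndarray:
        """Column-centered dosage matrix W - phi*p (requires no missing)."""
        if self.has_missing:
            raise ValueError("centering requires imputed data; run impute_missing first")
        return self.values - self.ploidy * self.allele_freq


@dataclass
class PhenotypeVector:
    """One adjusted trait value (e.g., a BLUE) per individual."""

    values: np.ndarray
    sample_ids: list[str]
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("phenotype values must be 1-D")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.size:
            raise ValueError("sample_ids length does not match values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if np.isinf(self.values).any():
            raise ValueError("phenotypes contain infinities")

    @property
    def n_samples(self) -> int:
        return self.values.size


def align(d: DosageMatrix, y: PhenotypeVector) -> tuple[DosageMatrix, PhenotypeVector]:
    """Subset genotypes and phenotypes to their sample intersection.

    Order follows the genotype panel.  Raises if the intersection is empty.
    """
    pheno_index = {s: i for i, s in enumerate(y.sample_ids)}
    keep = [i for i, s in enumerate(d.sample_ids) if s in pheno_index]
    if not keep:
        raise ValueError("no samples shared between genotypes and phenotypes")
    if len(keep) < d.n_samples or len(keep) < y.n_samples:
        logger.info(
            "aligning samples: %d shared of %d genotyped / %d phenotyped",
            len(keep), d.n_samples, y.n_samples,
        )
    d2 = d.take_samples(keep)
    yv = np.array([y.values[pheno_index[s]] for s in d2.sample_ids])
    return d2, PhenotypeVector(yv, d2.sample_ids, y.trait)


# ---------------------------------------------------------------------------
# VCF / delimited readers and writers
# ---------------------------------------------------------------------------

def read_vcf_dosage(
    path: str,
    ploidy: int,
    field_policy: str = "genotype-calls",
    dosage_field: str = "DS",
) -> tuple[DosageMatrix, dict]:
    """Read a VCF into a dosage matrix, keeping only biallelic SNPs.

    ``field_policy`` selects how dosage is derived: ``genotype-calls``
    counts alternate alleles in GT (arity must equal ``ploidy``), while
    ``dosage-field`` rounds the per-sample ``dosage_field`` value to the
    nearest integer.  Multiallelic records and indels are dropped and
    counted in the returned report dict.
    """
    import pysam

    if field_policy not in ("genotype-calls", "dosage-field"):
        raise ValueError(f"unknown field_policy: {field_policy!r}")

    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    rows: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    report = {"kept": 0, "multiallelic_dropped": 0, "indel_dropped": 0}

    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            report["multiallelic_dropped"] += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == "." or alt == ".":
            report["indel_dropped"] += 1
            continue
        dos = np.full(len(samples), np.nan)
        for j, s in enumerate(samples):
            sample = rec.samples[s]
            if field_policy == "genotype-calls":
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                if len(gt) != ploidy:
                    raise ValueError(
                        f"GT arity {len(gt)} != ploidy {ploidy} at record "
                        f"{rec.chrom}:{rec.pos} sample {s}"
                    )
                if any(a is None for a in gt):
                    continue  # partial call treated as missing
                dos[j] = sum(1 for a in gt if a == 1)
            else:
                val = sample.get(dosage_field)
                if val is None:
                    continue
                if isinstance(val, tuple):
                    val = val[0]
                if val is None:
                    continue
                val = float(val)
                if val < 0 or val > ploidy:
                    raise ValueError(
                        f"dosage field {dosage_field}={val} outside [0, {ploidy}] "
                        f"at record {rec.chrom}:{rec.pos} sample {s}"
                    )
                dos[j] = round(val)
        rid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
        meta_rows.append((rid, str(rec.chrom), int(rec.pos), ref, alt))
        rows.append(dos)
        report["kept"] += 1
    vcf.close()

    if not rows:
        raise ValueError(f"no biallelic SNP records found in {path}")
    values = np.column_stack(rows)
    meta = pd.DataFrame(meta_rows, columns=MARKER_META_COLUMNS)
    return DosageMatrix(values, ploidy, samples, meta), report


def write_vcf(d: DosageMatrix, path: str) -> None:
    """Write a dosage matrix as an uncompressed VCF with polyploid GT calls.

    Dosages are emitted as unphased GT strings with ``round(dosage)`` alt
    alleles; missing entries become fully missing calls.
    """
    phi = d.ploidy
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(d.marker_meta["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(d.sample_ids)
            + "\n"
        )
        missing_gt = "/".join(["."] * phi)
        for i, meta in enumerate(d.marker_meta.itertuples(index=False)):
            calls = []
            for v in d.values[:, i]:
                if np.isnan(v):
                    calls.append(missing_gt)
                else:
                    k = int(round(v))
                    calls.append("/".join(["0"] * (phi - k) + ["1"] * k))
            fh.write(
                f"{meta.chrom}\t{meta.pos}\t{meta.id}\t{meta.ref}\t{meta.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_matrix(d: DosageMatrix, path: str, sep: str = ",") -> None:
    """Write a dosage matrix as delimited text (individuals as rows).

    The first line carries ``#ploidy=<phi>``; marker metadata goes to a
    sidecar ``<path>.markers.csv`` so a round trip preserves it.
    """
    df = pd.DataFrame(d.values, index=d.sample_ids, columns=d.marker_ids)
    with open(path, "w") as fh:
        fh.write(f"#ploidy={d.ploidy}\n")
        df.to_csv(fh, sep=sep, index_label="sample_id")
    d.marker_meta.to_csv(f"{path}.markers.csv", index=False)


def read_matrix(path: str, sep: str = ",", ploidy: int | None = None) -> DosageMatrix:
    """Read a delimited dosage matrix written by :func:`write_matrix`.

    If the ``#ploidy=`` header line is absent, ``ploidy`` must be given.
    Marker metadata is restored from the sidecar file when present.
    """
    import os

    with open(path) as fh:
        first = fh.readline().strip()
    skip = 0
    if first.startswith("#ploidy="):
        ploidy = int(first.split("=", 1)[1])
        skip = 1
    if ploidy is None:
        raise ValueError("ploidy not found in file header and not supplied")
    df = pd.read_csv(path, sep=sep, skiprows=skip, index_col=0)
    sidecar = f"{path}.markers.csv"
    meta = None
    if os.path.exists(sidecar):
        meta = pd.read_csv(sidecar, dtype={"id": str, "chrom": str, "ref": str, "alt": str})
    return DosageMatrix(
        df.to_numpy(dtype=float),
        ploidy,
        [str(s) for s in df.index],
        meta if meta is not None else _default_marker_meta([str(c) for c in df.columns]),
    )


def write_phenotypes(y: PhenotypeVector, path: str) -> None:
    pd.DataFrame(
        {"sample_id": y.sample_ids, "trait": y.trait, "value": y.values}
    ).to_csv(path, index=False)


def read_phenotypes(path: str, trait: str | None = None) -> PhenotypeVector:
    """Read a phenotype CSV with columns ``sample_id, trait, value``."""
    df = pd.read_csv(path, dtype={"sample_id": str, "trait": str})
    required = {"sample_id", "trait", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(required)}")
    traits = df["trait"].unique()
    if trait is None:
        if len(traits) > 1:
            raise ValueError(f"multiple traits present ({list(traits)}); pick one")
        trait = traits[0]
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not found in {path}")
    return PhenotypeVector(sub["value"].to_numpy(float), sub["sample_id"].tolist(), trait)


# ---------------------------------------------------------------------------
# Filters and recodings
# ---------------------------------------------------------------------------

def impute_missing(d: DosageMatrix) -> DosageMatrix:
    """Replace missing entries with the marker mean dosage.

    Markers with no observed values are dropped with a warning.  Marker
    means (hence allele frequencies) are unchanged by the imputation.
    """
    vals = d.values.copy()
    n_obs = (~np.isnan(vals)).sum(axis=0)
    dead = n_obs == 0
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} fully missing marker(s)", stacklevel=2
        )
        keep = np.flatnonzero(~dead)
        d = d.take_markers(keep)
        vals = vals[:, keep]
    miss = np.isnan(vals)
    n_imputed = int(miss.sum())
    if n_imputed:
        col_means = np.nanmean(vals, axis=0)
        vals[miss] = np.broadcast_to(col_means, vals.shape)[miss]
        logger.info("imputed %d missing entries with marker means", n_imputed)
    return replace(d, values=vals, marker_meta=d.marker_meta.copy())


def filter_maf(d: DosageMatrix, maf_min: float = 0.05) -> DosageMatrix:
    """Drop markers with minor-allele frequency below ``maf_min``.

    Monomorphic markers (``p`` of 0 or 1) are always removed: they have
    ``p(1-p) = 0`` and would break every relationship-matrix denominator.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    p = d.allele_freq
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero((maf >= maf_min) & (maf > 0))
    if keep.size == 0:
        raise ValueError("no markers pass MAF filter")
    if keep.size < d.n_markers:
        logger.info("MAF filter removed %d of %d markers", d.n_markers - keep.size, d.n_markers)
    return d.take_markers(keep)


_PSEUDODIPLOID_MAP = {0: 0.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 2.0}


def pseudodiploid_recode(d: DosageMatrix) -> DosageMatrix:
    """Collapse tetraploid dosages to a diploid-like 0/1/2 coding.

    All heterozygous classes (dosage 1, 2, 3) share one effect class;
    the homozygotes map to 0 and 2.  Output ploidy is 2.  Only defined
    for tetraploid input — recoding an already diploid matrix errors.
    """
    if d.ploidy != 4:
        raise ValueError(f"pseudodiploid_recode requires ploidy 4, got {d.ploidy}")
    vals = d.values.copy()
    obs = ~np.isnan(vals)
    if not np.all(np.equal(np.mod(vals[obs], 1), 0)):
        raise ValueError("pseudodiploid_recode requires integer dosages (recode before imputation)")
    out = np.full_like(vals, np.nan)
    for k, v in _PSEUDODIPLOID_MAP.items():
        out[vals == k] = v
    return replace(d, values=out, ploidy=2, marker_meta=d.marker_meta.copy())


def indicator_expand(d: DosageMatrix) -> tuple[np.ndarray, np.ndarray]:
    """One-hot expand each tetraploid marker into 5 genotype-class columns.

    Returns ``(indicators, class_freq)`` where ``indicators`` is
    ``(n, 5*m)`` with exactly one 1 per individual per marker (class order
    dosage 0..4 within each marker) and ``class_freq`` holds each column's
    observed genotype-class frequency.
    """
    if d.ploidy != 4:
        raise ValueError(f"indicator_expand requires ploidy 4, got {d.ploidy}")
    if d.has_missing:
        raise ValueError("indicator_expand requires no missing values; run impute_missing")
    vals = np.rint(d.values).astype(int)
    if not np.array_equal(vals, d.values):
        raise ValueError("indicator_expand requires integer dosages")
    n, m = vals.shape
    ind = np.zeros((n, 5 * m))
    cols = 5 * np.arange(m)[None, :] + vals
    ind[np.arange(n)[:, None], cols] = 1.0
    return ind, ind.mean(axis=0)
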