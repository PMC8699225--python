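"""Genomic relationship matrix (GRM) builders.

Four constructions are provided:

* ``vanraden_grm`` — centered cross-product ``(W - Wbar)(W - Wbar)' / c``.
  As printed in the source formulation the numerator is written ``ZZ'``
  with "Z an identity matrix for the markers"; taken literally that
  quadratic form is degenerate, so Z is interpreted as the column-centered
  dosage matrix (the standard VanRaden construction).  Two denominators
  are offered: ``ploidy_scaled`` uses ``phi * sum(p(1-p))`` (unit expected
  diagonal for dosages 0..phi) and ``paper_literal`` uses the printed
  diploid constant ``2 * sum(p(1-p))``.
* ``yang_grm`` — allele-frequency-weighted per-marker average with
  distinct diagonal and off-diagonal forms (diploid coding only).
* ``slater_full_autotetraploid_grm`` — genotype-class indicator version
  for tetraploids, 5 columns per marker.
* ``weighted_grm`` — ``(W - Wbar) D (W - Wbar)' / c`` with per-marker
  weights on the diagonal of D; with unit weights it reduces exactly to
  ``vanraden_grm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polygs.dosage_io import DosageMatrix, indicator_expand

DENOMINATOR_POLICIES = ("ploidy_scaled", "paper_literal")


@dataclass
class KinshipMatrix:
    """n x n relationship matrix with its construction tag and scaling."""

    values: np.ndarray
    sample_ids: list[str]
    method: str
    scaling_constant: float = np.nan
    weight_source: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        rows = np.asarray(rows)
        cols = rows if cols is None else np.asarray(cols)
        return self.values[np.ix_(rows, cols)]


@dataclass
class WeightVector:
    """Per-marker nonnegative weights forming the diagonal of D."""

    w: np.ndarray
    source: str = "uniform"
    normalization: str = "mean_one"
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ValueError("weights must be 1-D")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if self.normalization not in ("raw", "mean_one"):
            raise ValueError(f"unknown normalization: {self.normalization!r}")

    def resolved(self) -> np.ndarray:
        """Weights after applying the normalization policy."""
        if self.normalization == "mean_one":
            mean = self.w.mean()
            if mean == 0:
                raise ValueError("all weights are zero; cannot normalize")
            return self.w / mean
        return self.w.copy()


def _check_polymorphic(d: DosageMatrix) -> np.ndarray:
    p = d.allele_freq
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "monomorphic markers present (p(1-p)=0); apply filter_maf first"
        )
    return p


def _denominator(d: DosageMatrix, policy: str) -> float:
    if policy not in DENOMINATOR_POLICIES:
        raise ValueError(f"unknown denominator_policy: {policy!r}")
    p = d.allele_freq
    s = float(np.sum(p * (1 - p)))
    return (d.ploidy if policy == "ploidy_scaled" else 2.0) * s


def vanraden_grm(
    d: DosageMatrix, denominator_policy: str = "ploidy_scaled"
) -> KinshipMatrix:
    """Centered cross-product GRM ``(W - Wbar)(W - Wbar)' / c``.

    Column means equal ``phi * p_i``, so rows of G sum to zero and G is
    positive semidefinite by construction.
    """
    _check_polymorphic(d)
    c = _denominator(d, denominator_policy)
    Z = d.centered()
    G = Z @ Z.T / c
    return KinshipMatrix(G, list(d.sample_ids), "vanraden", scaling_constant=c)


def yang_grm(d: DosageMatrix) -> KinshipMatrix:
    """Allele-frequency-weighted GRM for diploid-coded dosages.

    Off-diagonal: ``(1/N) sum_i (w_ij - 2p_i)(w_ik - 2p_i) / (2p_i(1-p_i))``.
    Diagonal: ``1 + (1/N) sum_i (w_ij^2 - (1+2p_i) w_ij + 2p_i^2) / (2p_i(1-p_i))``.

    The source prose states the coding "0 = AA, 1 = BB, 2 = AB", which is
    inconsistent with the ``2 p_i`` centering; the conventional
    alternate-allele count (0=AA, 1=AB, 2=BB) is used here.
    """
    if d.ploidy != 2:
        raise ValueError(
            "yang_grm requires diploid coding (ploidy 2); use pseudodiploid_recode"
        )
    p = _check_polymorphic(d)
    if d.has_missing:
        raise ValueError("yang_grm requires no missing values")
    W = d.values
    N = d.n_markers
    denom = 2.0 * p * (1 - p)
    Zs = (W - 2.0 * p) / np.sqrt(denom)
    G = Zs @ Zs.T / N
    diag = 1.0 + np.sum((W**2 - (1.0 + 2.0 * p) * W + 2.0 * p**2) / denom, axis=1) / N
    np.fill_diagonal(G, diag)
    return KinshipMatrix(G, list(d.sample_ids), "yang", scaling_constant=float(N))


def slater_full_autotetraploid_grm(d: DosageMatrix) -> KinshipMatrix:
    """Full-autotetraploid GRM over genotype-class indicator columns.

    Each marker contributes 5 one-hot columns (genotype classes AAAA..BBBB);
    with class frequencies ``p_i``, every entry is
    ``1 + (1/M) sum_i (w_ij - p_i)(w_ik - p_i) / (p_i(1-p_i))`` with
    ``M = 5 * markers``.  Indicator columns whose class frequency is 0 or 1
    carry no contrast and are skipped (M is unchanged); markers losing all
    classes are dropped with a warning.
    """
    ind, freq = indicator_expand(d)
    m = d.n_markers
    valid = (freq > 0) & (freq < 1)
    dead_markers = [
        d.marker_ids[j] for j in range(m) if not valid[5 * j : 5 * (j + 1)].any()
    ]
    if dead_markers:
        warnings.warn(
            f"{len(dead_markers)} marker(s) with no informative genotype class "
            f"dropped from full-autotetraploid GRM", stacklevel=2
        )
        keep = [j for j in range(m) if d.marker_ids[j] not in set(dead_markers)]
        d = d.take_markers(keep)
        ind, freq = indicator_expand(d)
        m = d.n_markers
        valid = (freq > 0) & (freq < 1)
    M = 5 * m
    pv = freq[valid]
    Zs = (ind[:, valid] - pv) / np.sqrt(pv * (1 - pv))
    G = 1.0 + Zs @ Zs.T / M
    return KinshipMatrix(
        G, list(d.sample_ids), "full_autotetraploid", scaling_constant=float(M)
    )


def weighted_grm(
    d: DosageMatrix,
    w: WeightVector,
    denominator_policy: str = "ploidy_scaled",
) -> KinshipMatrix:
    """SNP-weighted GRM ``G* = (W - Wbar) D (W - Wbar)' / c``, D = diag(w).

    Weights are normalized to mean one by default (keeps ``tr(G*)``
    comparable to ``tr(G)``); with unit weights the result equals
    :func:`vanraden_grm` exactly.
    """
    _check_polymorphic(d)
    if w.w.size != d.n_markers:
        raise ValueError(
            f"weight length {w.w.size} does not match marker count {d.n_markers}"
        )
    if w.marker_ids is not None and w.marker_ids != d.marker_ids:
        raise ValueError("weight marker ids do not match dosage matrix marker ids")
    wv = w.resolved()
    if np.all(wv == 0):
        raise ValueError("all weights are zero")
    c = _denominator(d, denominator_policy)
    Z = d.centered()
    Zw = Z * np.sqrt(wv)
    G = Zw @ Zw.T / c
    return KinshipMatrix(
        G, list(d.sample_ids), "weighted", scaling_constant=c, weight_source=w.source
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_kinship(k: KinshipMatrix, path: str, sep: str = ",") -> None:
    df = pd.DataFrame(k.values, index=k.sample_ids, columns=k.sample_ids)
    with open(path, "w") as fh:
        fh.write(f"#method={k.method} scaling_constant={k.scaling_constant}\n")
        df.to_csv(fh, sep=sep, index_label="sample_id")


def read_kinship(path: str, sep: str = ",") -> KinshipMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
    method, scaling = "unknown", np.nan
    skip = 0
    if first.startswith("#method="):
        skip = 1
        parts = dict(tok.split("=", 1) for tok in first[1:].split())
        method = parts.get("method", "unknown")
        scaling = float(parts.get("scaling_constant", "nan"))
    df = pd.read_csv(path, sep=sep, skiprows=skip, index_col=0)
    return KinshipMatrix(
        df.to_numpy(float), [str(s) for s in df.index], method, scaling_constant=scaling
    )


def write_weights(w: WeightVector, path: str) -> None:
    ids = w.marker_ids if w.marker_ids is not None else [
        f"M{i + 1:05d}" for i in range(w.w.size)
    ]
    pd.DataFrame({"marker_id": ids, "weight": w.w, "source": w.source}).to_csv(
        path, index=False
    )


def read_weights(path: str, normalization: str = "mean_one") -> WeightVector:
    df = pd.read_csv(path, dtype={"marker_id": str, "source": str})
    required = {"marker_id", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"weight file must have columns {sorted(required)}")
    source = df["source"].iloc[0] if "source" in df.columns else "file"
    return WeightVector(
        df["weight"].to_numpy(float),
        source=str(source),
        normalization=normalization,
        marker_ids=df["marker_id"].tolist(),
    )
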