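"""Kinship-corrected single-marker association scan over dosage models.

Each biallelic tetraploid marker is tested under one or more gene-action
codings of the allele dosage (0..4 = AAAA..BBBB):

==============  =================================================
additive        0.00, 0.25, 0.50, 0.75, 1.00
diplo-additive  0.00, 0.50, 0.50, 0.50, 1.00 (heterozygotes collapsed)
diplo-general   factor over {hom-ref, heterozygote, hom-alt} (2 df)
general         factor over observed dosage classes (up to 4 df)
1-dom-ref       1.00, 1.00, 1.00, 1.00, 0.00 (ref simplex dominant)
2-dom-ref       1.00, 1.00, 1.00, 0.00, 0.00 (ref duplex dominant)
1-dom-alt       0.00, 1.00, 1.00, 1.00, 1.00 (alt simplex dominant)
2-dom-alt       0.00, 0.00, 1.00, 1.00, 1.00 (alt duplex dominant)
==============  =================================================

Testing follows the P3D scheme: variance components are estimated once
under the null (no marker) and each marker is then tested by generalized
least squares with an F-test on its effect block.  Scores are
``-log10 p``, the usual input for SNP-weight construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from polygs.dosage_io import DosageMatrix, PhenotypeVector
from polygs.grm import KinshipMatrix, WeightVector
from polygs.mixed_model import reml_fit

logger = logging.getLogger(__name__)

SCORE_CAP = 300.0


@dataclass(frozen=True)
class DosageModel:
    """A gene-action coding of allele dosage for the marker test."""

    name: str
    kind: str  # "code" (single effect column) or "factor" (indicator block)
    codes: tuple[float, ...] | None = None  # dosage -> effect, code models only
    groups: tuple[int, ...] | None = None  # dosage -> class label, factor models

    @property
    def max_df(self) -> int:
        if self.kind == "code":
            return 1
        return len(set(self.groups)) - 1


DOSAGE_MODELS: dict[str, DosageModel] = {
    "additive": DosageModel("additive", "code", codes=(0.0, 0.25, 0.5, 0.75, 1.0)),
    "diplo-additive": DosageModel(
        "diplo-additive", "code", codes=(0.0, 0.5, 0.5, 0.5, 1.0)
    ),
    "diplo-general": DosageModel(
        "diplo-general", "factor", groups=(0, 1, 1, 1, 2)
    ),
    "general": DosageModel("general", "factor", groups=(0, 1, 2, 3, 4)),
    "1-dom-ref": DosageModel("1-dom-ref", "code", codes=(1.0, 1.0, 1.0, 1.0, 0.0)),
    "2-dom-ref": DosageModel("2-dom-ref", "code", codes=(1.0, 1.0, 1.0, 0.0, 0.0)),
    "1-dom-alt": DosageModel("1-dom-alt", "code", codes=(0.0, 1.0, 1.0, 1.0, 1.0)),
    "2-dom-alt": DosageModel("2-dom-alt", "code", codes=(0.0, 0.0, 1.0, 1.0, 1.0)),
}


def _resolve_model(model: str | DosageModel) -> DosageModel:
    if isinstance(model, DosageModel):
        return model
    try:
        return DOSAGE_MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown dosage model {model!r}; known: {sorted(DOSAGE_MODELS)}"
        ) from None


def design_columns(
    model: str | DosageModel,
    dosages: np.ndarray,
    ploidy: int = 4,
    min_class_count: int = 2,
) -> np.ndarray:
    """Effect design block for one marker under a dosage model.

    Code models yield a single column of per-class effect codes; the
    additive model generalizes to any ploidy as ``dosage / ploidy``.
    Factor models yield an indicator block over observed classes with one
    class as baseline; classes below ``min_class_count`` fold into the
    baseline.  A block with no contrast comes back with zero columns.
    """
    m = _resolve_model(model)
    dos = np.rint(np.asarray(dosages, float)).astype(int)
    if dos.min() < 0 or dos.max() > ploidy:
        raise ValueError(f"dosages outside [0, {ploidy}]")

    if m.kind == "code":
        if m.name == "additive":
            col = dos / ploidy
        else:
            if ploidy != 4:
                raise ValueError(f"model {m.name!r} is defined for ploidy 4")
            col = np.asarray(m.codes, float)[dos]
        if np.ptp(col) == 0:
            return np.empty((dos.size, 0))
        return col[:, None]

    if ploidy != 4 and m.name != "general":
        raise ValueError(f"model {m.name!r} is defined for ploidy 4")
    groups = (
        np.asarray(m.groups)[dos] if m.name != "general" or ploidy == 4 else dos
    )
    labels, counts = np.unique(groups, return_counts=True)
    kept = [lab for lab, cnt in zip(labels, counts) if cnt >= min_class_count]
    if len(kept) < 2:
        return np.empty((dos.size, 0))
    # first retained class is the baseline
    block = np.column_stack([(groups == lab).astype(float) for lab in kept[1:]])
    return block


@dataclass
class ScanResult:
    """Per-(marker, model) association scores with skip diagnostics."""

    scores: pd.DataFrame  # index marker_id, one column per model, -log10 p
    df_tested: pd.DataFrame  # effect degrees of freedom actually used
    reasons: pd.DataFrame  # skip reason or "" per (marker, model)
    marker_meta: pd.DataFrame
    kinship_corrected: bool

    @property
    def models(self) -> list[str]:
        return list(self.scores.columns)

    def n_tested(self, model: str) -> int:
        return int(self.scores[model].notna().sum())

    def n_skipped(self, model: str) -> int:
        return int(self.scores[model].isna().sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (marker_id, chrom, pos, model, score, reason)."""
        rows = []
        for model in self.models:
            sub = self.marker_meta[["id", "chrom", "pos"]].copy()
            sub["model"] = model
            sub["score"] = self.scores[model].to_numpy()
            sub["df"] = self.df_tested[model].to_numpy()
            sub["reason"] = self.reasons[model].to_numpy()
            rows.append(sub)
        return pd.concat(rows, ignore_index=True).rename(columns={"id": "marker_id"})


def _whitener(K: np.ndarray | None, delta: float | None, n: int):
    """Cholesky factor L of (K + delta I); None means identity covariance."""
    if K is None:
        return None
    V = K + delta * np.eye(n)
    return linalg.cholesky(V, lower=True)


def _whiten(L, M: np.ndarray) -> np.ndarray:
    if L is None:
        return M
    return linalg.solve_triangular(L, M, lower=True)


def _block_f_test(yw, Xw, Bw, rss0, Qx):
    """F-test of block Bw added to Xw, on whitened data."""
    n = yw.size
    RB = Bw - Qx @ (Qx.T @ Bw)
    # drop numerically null directions (constant or collinear with Xw)
    Qb, Rb, _ = linalg.qr(RB, mode="economic", pivoting=True)
    if Rb.size == 0:
        return None
    tol = max(RB.shape) * np.finfo(float).eps * abs(Rb[0, 0]) if Rb.size else 0.0
    rank = int(np.sum(np.abs(np.diag(Rb)) > tol))
    if rank == 0:
        return None
    Qb = Qb[:, :rank]
    ry = yw - Qx @ (Qx.T @ yw)
    proj = Qb.T @ ry
    rss1 = rss0 - float(proj @ proj)
    df2 = n - Xw.shape[1] - rank
    if df2 <= 0:
        raise ValueError("fewer observations than fixed-effect columns")
    if rss1 <= 1e-12 * rss0:  # perfect fit up to float noise
        return np.inf, rank, df2
    F = (rss0 - rss1) / rank / (rss1 / df2)
    return F, rank, df2


def scan(
    d: DosageMatrix,
    y: PhenotypeVector,
    K: KinshipMatrix | None = None,
    models: list[str | DosageModel] | None = None,
    covariates: np.ndarray | None = None,
    p3d: bool = True,
    min_class_count: int = 2,
    score_cap: float = SCORE_CAP,
) -> ScanResult:
    """Single-marker association scan returning ``-log10 p`` scores.

    With ``K`` given, the null-model covariance ``K + delta I`` (delta from
    a single REML fit, P3D) whitens the data and every marker is tested by
    GLS; with ``K=None`` tests are plain OLS.  ``p3d=False`` re-estimates
    variance components for every marker (slow, rarely needed).
    """
    if d.sample_ids != y.sample_ids:
        raise ValueError("genotypes and phenotypes are not aligned; call align first")
    if models is None:
        models = list(DOSAGE_MODELS)
    models = [_resolve_model(m) for m in models]
    n = d.n_samples
    yv = y.values
    X0 = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X0 = np.column_stack([X0, cov])
    if n <= X0.shape[1] + max(m.max_df for m in models):
        raise ValueError("fewer individuals than fixed-effect columns")

    Kv = K.values if K is not None else None
    delta = None
    if Kv is not None and p3d:
        vc0 = reml_fit(yv, Kv, X=X0 if covariates is not None else None)
        delta = vc0.delta
        if not np.isfinite(delta):
            # h2 -> 0 boundary: residual covariance is effectively I
            Kv, delta = None, None

    L = _whitener(Kv, delta, n) if (Kv is not None and p3d) else None
    yw = _whiten(L, yv)
    Xw = _whiten(L, X0)
    Qx, _ = linalg.qr(Xw, mode="economic")
    ry = yw - Qx @ (Qx.T @ yw)
    rss0 = float(ry @ ry)

    marker_ids = d.marker_ids
    m_markers = d.n_markers
    scores = {m.name: np.full(m_markers, np.nan) for m in models}
    dfs = {m.name: np.zeros(m_markers, dtype=int) for m in models}
    reasons = {m.name: np.array([""] * m_markers, dtype=object) for m in models}

    for model in models:
        if model.kind == "code" and (p3d or Kv is None):
            _scan_code_vectorized(
                model, d, yw, Xw, Qx, ry, rss0, L, scores, dfs, reasons, score_cap
            )
        else:
            _scan_looped(
                model, d, yv, X0, Kv, p3d, delta, min_class_count,
                scores, dfs, reasons, score_cap,
            )

    return ScanResult(
        scores=pd.DataFrame(scores, index=marker_ids),
        df_tested=pd.DataFrame(dfs, index=marker_ids),
        reasons=pd.DataFrame(reasons, index=marker_ids),
        marker_meta=d.marker_meta.copy(),
        kinship_corrected=Kv is not None,
    )


def _scan_code_vectorized(
    model, d, yw, Xw, Qx, ry, rss0, L, scores, dfs, reasons, score_cap
):
    """All single-column models at once: one whiten + residualize per model."""
    n, m = d.values.shape
    dos = np.rint(d.values).astype(int)
    if model.name == "additive":
        C = dos / d.ploidy
    else:
        if d.ploidy != 4:
            raise ValueError(f"model {model.name!r} is defined for ploidy 4")
        C = np.asarray(model.codes, float)[dos]
    span = np.ptp(C, axis=0)
    Cw = _whiten(L, C)
    RC = Cw - Qx @ (Qx.T @ Cw)
    cc = np.einsum("ij,ij->j", RC, RC)
    cy = RC.T @ ry
    df2 = n - Xw.shape[1] - 1
    ok = (span > 0) & (cc > 1e-12 * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = rss0 - cy**2 / cc
        rss1 = np.where(rss1 < 1e-12 * rss0, 0.0, rss1)  # perfect fit
        F = np.where(rss1 > 0, (rss0 - rss1) / (rss1 / df2), np.inf)
    p = stats.f.sf(F, 1, df2)
    with np.errstate(divide="ignore"):
        s = np.minimum(-np.log10(p), score_cap)
    scores[model.name][ok] = s[ok]
    dfs[model.name][ok] = 1
    reasons[model.name][~ok] = "no contrast"


def _scan_looped(
    model, d, yv, X0, Kv, p3d, delta, min_class_count,
    scores, dfs, reasons, score_cap,
):
    """Per-marker path: factor models, and per-marker REML when p3d=False."""
    n = yv.size
    if p3d or Kv is None:
        L = _whitener(Kv, delta, n) if Kv is not None else None
        yw = _whiten(L, yv)
        Xw = _whiten(L, X0)
        Qx, _ = linalg.qr(Xw, mode="economic")
        ryw = yw - Qx @ (Qx.T @ yw)
        rss0 = float(ryw @ ryw)
    for j in range(d.n_markers):
        B = design_columns(model, d.values[:, j], d.ploidy, min_class_count)
        if B.shape[1] == 0:
            reasons[model.name][j] = "no contrast"
            continue
        if not p3d and Kv is not None:
            vc_j = reml_fit(yv, Kv, X=np.column_stack([X0, B]))
            dj = vc_j.delta
            Lj = _whitener(Kv, dj, n) if np.isfinite(dj) else None
            yw = _whiten(Lj, yv)
            Xw = _whiten(Lj, X0)
            Qx, _ = linalg.qr(Xw, mode="economic")
            ryw = yw - Qx @ (Qx.T @ yw)
            rss0 = float(ryw @ ryw)
            Bw = _whiten(Lj, B)
        else:
            Bw = _whiten(L, B)
        res = _block_f_test(yw, Xw, Bw, rss0, Qx)
        if res is None:
            reasons[model.name][j] = "no contrast"
            continue
        F, df1, df2 = res
        p = stats.f.sf(F, df1, df2)
        with np.errstate(divide="ignore"):
            s = min(-np.log10(p), score_cap) if p > 0 else score_cap
        scores[model.name][j] = s
        dfs[model.name][j] = df1


def scores_to_weights(
    s: ScanResult,
    model: str,
    floor_eps: float = 1e-6,
    normalization: str = "mean_one",
) -> WeightVector:
    """Turn one model's ``-log10 p`` scores into a SNP weight vector.

    Tested markers get ``max(score, floor_eps)``; skipped markers get the
    floor so the weighted GRM never silently zeroes a marker out.
    """
    if model not in s.scores.columns:
        raise ValueError(f"model {model!r} not present in scan result")
    w = s.scores[model].to_numpy(float).copy()
    w[~np.isfinite(w)] = floor_eps
    w = np.maximum(w, floor_eps)
    return WeightVector(
        w,
        source=f"gwas:{model}",
        normalization=normalization,
        marker_ids=list(s.scores.index),
    )


def weight_correlations(weights: dict[str, WeightVector | np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlations among SNP-weight vectors.

    Zero-variance vectors yield NaN for their pairs (undefined correlation).
    """
    if len(weights) < 2:
        raise ValueError("need at least two weight vectors")
    arrays = {
        name: (wv.w if isinstance(wv, WeightVector) else np.asarray(wv, float))
        for name, wv in weights.items()
    }
    sizes = {a.size for a in arrays.values()}
    if len(sizes) != 1:
        raise ValueError("weight vectors cover different marker sets")
    df = pd.DataFrame(arrays)
    return df.corr(method="pearson")
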