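"""Repeated k-fold cross-validation of genomic prediction accuracy.

Accuracy is the Pearson correlation between predicted genetic values and
the observed phenotypes of the held-out fold.  All configurations in one
experiment share fold assignments so per-fold differences are paired.

Two leakage regimes are first-class and always labeled in the output:

* ``nested`` — SNP weights and variance components are recomputed from
  the training fold only (honest generalization estimate);
* ``mimic_paper`` — weights come from a single scan of the full data
  before fold splitting, reproducing the common practice of deriving
  weights and accuracies from the same individuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polygs.dosage_io import DosageMatrix, PhenotypeVector
from polygs.grm import (
    KinshipMatrix,
    WeightVector,
    slater_full_autotetraploid_grm,
    vanraden_grm,
    weighted_grm,
    yang_grm,
)
from polygs.gwas_scan import scan, scores_to_weights
from polygs.mixed_model import gblup_predict, reml_fit

logger = logging.getLogger(__name__)

GRM_METHODS = ("vanraden", "full_autotetraploid", "yang")


def make_folds(n: int, k: int, repeats: int, seed: int) -> np.ndarray:
    """Random balanced fold labels, shape (repeats, n), values in 0..k-1.

    Fold sizes differ by at most one (the first ``n mod k`` folds get the
    extra individual).  Deterministic given the seed.
    """
    if k > n:
        raise ValueError("k cannot exceed n")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    out = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        out[r] = labels[rng.permutation(n)]
    return out


@dataclass
class ModelConfig:
    """One prediction model to evaluate: GRM method + weight source."""

    name: str
    grm_method: str = "vanraden"
    weight_source: str = "uniform"  # uniform | gwas:<model> | external
    external_weights: WeightVector | None = None
    leakage_mode: str = "nested"  # nested | mimic_paper
    denominator_policy: str = "ploidy_scaled"
    weight_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.grm_method not in GRM_METHODS:
            raise ValueError(f"unknown grm_method: {self.grm_method!r}")
        if self.leakage_mode not in ("nested", "mimic_paper"):
            raise ValueError(f"unknown leakage_mode: {self.leakage_mode!r}")
        if self.weight_source == "external" and self.external_weights is None:
            raise ValueError("weight_source='external' requires external_weights")
        if self.grm_method != "vanraden" and self.weight_source != "uniform":
            raise ValueError("SNP weighting is defined on the centered (vanraden) GRM")


@dataclass
class CVReport:
    """Per-(repeat, fold) accuracies for one model configuration."""

    config_name: str
    records: pd.DataFrame  # columns: repeat, fold, r, n_test
    leakage_mode: str
    fold_seed: int
    folds: np.ndarray = field(repr=False)

    @property
    def mean_r(self) -> float:
        return float(self.records["r"].mean())

    @property
    def sd_r(self) -> float:
        return float(self.records["r"].std(ddof=1))

    def summary(self) -> dict:
        return {
            "config": self.config_name,
            "leakage_mode": self.leakage_mode,
            "mean_r": self.mean_r,
            "sd_r": self.sd_r,
            "n_folds": int(len(self.records)),
            "n_missing": int(self.records["r"].isna().sum()),
        }


def _base_grm(d: DosageMatrix, cfg: ModelConfig) -> KinshipMatrix:
    if cfg.grm_method == "vanraden":
        return vanraden_grm(d, cfg.denominator_policy)
    if cfg.grm_method == "full_autotetraploid":
        return slater_full_autotetraploid_grm(d)
    return yang_grm(d)


def _gwas_weights(
    d: DosageMatrix, y: PhenotypeVector, model: str, floor: float
) -> WeightVector:
    K = vanraden_grm(d)
    s = scan(d, y, K=K, models=[model])
    return scores_to_weights(s, model, floor_eps=floor)


def run_cv(
    config: ModelConfig,
    d: DosageMatrix,
    y: PhenotypeVector,
    folds: np.ndarray,
    fold_seed: int = 0,
) -> CVReport:
    """Evaluate one configuration over precomputed fold assignments.

    Kinship is built from genotypes of all individuals (marker data carry
    no phenotype information); REML variance components are always fitted
    on the training fold only.  SNP-weight recomputation follows the
    configuration's leakage mode.  Folds whose test phenotype is constant
    get a missing ``r`` and are excluded from summaries with a warning.
    """
    if d.sample_ids != y.sample_ids:
        raise ValueError("genotypes and phenotypes are not aligned; call align first")
    folds = np.asarray(folds)
    if folds.ndim != 2 or folds.shape[1] != d.n_samples:
        raise ValueError("fold array shape does not match sample count")

    weights_full: WeightVector | None = None
    if config.weight_source == "external":
        weights_full = config.external_weights
    elif config.weight_source.startswith("gwas:"):
        if config.leakage_mode == "mimic_paper":
            weights_full = _gwas_weights(
                d, y, config.weight_source.split(":", 1)[1], config.weight_floor
            )
    elif config.weight_source != "uniform":
        raise ValueError(f"unknown weight_source: {config.weight_source!r}")

    if config.weight_source == "uniform":
        K_full = _base_grm(d, config)
    elif weights_full is not None:
        K_full = weighted_grm(d, weights_full, config.denominator_policy)
    else:
        K_full = None  # nested gwas weights: rebuilt per fold

    rows = []
    ids = np.array(d.sample_ids)
    for rep in range(folds.shape[0]):
        for fold in range(folds[rep].max() + 1):
            test_mask = folds[rep] == fold
            tr_idx = np.flatnonzero(~test_mask)
            te_idx = np.flatnonzero(test_mask)
            y_tr = y.values[tr_idx]
            y_te = y.values[te_idx]

            if K_full is None:
                d_tr = d.take_samples(tr_idx)
                y_tr_vec = PhenotypeVector(y_tr, list(ids[tr_idx]), y.trait)
                w = _gwas_weights(
                    d_tr, y_tr_vec, config.weight_source.split(":", 1)[1],
                    config.weight_floor,
                )
                K = weighted_grm(d, w, config.denominator_policy)
            else:
                K = K_full

            res = gblup_predict(
                y_tr, K, list(ids[tr_idx]), list(ids[te_idx])
            )
            pred = res.gebv[res.sets == "test"]
            if np.ptp(y_te) == 0 or np.ptp(pred) == 0:
                warnings.warn(
                    f"constant test phenotype or prediction in repeat {rep} "
                    f"fold {fold}; accuracy undefined", stacklevel=2
                )
                r = np.nan
            else:
                r = float(np.corrcoef(pred, y_te)[0, 1])
            rows.append({"repeat": rep, "fold": fold, "r": r, "n_test": te_idx.size})

    return CVReport(
        config_name=config.name,
        records=pd.DataFrame(rows),
        leakage_mode=config.leakage_mode,
        fold_seed=fold_seed,
        folds=folds,
    )


def compare_report(reports: list[CVReport]) -> pd.DataFrame:
    """Ranked comparison of configurations sharing fold assignments.

    Returns one row per configuration with mean/sd accuracy, the paired
    mean difference against the first (baseline) report, and rank order.
    Raises if fold assignments differ (comparisons must be paired).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    base = reports[0]
    for rep in reports[1:]:
        if rep.folds.shape != base.folds.shape or not np.array_equal(
            rep.folds, base.folds
        ):
            raise ValueError(
                "fold assignments differ between reports; rerun with shared folds"
            )
    rows = []
    base_r = base.records.sort_values(["repeat", "fold"])["r"].to_numpy()
    for rep in reports:
        rs = rep.records.sort_values(["repeat", "fold"])["r"].to_numpy()
        rows.append(
            {
                "config": rep.config_name,
                "leakage_mode": rep.leakage_mode,
                "mean_r": float(np.nanmean(rs)),
                "sd_r": float(np.nanstd(rs, ddof=1)),
                "paired_diff_vs_baseline": float(np.nanmean(rs - base_r)),
            }
        )
    out = pd.DataFrame(rows)
    out["rank"] = out["mean_r"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank").reset_index(drop=True)
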