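"""Synthetic autotetraploid genotype/phenotype generator.

Dosages are drawn per marker as Binomial(ploidy, p) across individuals —
a random-bivalent-pairing Hardy-Weinberg approximation (no double
reduction).  Optional LD blocks copy a latent founder column with a
per-individual mutation rate.  Phenotypes are built from a configurable
QTL architecture whose per-QTL gene actions reuse the scan module's
dosage-effect codings, with residual noise scaled to a target
heritability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from polygs.dosage_io import DosageMatrix, PhenotypeVector, _default_marker_meta

GENE_ACTIONS = (
    "additive",
    "diplo-additive",
    "1-dom-ref",
    "1-dom-alt",
    "2-dom-ref",
    "2-dom-alt",
)

_GENE_ACTION_CODES = {
    "additive": (0.0, 0.25, 0.5, 0.75, 1.0),
    "diplo-additive": (0.0, 0.5, 0.5, 0.5, 1.0),
    "1-dom-ref": (1.0, 1.0, 1.0, 1.0, 0.0),
    "2-dom-ref": (1.0, 1.0, 1.0, 0.0, 0.0),
    "1-dom-alt": (0.0, 1.0, 1.0, 1.0, 1.0),
    "2-dom-alt": (0.0, 0.0, 1.0, 1.0, 1.0),
}


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset."""

    n: int = 300
    m: int = 2000
    ploidy: int = 4
    freq_range: tuple[float, float] = (0.1, 0.9)
    ld_block_size: int = 1  # 1 = independent markers
    ld_mutation_rate: float = 0.1
    n_qtl: int = 5
    architecture: str = "major"  # major | polygenic | mixed
    gene_action: str | list[str] = "additive"
    h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_qtl > self.m:
            raise ValueError("n_qtl cannot exceed number of markers")
        if self.architecture not in ("major", "polygenic", "mixed"):
            raise ValueError(f"unknown architecture: {self.architecture!r}")
        lo, hi = self.freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("freq_range must satisfy 0 < lo <= hi < 1")


@dataclass
class SimTruth:
    """Ground truth behind a simulated phenotype."""

    qtl_ids: list[str]
    effects: list[float]
    gene_actions: list[str]
    g_true: np.ndarray
    realized_h2: float
    target_h2: float

    def to_json(self, path: str) -> None:
        payload = {
            "qtl_ids": self.qtl_ids,
            "effects": self.effects,
            "gene_actions": self.gene_actions,
            "g_true": np.asarray(self.g_true).tolist(),
            "realized_h2": self.realized_h2,
            "target_h2": self.target_h2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["g_true"] = np.asarray(payload["g_true"])
        return cls(**payload)


def simulate_genotypes(cfg: SimConfig) -> DosageMatrix:
    """Draw an n x m tetraploid dosage panel, deterministic given seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    lo, hi = cfg.freq_range
    n, m, phi = cfg.n, cfg.m, cfg.ploidy
    if cfg.ld_block_size <= 1:
        p = rng.uniform(lo, hi, size=m)
        vals = rng.binomial(phi, p[None, :], size=(n, m)).astype(float)
    else:
        bs = cfg.ld_block_size
        n_blocks = int(np.ceil(m / bs))
        p = np.empty(m)
        vals = np.empty((n, m))
        for b in range(n_blocks):
            j0, j1 = b * bs, min((b + 1) * bs, m)
            pb = rng.uniform(lo, hi)
            founder = rng.binomial(phi, pb, size=n).astype(float)
            for j in range(j0, j1):
                col = founder.copy()
                mut = rng.random(n) < cfg.ld_mutation_rate
                col[mut] = rng.binomial(phi, pb, size=int(mut.sum()))
                vals[:, j] = col
                p[j] = pb
    meta = _default_marker_meta([f"M{j + 1:05d}" for j in range(m)])
    meta["chrom"] = (np.arange(m) // max(m // 10, 1) + 1).astype(str)
    meta["pos"] = np.arange(m) % max(m // 10, 1) * 1000 + 1
    return DosageMatrix(vals, phi, [f"S{i + 1:04d}" for i in range(n)], meta)


def _qtl_effect_sets(cfg: SimConfig, eligible: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Choose QTL marker indices and raw effect sizes per architecture."""
    if cfg.architecture == "major":
        idx = rng.choice(eligible, size=min(cfg.n_qtl, eligible.size), replace=False)
        eff = rng.normal(0.0, 1.0, size=idx.size)
        eff += np.sign(eff)  # keep every major effect away from zero
    elif cfg.architecture == "polygenic":
        k = min(max(cfg.n_qtl, eligible.size // 2), eligible.size)
        idx = rng.choice(eligible, size=k, replace=False)
        eff = rng.normal(0.0, 0.1, size=k)
    else:  # mixed
        k_major = min(cfg.n_qtl, eligible.size)
        idx_major = rng.choice(eligible, size=k_major, replace=False)
        eff_major = rng.normal(0.0, 1.0, size=k_major)
        eff_major += np.sign(eff_major)
        rest = np.setdiff1d(eligible, idx_major)
        k_minor = min(rest.size, eligible.size // 2)
        idx_minor = rng.choice(rest, size=k_minor, replace=False)
        eff_minor = rng.normal(0.0, 0.1, size=k_minor)
        idx = np.concatenate([idx_major, idx_minor])
        eff = np.concatenate([eff_major, eff_minor])
    return idx, eff


def simulate_phenotypes(
    d: DosageMatrix, cfg: SimConfig
) -> tuple[PhenotypeVector, SimTruth]:
    """Phenotypes from a QTL architecture at the configured heritability.

    ``g_true = sum_q effect_q * code_q(dosage_q)`` with per-QTL gene-action
    codes; residual noise is scaled so var(g)/var(g+e) hits the target h2
    up to sampling error, and the realized ratio is recorded.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    p = d.allele_freq
    maf = np.minimum(p, 1 - p)
    eligible = np.flatnonzero(maf >= 0.05)
    if eligible.size == 0:
        raise ValueError("no markers with MAF >= 0.05 to place QTL on")

    actions = (
        [cfg.gene_action] if isinstance(cfg.gene_action, str) else list(cfg.gene_action)
    )
    for a in actions:
        if a not in _GENE_ACTION_CODES:
            raise ValueError(f"unknown gene action {a!r}; known: {GENE_ACTIONS}")

    idx, eff = _qtl_effect_sets(cfg, eligible, rng)
    qtl_actions = [actions[q % len(actions)] for q in range(idx.size)]

    n = d.n_samples
    g = np.zeros(n)
    dos = np.rint(d.values).astype(int)
    for j, e, act in zip(idx, eff, qtl_actions):
        codes = np.asarray(_GENE_ACTION_CODES[act])
        g += e * codes[dos[:, j]]
    g -= g.mean()
    var_g = float(g.var())

    if cfg.h2 == 0:
        g = np.zeros(n)
        y = rng.normal(0.0, 1.0, size=n)
    elif cfg.h2 == 1:
        if var_g == 0:
            raise ValueError("h2=1 requested but simulated genetic variance is zero")
        y = g.copy()
    else:
        if var_g == 0:
            raise ValueError("simulated genetic variance is zero; add QTL")
        sigma_e = np.sqrt(var_g * (1 - cfg.h2) / cfg.h2)
        y = g + rng.normal(0.0, sigma_e, size=n)

    var_y = float(y.var())
    realized = float(g.var() / var_y) if var_y > 0 else 0.0
    truth = SimTruth(
        qtl_ids=[d.marker_ids[j] for j in idx],
        effects=[float(e) for e in eff],
        gene_actions=qtl_actions,
        g_true=g,
        realized_h2=realized,
        target_h2=cfg.h2,
    )
    return PhenotypeVector(y, list(d.sample_ids), "sim_trait"), truth
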