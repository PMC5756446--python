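"""Accuracy and QTL-tagging metrics for genomic prediction.

Genomic accuracy is the Pearson correlation between true breeding values
and GEBVs in the validation generation; phenotype accuracy correlates
GEBVs with phenotypes adjusted for the model's systematic effects (here
the overall mean). A QTL counts as *tagged* when its dosage vector has
squared correlation r^2 > 0.7 with at least one SNP of the selected panel,
and the share of genetic variance explained sums the Hardy–Weinberg
single-locus variances 2 p q a^2 of the tagged QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AccuracyReport",
    "genomic_accuracy",
    "phenotype_accuracy",
    "tag_qtl",
    "aggregate_reports",
]


@dataclass
class AccuracyReport:
    """One scenario-cell x replicate row of the results tables."""

    acc_g: float
    acc_p: float
    n_selected_snps: int
    n_tagged_qtl: int
    gv_explained_pct: float
    per_qtl_max_r2: np.ndarray = field(default=None, repr=False)
    meta: dict = field(default_factory=dict)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def genomic_accuracy(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between true breeding values and GEBVs."""
    return _pearson(tbv, gebv)


def phenotype_accuracy(gebv: np.ndarray, phenotypes: np.ndarray, mu_hat: float = 0.0) -> float:
    """Pearson correlation between GEBVs and mean-adjusted phenotypes."""
    y = np.asarray(phenotypes, dtype=float) - float(mu_hat)
    return _pearson(gebv, y)


def tag_qtl(
    qtl_dosages: np.ndarray,
    snp_dosages: np.ndarray,
    qtl_effects: np.ndarray | None = None,
    threshold: float = 0.7,
) -> dict:
    """Dosage-r^2 tagging of QTL by a selected SNP panel.

    r^2 is the squared Pearson correlation between dosage vectors over the
    same animals (composite LD, no phasing needed). Monomorphic QTL are
    excluded from both the count and the variance denominator; their number
    is reported. Returns a dict with ``n_tagged``, ``max_r2`` (per
    polymorphic QTL), ``gv_explained_pct`` (NaN when effects are not
    given) and ``n_monomorphic``.
    """
    Q = np.asarray(qtl_dosages, dtype=float)
    S = np.asarray(snp_dosages, dtype=float)
    if S.ndim != 2 or Q.ndim != 2 or (S.size and Q.shape[0] != S.shape[0]):
        raise ValueError("QTL and SNP dosages must share the animal axis")
    n = Q.shape[0]
    q_sd = Q.std(axis=0)
    poly = q_sd > 0
    n_mono = int((~poly).sum())
    max_r2 = np.zeros(int(poly.sum()))
    if S.shape[1] > 0 and poly.any():
        s_sd = S.std(axis=0)
        s_ok = s_sd > 0
        if s_ok.any():
            Qs = (Q[:, poly] - Q[:, poly].mean(0)) / q_sd[poly]
            Ss = (S[:, s_ok] - S[:, s_ok].mean(0)) / s_sd[s_ok]
            r = Qs.T @ Ss / n
            max_r2 = (r**2).max(axis=1)
    tagged = max_r2 > threshold
    out = {
        "n_tagged": int(tagged.sum()),
        "max_r2": max_r2,
        "n_monomorphic": n_mono,
        "gv_explained_pct": float("nan"),
    }
    if qtl_effects is not None:
        a = np.asarray(qtl_effects, dtype=float)
        p = Q.mean(axis=0) / 2.0
        v = 2.0 * p * (1.0 - p) * a**2
        vp = v[poly]
        denom = vp.sum()
        out["gv_explained_pct"] = float(100.0 * vp[tagged].sum() / denom) if denom > 0 else 0.0
    return out


def aggregate_reports(reports: list[AccuracyReport]) -> pd.DataFrame:
    """Mean and standard error over replicates, one row per metric."""
    if not reports:
        raise ValueError("no reports to aggregate")
    df = pd.DataFrame(
        {
            "acc_g": [r.acc_g for r in reports],
            "acc_p": [r.acc_p for r in reports],
            "n_selected_snps": [r.n_selected_snps for r in reports],
            "n_tagged_qtl": [r.n_tagged_qtl for r in reports],
            "gv_explained_pct": [r.gv_explained_pct for r in reports],
        }
    )
    n = len(df)
    agg = pd.DataFrame({"mean": df.mean(), "se": df.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0})
    agg["n_replicates"] = n
    return agg
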