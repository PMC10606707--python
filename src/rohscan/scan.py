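"""Per-segment carrier scan: one mixed-model refit per catalog ROH.

Variance components are fixed at their pre-scan estimates.  The base system
(parity, herd-year-season, additive, permanent environment) is factorized
once; each segment adds a single carrier fixed-effect column, solved by a
bordered (Schur-complement) update of the base Cholesky factor.  The
one-sided alternative is a *negative* carrier effect: homozygosity across
the segment depresses litter size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

from .genotypes import PhenotypeTable
from .mixed_model import ModelSpec, VarianceComponents, build_design, _assemble, one_sided_p
from .relationships import RelationshipMatrix
from .roh import ROHCatalog

__all__ = ["ScanRecord", "scan", "bh_fdr", "summarize_scan", "merge_regions"]


@dataclass
class ScanRecord:
    chromosome: str
    start_bp: int
    end_bp: int
    start_idx: int
    end_idx: int
    n_snps: int
    n_carriers: int
    trait: str
    effect: float  # piglets, carrier minus non-carrier
    se: float
    p: float
    q: float = float("nan")


def scan(
    catalog: ROHCatalog,
    phen: PhenotypeTable,
    spec: ModelSpec,
    hinv: RelationshipMatrix,
    vc: VarianceComponents,
    het: dict | None = None,
    with_fdr: bool = True,
) -> pd.DataFrame:
    """Fit the carrier contrast for every catalog segment, one trait.

    Returns a DataFrame (one row per tested segment) with effect, SE,
    one-sided p (lower tail) and BH-FDR q.  Segments whose carrier status is
    constant across phenotyped sows, or whose carrier column is confounded
    with the base design, are skipped; skips are listed in
    ``result.attrs['skipped']``.
    """
    base_spec = ModelSpec(trait=spec.trait, het_covariate=spec.het_covariate,
                          carrier=False, hys=spec.hys, df=spec.df)
    y, X, fixed_names, terms = build_design(phen, base_spec, hinv, het=het)
    variances = {"hys": vc.sigma2_h, "u": vc.sigma2_a, "p": vc.sigma2_p}
    if not base_spec.hys:
        variances.pop("hys", None)
    C, rhs, blocks, W = _assemble(y, X, terms, {t.name: variances[t.name] for t in terms},
                                  vc.sigma2_e)
    factor = cho_factor(C)
    sol0 = cho_solve(factor, rhs)
    se2 = vc.sigma2_e

    sows = phen.records["sow"].to_numpy()
    sample_index = {s: i for i, s in enumerate(catalog.samples)}
    for s in dict.fromkeys(sows):
        if s not in sample_index:
            raise ValueError(f"phenotyped sow {s!r} not among catalog samples")
    sow_rows = np.array([sample_index[s] for s in sows])

    records, skipped = [], []
    segs = catalog.segments
    # one carrier record-indicator per segment; all bordered solves batched
    # against the single base factorization
    carrier_cols = np.zeros((len(catalog.samples), len(segs)))
    for k, seg in enumerate(segs):
        for c in seg.carriers:
            carrier_cols[sample_index[c], k] = 1.0
    Xc = carrier_cols[sow_rows, :]  # records x segments
    phen_sows = np.unique(sow_rows)
    n_car = carrier_cols[phen_sows, :].sum(axis=0).astype(int)
    ok = (n_car > 0) & (n_car < len(phen_sows))
    Wx = W.T @ Xc / se2
    s_c = (Xc * Xc).sum(axis=0) / se2
    T = cho_solve(factor, Wx)
    schur = s_c - np.einsum("ij,ij->j", Wx, T)
    confounded = schur <= 1e-10 * np.maximum(s_c, 1e-300)
    beta = np.where(ok & ~confounded,
                    (Xc.T @ y / se2 - Wx.T @ sol0) / np.where(schur > 0, schur, 1.0),
                    np.nan)
    for k, seg in enumerate(segs):
        if not ok[k]:
            skipped.append((seg.chromosome, seg.start_bp, seg.end_bp,
                            "carrier status constant among phenotyped sows"))
            continue
        if confounded[k]:
            skipped.append((seg.chromosome, seg.start_bp, seg.end_bp,
                            "carrier column confounded with base design"))
            continue
        se = float(np.sqrt(1.0 / schur[k]))
        p = one_sided_p(float(beta[k]), se, "less", df=spec.df)
        records.append(
            ScanRecord(seg.chromosome, seg.start_bp, seg.end_bp, seg.start_idx,
                       seg.end_idx, seg.n_snps, int(n_car[k]), spec.trait,
                       float(beta[k]), se, p)
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    if with_fdr and len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    df.attrs["skipped"] = skipped
    df.attrs["trait"] = spec.trait
    return df


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summarize_scan(records: pd.DataFrame, alphas=(0.05, 0.01, 0.001)) -> dict:
    """Counts/proportions of significant segments, overall and per chromosome."""
    n = len(records)
    counts = {a: int((records["p"] < a).sum()) if n else 0 for a in alphas}
    per_chrom = {}
    if n:
        for chrom, sub in records.groupby("chromosome", sort=False):
            per_chrom[chrom] = {a: int((sub["p"] < a).sum()) for a in alphas}
    return {
        "n_segments": n,
        "counts": counts,
        "proportions": {a: (counts[a] / n if n else 0.0) for a in alphas},
        "per_chromosome": per_chrom,
    }


def merge_regions(records: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Merge overlapping/bookended significant segments into regions.

    Returns one row per region: chromosome, min start, max end, best
    (smallest) p among members, and the member count.
    """
    if len(records) == 0:
        return pd.DataFrame(
            columns=["chromosome", "start_bp", "end_bp", "best_p", "n_segments"]
        )
    sig = records[records["p"] < alpha].sort_values(
        ["chromosome", "start_bp", "end_bp"]
    )
    rows = []
    for chrom, sub in sig.groupby("chromosome", sort=False):
        cur = None
        for _, r in sub.iterrows():
            if cur is None or r.start_bp > cur["end_bp"]:
                if cur is not None:
                    rows.append(cur)
                cur = {"chromosome": chrom, "start_bp": int(r.start_bp),
                       "end_bp": int(r.end_bp), "best_p": float(r.p), "n_segments": 1}
            else:
                cur["end_bp"] = max(cur["end_bp"], int(r.end_bp))
                cur["best_p"] = min(cur["best_p"], float(r.p))
                cur["n_segments"] += 1
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp",
                                       "best_p", "n_segments"])
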