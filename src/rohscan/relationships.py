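"""Pedigree (A), genomic (G) and single-step (H-inverse) relationship matrices.

The additive genetic effect of the repeatability model is given the
single-step covariance structure: pedigree relationships for everyone,
corrected on the genotyped block by a VanRaden genomic relationship matrix
blended with the pedigree submatrix A22 for invertibility,

    H^-1 = A^-1 + [0 0; 0 (G_blend^-1 - A22^-1)]  on genotyped individuals.

Matrices are dense; at the scale this package targets (pedigrees of a few
hundred to a few thousand individuals) dense symmetric factorizations are
faster than sparse bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeDataset, Pedigree

__all__ = ["RelationshipMatrix", "a_matrix", "g_matrix", "h_inverse", "write_coo"]


@dataclass
class RelationshipMatrix:
    """Symmetric relationship structure over an ordered id list."""

    ids: list
    values: np.ndarray
    kind: str  # one of A, A22, G, H_inverse
    blend_alpha: float | None = None
    notes: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")

    def submatrix(self, ids):
        idx = [self.ids.index(i) if i in self.ids else None for i in ids]
        if any(k is None for k in idx):
            missing = [i for i, k in zip(ids, idx) if k is None]
            raise KeyError(f"ids not in matrix: {missing[:5]}")
        idx = np.array(idx)
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                  self.kind, self.blend_alpha, list(self.notes))


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular recurrence.

    Unknown parents are treated as unrelated, non-inbred founders.  The
    diagonal equals 1 + F (the individual's inbreeding coefficient).
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        row = np.zeros(i)
        if s is not None:
            row += 0.5 * A[s, :i]
        if d is not None:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(list(ped.ids), A, "A")


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    return np.diag(a_matrix(ped).values) - 1.0


def g_matrix(
    gd: GenotypeDataset,
    a22: RelationshipMatrix | None = None,
    blend_alpha: float = 0.95,
) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix with A22 blending.

    G = Zc Zc' / (2 sum p(1-p)) with observed-frequency centering; the
    returned matrix is blend_alpha * G + (1 - blend_alpha) * A22.
    Monomorphic markers carry no information and are dropped with a warning.
    """
    if gd.has_missing():
        raise ValueError("missing calls present; impute before g_matrix")
    if not 0 <= blend_alpha <= 1:
        raise ValueError("blend_alpha must lie in [0,1]")
    if blend_alpha < 1 and a22 is None:
        raise ValueError("blending toward A22 requires the a22 matrix")
    M = gd.calls.astype(float)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; G undefined")
    if (~poly).any():
        warnings.warn(f"g_matrix: dropped {int((~poly).sum())} monomorphic markers")
    M, p = M[:, poly], p[poly]
    Zc = M - 2 * p
    denom = 2.0 * np.sum(p * (1 - p))
    G = (Zc @ Zc.T) / denom
    if blend_alpha < 1:
        a22s = a22.submatrix(gd.samples) if a22.ids != list(gd.samples) else a22
        G = blend_alpha * G + (1 - blend_alpha) * a22s.values
    return RelationshipMatrix(list(gd.samples), G, "G", blend_alpha)


def a_inverse(ped: Pedigree) -> np.ndarray:
    """A-inverse from the parent-offspring contribution rules with inbreeding.

    Mendelian sampling variances use the parents' inbreeding coefficients
    from the tabular A.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s is not None and d is not None:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif s is not None or d is not None:
            k = s if s is not None else d
            m = 0.75 - 0.25 * F[k]
        else:
            m = 1.0
        alpha = 1.0 / m
        Ainv[i, i] += alpha
        for par in (s, d):
            if par is not None:
                Ainv[i, par] -= alpha / 2
                Ainv[par, i] -= alpha / 2
        for p1 in (s, d):
            for p2 in (s, d):
                if p1 is not None and p2 is not None:
                    Ainv[p1, p2] += alpha / 4
    return Ainv


def h_inverse(
    ped: Pedigree,
    gd: GenotypeDataset | None,
    genotyped_ids=None,
    blend_alpha: float = 0.95,
) -> RelationshipMatrix:
    """Single-step H-inverse over the pedigree id order.

    With no genotyped individuals this is exactly A-inverse.  Otherwise the
    genotyped block receives the correction G_blend^-1 - A22^-1.
    """
    Ainv = a_inverse(ped)
    if gd is not None and genotyped_ids is None:
        genotyped_ids = list(gd.samples)
    genotyped_ids = list(genotyped_ids or [])
    if gd is None or not genotyped_ids:
        return RelationshipMatrix(list(ped.ids), Ainv, "H_inverse", blend_alpha,
                                  ["no genotyped individuals: H^-1 = A^-1"])
    notes = []
    missing = [g for g in genotyped_ids if g not in ped.index]
    if missing:
        raise ValueError(f"genotyped individuals absent from pedigree: {missing[:5]}")
    A = a_matrix(ped)
    idx = np.array([ped.index[g] for g in genotyped_ids])
    A22 = A.values[np.ix_(idx, idx)]
    Gm = g_matrix(gd, RelationshipMatrix(genotyped_ids, A22, "A22"), blend_alpha)
    order = [gd.samples.index(g) for g in genotyped_ids]
    Gv = Gm.values[np.ix_(order, order)]
    try:
        Ginv = np.linalg.inv(Gv)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "blended G is singular; decrease blend_alpha to add more A22 weight"
        ) from exc
    A22inv = np.linalg.inv(A22)
    Hinv = Ainv.copy()
    Hinv[np.ix_(idx, idx)] += Ginv - A22inv
    Hinv = 0.5 * (Hinv + Hinv.T)
    notes.append(f"single-step correction on {len(idx)} genotyped individuals")
    return RelationshipMatrix(list(ped.ids), Hinv, "H_inverse", blend_alpha, notes)


def write_coo(rm: RelationshipMatrix, path, id_map_path=None, atol=1e-12):
    """Export the lower triangle as coordinate-list TSV (i, j, value)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        V = rm.values
        for i in range(len(rm.ids)):
            for j in range(i + 1):
                if abs(V[i, j]) > atol:
                    fh.write(f"{i + 1}\t{j + 1}\t{V[i, j]:.10g}\n")
    if id_map_path:
        with open(id_map_path, "w") as fh:
            fh.write("index\tid\n")
            for k, s in enumerate(rm.ids, 1):
                fh.write(f"{k}\t{s}\n")
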