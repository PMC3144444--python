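"""Pedigree (A) and genomic (G) relationship matrices.

A is built by the tabular method, its sparse inverse by Henderson's rules
with inbreeding, and G by VanRaden's first method: G = ZZ' / (2 sum p(1-p))
with Z the genotype dosages centered at twice the allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "topological_order",
    "build_A",
    "build_A_inverse",
    "inbreeding_coefficients",
    "build_G",
]


@dataclass
class RelationshipMatrix:
    ids: np.ndarray
    values: "np.ndarray | sp.spmatrix"
    kind: str  # pedigree | pedigree_inverse | genomic

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.ids, columns=self.ids)


def topological_order(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Reorder so every parent precedes its offspring; raises on cycles."""
    ids = pedigree["id"].to_numpy()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")
    known = set()
    remaining = pedigree.sort_values(["generation", "id"]).copy()
    ordered_idx: list = []
    pending = remaining.index.tolist()
    # generation+id sorting settles almost every real pedigree in one sweep
    progress = True
    while pending and progress:
        progress = False
        still = []
        for idx in pending:
            row = remaining.loc[idx]
            s, d = int(row["sire"]), int(row["dam"])
            if (s == 0 or s in known) and (d == 0 or d in known):
                known.add(int(row["id"]))
                ordered_idx.append(idx)
                progress = True
            else:
                still.append(idx)
        pending = still
    if pending:
        raise ValueError("pedigree contains a cycle or an unlisted parent")
    return remaining.loc[ordered_idx].reset_index(drop=True)


def build_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ij = 0.5 (a_{j,sire(i)} + a_{j,dam(i)}), a_ii = 1 + 0.5 a_{sire,dam};
    unknown parents contribute zero.
    """
    ped = topological_order(pedigree)
    ids = ped["id"].to_numpy()
    n = len(ids)
    pos = {int(i): k for k, i in enumerate(ids)}
    sire = np.array([pos.get(int(s), -1) for s in ped["sire"]])
    dam = np.array([pos.get(int(d), -1) for d in ped["dam"]])
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=ids, values=A, kind="pedigree")


def inbreeding_coefficients(pedigree: pd.DataFrame) -> pd.Series:
    """F_i = a_ii - 1 from the tabular method, indexed by id."""
    A = build_A(pedigree)
    return pd.Series(np.diag(A.dense()) - 1.0, index=A.ids, name="F")


def build_A_inverse(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules, using tabular inbreeding.

    For individual i with parents s, d the Mendelian-sampling variance is
    d_i = 0.5 - 0.25 (F_s + F_d) (terms dropped for unknown parents, 1 for
    two unknown parents); contributions 1/d_i at (i,i), -0.5/d_i at (i,p),
    0.25/d_i at (p,q) for known parents p, q.
    """
    ped = topological_order(pedigree)
    ids = ped["id"].to_numpy()
    n = len(ids)
    pos = {int(i): k for k, i in enumerate(ids)}
    sire = np.array([pos.get(int(s), -1) for s in ped["sire"]])
    dam = np.array([pos.get(int(d), -1) for d in ped["dam"]])
    F = inbreeding_coefficients(ped).to_numpy()
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = sire[i], dam[i]
        di = 1.0
        if s >= 0:
            di -= 0.25 * (1.0 + F[s])
        if d >= 0:
            di -= 0.25 * (1.0 + F[d])
        w = 1.0 / di
        rows.append(i), cols.append(i), vals.append(w)
        for p in (s, d):
            if p >= 0:
                rows += [i, p]
                cols += [p, i]
                vals += [-0.5 * w, -0.5 * w]
        if s >= 0 and d >= 0:
            rows += [s, d, s, d]
            cols += [s, d, d, s]
            vals += [0.25 * w, 0.25 * w, 0.25 * w, 0.25 * w]
        elif s >= 0:
            rows.append(s), cols.append(s), vals.append(0.25 * w)
        elif d >= 0:
            rows.append(d), cols.append(d), vals.append(0.25 * w)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(ids=ids, values=Ainv, kind="pedigree_inverse")


def build_G(
    genotypes: GenotypeMatrix, freqs: "np.ndarray | None" = None
) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    ``freqs`` are the centering allele frequencies; they default to the
    pooled observed frequencies of the supplied (fully imputed) matrix.
    """
    calls = genotypes.calls
    if np.isnan(calls).any():
        raise ValueError("genotypes contain missing calls; impute first")
    if freqs is None:
        freqs = calls.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise ValueError("all SNP monomorphic at the supplied frequencies")
    Z = calls - 2.0 * freqs
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(ids=genotypes.ids, values=G, kind="genomic")
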