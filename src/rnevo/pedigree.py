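"""Pedigree container and numerator-relationship-matrix machinery.

The additive genetic structure of an animal model enters through the inverse
of the numerator relationship matrix A.  ``Pedigree`` validates the
individual/dam/sire triples (acyclicity, parent-before-offspring cohorts) and
builds the sparse A-inverse by Henderson's rules, with inbreeding coefficients
from the tabular method applied to each individual's ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown parents...)."""


@dataclass
class RelationshipStructure:
    """Sparse inverse of the numerator relationship matrix A.

    Attributes
    ----------
    ids : list
        Individual ids in the (topological) order used for the matrix rows.
    a_inv : scipy.sparse.csr_matrix
        Sparse A^-1 in that ordering.
    inbreeding : np.ndarray
        Inbreeding coefficient F per individual (same order).
    chol_factor : scipy.sparse.csr_matrix
        S = D^{-1/2} (I - P) with P the half-parent incidence matrix, so that
        A^-1 = S' S.  Used to draw exact Gaussian samples with covariance
        proportional to A.
    """

    ids: list
    a_inv: sparse.csr_matrix
    inbreeding: np.ndarray
    chol_factor: sparse.csr_matrix
    index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {i: k for k, i in enumerate(self.ids)}


class Pedigree:
    """Individual/dam/sire pedigree with cohort years and sexes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``id``, ``dam``, ``sire``, ``cohort``, ``sex``; missing
        parents as ``None``/NaN.  Founders have both parents missing or one
        (single known parent is allowed).
    """

    REQUIRED = ("id", "dam", "sire")

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        t = table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise PedigreeError(f"pedigree table missing column {col!r}")
        if "cohort" not in t.columns:
            t["cohort"] = np.nan
        if "sex" not in t.columns:
            t["sex"] = "U"
        for col in ("id", "dam", "sire"):
            t[col] = t[col].astype(object)
        t["dam"] = t["dam"].where(pd.notna(t["dam"]), None)
        t["sire"] = t["sire"].where(pd.notna(t["sire"]), None)
        self.table = t.reset_index(drop=True)
        self._order = None
        if validate:
            self.validate()

    def __len__(self):
        return len(self.table)

    @property
    def ids(self):
        return list(self.table["id"])

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        t = self.table
        ids = t["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        known = set(ids)
        for col in ("dam", "sire"):
            for parent in t[col]:
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"{col} {parent!r} is not itself listed as an individual"
                    )
        self._order = self._toposort()
        # cohort ordering, when cohorts are known
        cohort = dict(zip(t["id"], t["cohort"]))
        for _, row in t.iterrows():
            for parent in (row["dam"], row["sire"]):
                if parent is None:
                    continue
                cp, co = cohort.get(parent), row["cohort"]
                if pd.notna(cp) and pd.notna(co) and not cp < co:
                    raise PedigreeError(
                        f"parent {parent!r} cohort {cp} not earlier than "
                        f"offspring {row['id']!r} cohort {co}"
                    )

    def _toposort(self) -> list:
        """Kahn topological order (parents before offspring); detects cycles."""
        t = self.table
        children: dict = {}
        indeg = {}
        for _, row in t.iterrows():
            i = row["id"]
            parents = [p for p in (row["dam"], row["sire"]) if p is not None]
            if i in parents:
                raise PedigreeError(f"individual {i!r} listed as its own parent")
            indeg[i] = len(parents)
            for p in parents:
                children.setdefault(p, []).append(i)
        queue = [i for i, d in indeg.items() if d == 0]
        order = []
        while queue:
            nxt = []
            for i in queue:
                order.append(i)
                for c in children.get(i, ()):
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        nxt.append(c)
            queue = nxt
        if len(order) != len(t):
            cyc = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree contains a cycle involving {cyc[:5]}")
        return order

    def topological_order(self) -> list:
        if self._order is None:
            self._order = self._toposort()
        return self._order

    # ------------------------------------------------------------------ #
    def relationship_matrix(self) -> tuple[np.ndarray, list]:
        """Dense numerator relationship matrix A by the tabular method.

        Suitable for small pedigrees (used for oracle checks and for
        inbreeding on ancestor subsets); O(n^2) memory.
        """
        order = self.topological_order()
        idx = {i: k for k, i in enumerate(order)}
        parents = {
            row["id"]: (row["dam"], row["sire"]) for _, row in self.table.iterrows()
        }
        n = len(order)
        A = np.zeros((n, n))
        for k, i in enumerate(order):
            d, s = parents[i]
            di = idx[d] if d is not None else None
            si = idx[s] if s is not None else None
            if di is not None and si is not None:
                A[k, k] = 1.0 + 0.5 * A[di, si]
            else:
                A[k, k] = 1.0
            if k:  # vectorized tabular recursion over earlier individuals
                row = np.zeros(k)
                if di is not None:
                    row += 0.5 * A[:k, di]
                if si is not None:
                    row += 0.5 * A[:k, si]
                A[k, :k] = row
                A[:k, k] = row
        return A, order

    def inbreeding(self) -> pd.Series:
        """Inbreeding coefficient F_i = A_ii - 1 via the tabular method."""
        A, order = self.relationship_matrix()
        return pd.Series(np.diag(A) - 1.0, index=order)

    def relationship_inverse(self, method: str = "inbred") -> RelationshipStructure:
        """Henderson's sparse A^-1.

        method='inbred' computes inbreeding coefficients first (tabular
        method) and uses Mendelian-sampling variances that account for
        parental inbreeding; method='noninbred' assumes F=0 throughout.
        """
        order = self.topological_order()
        idx = {i: k for k, i in enumerate(order)}
        parents = {
            row["id"]: (row["dam"], row["sire"]) for _, row in self.table.iterrows()
        }
        n = len(order)
        if method == "inbred":
            F = self.inbreeding().reindex(order).to_numpy()
        elif method == "noninbred":
            F = np.zeros(n)
        else:
            raise ValueError("method must be 'inbred' or 'noninbred'")

        rows, cols, vals = [], [], []  # for S = D^{-1/2} (I - P)
        d_inv = np.empty(n)
        for k, i in enumerate(order):
            dam, sire = parents[i]
            di = idx[dam] if dam is not None else None
            si = idx[sire] if sire is not None else None
            # Mendelian sampling variance
            v = 1.0
            if di is not None:
                v -= 0.25 * (1.0 + F[di])
            if si is not None:
                v -= 0.25 * (1.0 + F[si])
            d_inv[k] = 1.0 / v
            root = np.sqrt(d_inv[k])
            rows.append(k)
            cols.append(k)
            vals.append(root)
            for pi in (di, si):
                if pi is not None:
                    rows.append(k)
                    cols.append(pi)
                    vals.append(-0.5 * root)
        S = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        a_inv = (S.T @ S).tocsr()
        return RelationshipStructure(
            ids=order, a_inv=a_inv, inbreeding=F, chol_factor=S,
        )


def build_relationship_inverse(pedigree: Pedigree, method: str = "inbred"):
    """Functional alias for :meth:`Pedigree.relationship_inverse`."""
    return pedigree.relationship_inverse(method=method)


def permute_pedigree_links(pedigree: Pedigree, rng) -> Pedigree:
    """Negative control: shuffle (dam, sire) pairs among same-cohort offspring.

    Permuting parentage within cohorts preserves the pedigree's structural
    validity (parents still precede offspring) while destroying the
    resemblance between relatives, so a genuine additive-genetic signal must
    collapse when the model is fitted with the permuted pedigree.
    """
    t = pedigree.table.copy()
    has_parents = t["dam"].notna() | t["sire"].notna()
    for _, idx in t[has_parents].groupby("cohort").groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        perm = rng.permutation(len(idx))
        t.loc[idx, ["dam", "sire"]] = (
            t.loc[idx[perm], ["dam", "sire"]].to_numpy()
        )
    return Pedigree(t)
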