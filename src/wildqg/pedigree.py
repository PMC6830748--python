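"""Pedigree handling and pedigree-derived quantities.

The pedigree is the backbone of every quantitative-genetic computation in
this package: it defines the additive (numerator) relationship matrix ``A``
used by the animal models, individual inbreeding coefficients, genetic-group
(immigrant-ancestry) proportions, and it is the substrate for gene-dropping
simulations that generate null distributions of breeding-value change under
genetic drift.

Conventions
-----------
* Unknown parents are treated as unique, unrelated, non-inbred founders.
* ``A`` is built with the tabular (Henderson) recursion in topological
  order and stored dense; study-scale pedigrees (a few thousand members)
  are well within desk memory.
* The sparse inverse ``A^-1`` is built directly from pedigree structure
  (Henderson's rules with the inbreeding correction of Quaas) and is what
  the MCMC sampler actually consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeError",
    "validate_pedigree",
    "additive_relationship_matrix",
    "inbreeding_coefficients",
    "genetic_group_proportions",
    "gene_drop_breeding_values",
    "read_pedigree_csv",
    "write_pedigree_csv",
]

FEMALE = "F"
MALE = "M"
UNKNOWN = ""


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad parent links)."""


@dataclass
class Pedigree:
    """A validated pedigree in topological order (parents precede offspring).

    Attributes
    ----------
    table:
        DataFrame with columns ``id, sire, dam, sex, cohort``; missing
        parents are empty strings. Row order is topological.
    sire_idx, dam_idx:
        Integer row index of each individual's sire/dam, ``-1`` if unknown.
    """

    table: pd.DataFrame
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    _pos: dict = field(repr=False, default_factory=dict)
    _F: np.ndarray | None = field(repr=False, default=None)
    _ainv: sparse.csr_matrix | None = field(repr=False, default=None)
    _levels: list | None = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def cohort(self) -> np.ndarray:
        return self.table["cohort"].to_numpy()

    @property
    def sex(self) -> np.ndarray:
        return self.table["sex"].to_numpy()

    def position(self, individual_id) -> int:
        """Row index of ``individual_id``; raises ``KeyError`` if absent."""
        return self._pos[individual_id]

    def positions(self, ids) -> np.ndarray:
        return np.array([self._pos[i] for i in ids], dtype=int)

    # -- derived quantities ------------------------------------------------

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficient F (cached)."""
        if self._F is None:
            self._F = _inbreeding_from_structure(self.sire_idx, self.dam_idx)
        return self._F

    def relationship_matrix(self) -> np.ndarray:
        return _tabular_a(self.sire_idx, self.dam_idx)

    def a_inverse(self) -> sparse.csr_matrix:
        """Sparse inverse of the numerator relationship matrix (cached)."""
        if self._ainv is None:
            self._ainv = _a_inverse(self.sire_idx, self.dam_idx, self.inbreeding)
        return self._ainv

    def generation_levels(self) -> list:
        """Partition of row indices such that every parent sits in an
        earlier level; used to vectorise gene-dropping (cached)."""
        if self._levels is None:
            n = len(self)
            lev = np.zeros(n, dtype=int)
            for i in range(n):
                s, d = self.sire_idx[i], self.dam_idx[i]
                ls = lev[s] + 1 if s >= 0 else 0
                ld = lev[d] + 1 if d >= 0 else 0
                lev[i] = max(ls, ld)
            self._levels = [np.flatnonzero(lev == g) for g in range(lev.max() + 1)]
        return self._levels

    def ancestor_closure(self, ids) -> "Pedigree":
        """Sub-pedigree of ``ids`` and all their ancestors.

        The subset is closed under parenthood, so every genetic
        relationship among the retained individuals is preserved exactly;
        pruning individuals outside the closure leaves the animal-model
        likelihood of data on ``ids`` unchanged.
        """
        keep = set()
        stack = [self._pos[i] for i in ids]
        while stack:
            i = stack.pop()
            if i in keep:
                continue
            keep.add(i)
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0:
                    stack.append(int(p))
        rows = np.array(sorted(keep), dtype=int)  # original order stays topological
        sub = self.table.iloc[rows].reset_index(drop=True)
        pos = {v: k for k, v in enumerate(sub["id"])}
        sire_idx = np.array([pos.get(p, -1) if p != UNKNOWN else -1 for p in sub["sire"]], dtype=int)
        dam_idx = np.array([pos.get(p, -1) if p != UNKNOWN else -1 for p in sub["dam"]], dtype=int)
        F = self.inbreeding[rows].copy() if self._F is not None else None
        return Pedigree(table=sub, sire_idx=sire_idx, dam_idx=dam_idx, _pos=pos, _F=F)

    def mendelian_variance_weights(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variance, as a fraction of sigma_A."""
        return _mendelian_weights(self.sire_idx, self.dam_idx, self.inbreeding)

    def founder_mask(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)


def validate_pedigree(records: pd.DataFrame) -> Pedigree:
    """Validate raw pedigree records and return a topologically sorted Pedigree.

    Parameters
    ----------
    records:
        DataFrame with columns ``id, sire, dam`` and optionally ``sex`` and
        ``cohort``. Missing parents may be given as empty strings, ``None``
        or NaN.

    Raises
    ------
    PedigreeError
        On duplicate ids, unknown parent ids, cycles (an individual being
        its own ancestor), or sex-inconsistent parent use.
    """
    df = records.copy()
    for col in ("sire", "dam"):
        df[col] = df[col].map(_norm_parent)
    if "sex" not in df.columns:
        df["sex"] = UNKNOWN
    df["sex"] = df["sex"].fillna(UNKNOWN).astype(str).str.upper().str[:1].replace("N", UNKNOWN)
    if "cohort" not in df.columns:
        df["cohort"] = -1
    df["cohort"] = df["cohort"].fillna(-1).astype(int)

    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise PedigreeError(f"duplicate individual ids: {dupes[:5]}")
    pos = {v: k for k, v in enumerate(ids)}

    for col in ("sire", "dam"):
        missing = [p for p in df[col] if p != UNKNOWN and p not in pos]
        if missing:
            raise PedigreeError(f"{col} ids not in individual list: {missing[:5]}")

    sires = {p for p in df["sire"] if p != UNKNOWN}
    dams = {p for p in df["dam"] if p != UNKNOWN}
    both = sires & dams
    if both:
        raise PedigreeError(f"ids used as both sire and dam: {sorted(both)[:5]}")
    sex_of = dict(zip(df["id"], df["sex"]))
    bad_sires = sorted(p for p in sires if sex_of[p] == FEMALE)
    bad_dams = sorted(p for p in dams if sex_of[p] == MALE)
    if bad_sires or bad_dams:
        raise PedigreeError(
            f"sex-inconsistent parents: female sires {bad_sires[:5]}, male dams {bad_dams[:5]}"
        )

    order = _topological_order(df, pos)
    df = df.iloc[order].reset_index(drop=True)
    pos = {v: k for k, v in enumerate(df["id"])}
    sire_idx = np.array([pos.get(p, -1) if p != UNKNOWN else -1 for p in df["sire"]], dtype=int)
    dam_idx = np.array([pos.get(p, -1) if p != UNKNOWN else -1 for p in df["dam"]], dtype=int)
    return Pedigree(table=df, sire_idx=sire_idx, dam_idx=dam_idx, _pos=pos)


def _norm_parent(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return UNKNOWN
    s = str(v).strip()
    return UNKNOWN if s.lower() in ("", "na", "nan", "none", "0") else s


def _topological_order(df: pd.DataFrame, pos: dict) -> list[int]:
    """Kahn's algorithm over parent->offspring edges; deterministic tie-break
    by (cohort, original row). Raises on cycles with the offending ids."""
    n = len(df)
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p != UNKNOWN:
                children[pos[p]].append(i)
                indeg[i] += 1
    cohort = df["cohort"].to_numpy()
    import heapq

    heap = [(cohort[i], i) for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        _, i = heapq.heappop(heap)
        order.append(i)
        for j in children[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                heapq.heappush(heap, (cohort[j], j))
    if len(order) != n:
        stuck = sorted(df["id"].iloc[i] for i in range(n) if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {stuck[:10]}")
    return order


# -- relationship matrix & inbreeding -------------------------------------


def _tabular_a(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    n = len(sire_idx)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (A[s, :i] + A[d, :i])
            aii = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            row = 0.5 * A[p, :i]
            aii = 1.0
        else:
            row = np.zeros(i)
            aii = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = aii
    return A


def _inbreeding_from_structure(sire_idx, dam_idx) -> np.ndarray:
    # F_i = A(sire, dam)/2; obtained from the tabular A. Dense is fine at
    # study scale; guard against accidental huge input.
    n = len(sire_idx)
    if n > 20000:
        raise PedigreeError("pedigree too large for dense relationship computation")
    A = _tabular_a(sire_idx, dam_idx)
    return np.diag(A) - 1.0


def _mendelian_weights(sire_idx, dam_idx, F) -> np.ndarray:
    """Variance of the deviation from the known-parent average, /sigma_A.

    Both parents known: (1/2)(1 - (F_s+F_d)/2). One known parent: the unknown
    parent contributes as an unrelated non-inbred founder, giving
    3/4 - F_p/4. Founder: 1.
    """
    n = len(sire_idx)
    d = np.ones(n)
    both = (sire_idx >= 0) & (dam_idx >= 0)
    one = (sire_idx >= 0) ^ (dam_idx >= 0)
    d[both] = 0.5 - 0.25 * (F[sire_idx[both]] + F[dam_idx[both]])
    p = np.where(sire_idx >= 0, sire_idx, dam_idx)
    d[one] = 0.75 - 0.25 * F[p[one]]
    return d


def _a_inverse(sire_idx, dam_idx, F) -> sparse.csr_matrix:
    n = len(sire_idx)
    d = _mendelian_weights(sire_idx, dam_idx, F)
    alpha = 1.0 / d
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, dd = sire_idx[i], dam_idx[i]
        a = alpha[i]
        add(i, i, a)
        for p in (s, dd):
            if p >= 0:
                add(i, p, -a / 2)
                add(p, i, -a / 2)
                add(p, p, a / 4)
        if s >= 0 and dd >= 0:
            add(s, dd, a / 4)
            add(dd, s, a / 4)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def additive_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A (tabular method)."""
    return ped.relationship_matrix()


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-individual pedigree inbreeding coefficient F."""
    return ped.inbreeding.copy()


def genetic_group_proportions(
    ped: Pedigree,
    founder_groups: dict | None = None,
    default: float | None = 0.0,
) -> np.ndarray:
    """Expected proportion of 'immigrant' genome per individual.

    Founders carry a group label (0 = resident, 1 = immigrant) given in
    ``founder_groups`` (id -> value in [0, 1]); descendants take the mean of
    their parents' values. An unknown parent contributes ``default``
    (resident, 0, unless configured otherwise).

    Raises
    ------
    PedigreeError
        If a founder is unassigned and ``default`` is None.
    """
    founder_groups = founder_groups or {}
    n = len(ped)
    q = np.zeros(n)
    ids = ped.ids
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s < 0 and d < 0:
            if ids[i] in founder_groups:
                q[i] = float(founder_groups[ids[i]])
            elif default is None:
                raise PedigreeError(f"founder {ids[i]!r} has no genetic-group assignment")
            else:
                q[i] = default
            if not 0.0 <= q[i] <= 1.0:
                raise PedigreeError(f"group value for {ids[i]!r} outside [0, 1]")
        else:
            qs = q[s] if s >= 0 else _founder_default(ids[i], default)
            qd = q[d] if d >= 0 else _founder_default(ids[i], default)
            q[i] = 0.5 * (qs + qd)
    return q


def _founder_default(child_id, default):
    if default is None:
        raise PedigreeError(f"unknown parent of {child_id!r} needs a default group")
    return default


def gene_drop_breeding_values(
    ped: Pedigree,
    sigma_a: float | np.ndarray,
    seed=None,
    n_reps: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate breeding values down the pedigree (gene dropping).

    Founders are drawn from ``N(0, sigma_a)``; each non-founder is the mean
    of its (known) parents' values plus a Mendelian-sampling deviation whose
    variance is reduced by parental inbreeding. ``sigma_a`` may be a scalar
    variance or a k x k additive covariance matrix for joint multi-trait
    dropping.

    Returns
    -------
    ndarray
        Shape ``(n,)`` (scalar, one rep), ``(n_reps, n)`` (scalar), or with
        a trailing trait axis for matrix ``sigma_a``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sig = np.asarray(sigma_a, dtype=float)
    multi = sig.ndim == 2
    if multi:
        if not np.allclose(sig, sig.T):
            raise ValueError("sigma_a matrix must be symmetric")
        eigs = np.linalg.eigvalsh(sig)
        if eigs.min() < -1e-10 * max(1.0, eigs.max()):
            raise ValueError("sigma_a matrix must be positive semi-definite")
        k = sig.shape[0]
        L = _psd_cholesky(sig)
    else:
        if sig < 0:
            raise ValueError("sigma_a must be non-negative")
        k = 1
        L = np.sqrt(float(sig))

    n = len(ped)
    d = ped.mendelian_variance_weights()
    founders = ped.founder_mask()
    shape = (n_reps, n, k) if multi else (n_reps, n)
    # deviations: founders get full variance, non-founders the Mendelian share
    scale = np.where(founders, 1.0, d)
    z = rng.standard_normal(shape)
    if multi:
        dev = np.einsum("rnk,jk->rnj", z, L) * np.sqrt(scale)[None, :, None]
    else:
        dev = z * (L * np.sqrt(scale))[None, :]
    bv = np.zeros(shape)
    s_idx, d_idx = ped.sire_idx, ped.dam_idx
    for idx in ped.generation_levels():
        s, dd = s_idx[idx], d_idx[idx]
        mid = dev[:, idx].copy()
        has_s, has_d = s >= 0, dd >= 0
        if has_s.any():
            mid[:, has_s] += 0.5 * bv[:, s[has_s]]
        if has_d.any():
            mid[:, has_d] += 0.5 * bv[:, dd[has_d]]
        bv[:, idx] = mid
    if n_reps == 1:
        return bv[0]
    return bv


def _psd_cholesky(sig: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of semi-definite matrices."""
    try:
        return np.linalg.cholesky(sig)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sig)
        w = np.clip(w, 0.0, None)
        return v @ np.diag(np.sqrt(w))


# -- I/O -------------------------------------------------------------------


def read_pedigree_csv(path) -> Pedigree:
    """Read and validate a pedigree CSV (columns id, sire, dam, sex, cohort)."""
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str}, keep_default_na=False)
    return validate_pedigree(df)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, index=False)


def write_relationship_csv(ped: Pedigree, path, max_size: int = 2000) -> None:
    """Write the dense A matrix as a square CSV (guarded against huge pedigrees)."""
    if len(ped) > max_size:
        raise PedigreeError(
            f"refusing to write a {len(ped)}x{len(ped)} dense matrix; "
            f"raise max_size explicitly if you really want it"
        )
    A = ped.relationship_matrix()
    pd.DataFrame(A, index=ped.ids, columns=ped.ids).to_csv(path)


def write_inbreeding_csv(ped: Pedigree, path) -> None:
    pd.DataFrame({"id": ped.ids, "inbreeding": ped.inbreeding}).to_csv(path, index=False)


def write_genetic_groups_csv(ped: Pedigree, path, founder_groups=None, default=0.0) -> None:
    q = genetic_group_proportions(ped, founder_groups, default)
    pd.DataFrame({"id": ped.ids, "genetic_group": q}).to_csv(path, index=False)
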