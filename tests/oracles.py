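"""Independent oracles used by the test suite.

Deliberately naive implementations (recursive coancestry in exact rational
arithmetic, random pedigree generation) kept separate from the package so
the code paths under test share nothing with them.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd


def recursive_kinship(parents: dict):
    """Exact kinship (coancestry) oracle.

    ``parents`` maps id -> (sire-or-None, dam-or-None). Returns a function
    ``f(i, j)`` giving the kinship coefficient as a Fraction. Requires a
    rank (topological depth) to recurse on the younger argument, computed
    internally.
    """
    rank: dict = {}

    def depth(i):
        if i is None:
            return -1
        if i not in rank:
            s, d = parents[i]
            rank[i] = 1 + max(depth(s), depth(d))
        return rank[i]

    for i in parents:
        depth(i)
    memo: dict = {}

    def f(i, j):
        if i is None or j is None:
            return Fraction(0)
        key = (i, j) if str(i) <= str(j) else (j, i)
        if key in memo:
            return memo[key]
        if i == j:
            s, d = parents[i]
            val = Fraction(1, 2) + Fraction(1, 2) * f(s, d)
        else:
            # recurse on the individual with the greater depth (the one
            # that cannot be an ancestor of the other)
            if depth(i) < depth(j):
                i, j = j, i
            s, d = parents[i]
            val = Fraction(1, 2) * (f(s, j) + f(d, j))
        memo[key] = val
        return val

    return f


def oracle_relationship_matrix(parents: dict, order) -> np.ndarray:
    """Numerator relationship matrix A = 2 * kinship, exact then floated."""
    f = recursive_kinship(parents)
    n = len(order)
    A = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            A[a, b] = A[b, a] = float(2 * f(order[a], order[b]))
    return A


def oracle_inbreeding(parents: dict, order) -> np.ndarray:
    f = recursive_kinship(parents)
    return np.array([float(f(*parents[i])) for i in order])


def random_pedigree(rng: np.random.Generator, n: int = 30,
                    p_known: float = 0.7) -> pd.DataFrame:
    """Random valid pedigree: each individual may draw parents among
    earlier individuals of the right sex."""
    ids, sires, dams, sexes = [], [], [], []
    males, females = [], []
    for i in range(n):
        iid = f"X{i:03d}"
        sex = "M" if rng.random() < 0.5 else "F"
        sire = dam = ""
        if males and rng.random() < p_known:
            sire = males[int(rng.integers(len(males)))]
        if females and rng.random() < p_known:
            dam = females[int(rng.integers(len(females)))]
        ids.append(iid)
        sires.append(sire)
        dams.append(dam)
        sexes.append(sex)
        (males if sex == "M" else females).append(iid)
    return pd.DataFrame({"id": ids, "sire": sires, "dam": dams,
                         "sex": sexes, "cohort": np.arange(n) // 5})


def parents_dict(df: pd.DataFrame) -> dict:
    return {
        r.id: (r.sire if r.sire != "" else None, r.dam if r.dam != "" else None)
        for r in df.itertuples()
    }
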