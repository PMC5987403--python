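import numpy as np
import pandas as pd
import pytest

from pedeval.pedigree import Pedigree, make_pedigree


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int | None = None) -> Pedigree:
    """Random valid pedigree: founders first, later animals pick older parents."""
    if n_founders is None:
        n_founders = max(2, int(rng.integers(2, max(3, n // 2))))
    ids = list(range(1, n + 1))
    sires, dams = [], []
    for i in range(n):
        if i < n_founders:
            sires.append(0)
            dams.append(0)
        else:
            s, d = rng.choice(ids[:i], size=2, replace=True)
            sires.append(int(s))
            dams.append(int(d))
    frame = pd.DataFrame({"id": ids, "sire": sires, "dam": dams})
    # shuffle rows so sorting is exercised
    frame = frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return make_pedigree(frame)


def kinship_oracle(ped: Pedigree) -> np.ndarray:
    """Additive relationships by memoized coancestry recursion (independent of
    the tabular method): f(i,i) = (1 + f(s,d))/2, f(i,j) = (f(s,j)+f(d,j))/2
    for i younger than j, a_ij = 2 f(i,j)."""
    n = len(ped)
    sire = {int(i): int(s) for i, s in zip(ped.id, ped.sire)}
    dam = {int(i): int(d) for i, d in zip(ped.id, ped.dam)}
    memo = {}

    def f(i, j):
        if i == 0 or j == 0:
            return 0.0
        key = (i, j) if i <= j else (j, i)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + f(sire[i], dam[i]))
        else:
            a, b = (i, j) if i > j else (j, i)  # a is younger (larger code)
            val = 0.5 * (f(sire[a], b) + f(dam[a], b))
        memo[key] = val
        return val

    A = np.empty((n, n))
    for i in range(1, n + 1):
        for j in range(1, i + 1):
            A[i - 1, j - 1] = A[j - 1, i - 1] = 2.0 * f(i, j) if i != j else 1.0 + f(sire[i], dam[i])
    return A


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
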