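"""Pedigree handling: validation, recoding, additive relationships, inbreeding.

A pedigree is a directed acyclic graph in which every individual has at most
one recorded sire and one recorded dam (code 0 = unknown).  From a sorted
pedigree the numerator relationship matrix (A-matrix) is built with the
tabular method; its diagonal carries ``1 + F`` where ``F`` is the inbreeding
coefficient, and half the off-diagonal entry between two candidate parents is
the inbreeding coefficient of their prospective progeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "relationship_matrix",
    "inbreeding",
    "prospective_inbreeding",
]


class PedigreeError(ValueError):
    """Raised for structural problems: duplicates, missing parents, cycles."""


@dataclass
class Pedigree:
    """Recoded, topologically sorted pedigree.

    Internal ids are consecutive integers ``1..n`` in an order that places
    parents before offspring.  ``sire`` and ``dam`` use 0 for unknown.

    Attributes
    ----------
    id, sire, dam : np.ndarray of int
        Internal codes, parents-first order.
    original_id : np.ndarray of object
        The identifiers as they appeared on input, aligned with ``id``.
    generation : np.ndarray of object
        Optional spawning-year / generation label per individual.
    """

    id: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    original_id: np.ndarray
    generation: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {orig: int(i) for orig, i in zip(self.original_id, self.id)}

    def __len__(self) -> int:
        return len(self.id)

    def code_of(self, original_id) -> int:
        """Internal code for an original identifier."""
        try:
            return self._index[original_id]
        except KeyError:
            raise PedigreeError(f"unknown individual {original_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "id": self.id,
            "sire": self.sire,
            "dam": self.dam,
            "original_id": self.original_id,
        }
        if self.generation is not None:
            d["generation"] = self.generation
        return pd.DataFrame(d)


def _toposort(ids, sires, dams):
    """Stable Kahn's algorithm over parent->offspring edges; raises on cycles.

    Ties are broken by input position, so a file already in parents-first
    order keeps its order (write/read round-trips are identities).
    """
    import heapq

    n = len(ids)
    pos = {v: i for i, v in enumerate(ids)}
    children = [[] for _ in range(n)]
    n_parents = np.zeros(n, dtype=int)
    for i, (s, d) in enumerate(zip(sires, dams)):
        for p in (s, d):
            if p != 0:
                children[pos[p]].append(i)
                n_parents[i] += 1
    order = []
    ready = [i for i in range(n) if n_parents[i] == 0]
    heapq.heapify(ready)
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != n:
        stuck = [ids[i] for i in range(n) if n_parents[i] > 0]
        raise PedigreeError(f"cycle detected in pedigree involving ids {stuck[:10]}")
    return order


def make_pedigree(frame: pd.DataFrame) -> Pedigree:
    """Validate and recode a raw id/sire/dam table into a :class:`Pedigree`.

    Expects columns ``id``, ``sire``, ``dam`` and optionally ``year`` (or
    ``generation``).  Unknown parents must be coded 0 (the strings "0" and ""
    are accepted).
    """
    cols = {c.lower(): c for c in frame.columns}
    for req in ("id", "sire", "dam"):
        if req not in cols:
            raise PedigreeError(f"pedigree file missing column {req!r}")

    def norm(v):
        if pd.isna(v) or v == "" or v == 0 or v == "0":
            return 0
        if isinstance(v, float) and v.is_integer():
            return int(v)
        return v

    ids = [norm(v) for v in frame[cols["id"]]]
    sires = [norm(v) for v in frame[cols["sire"]]]
    dams = [norm(v) for v in frame[cols["dam"]]]

    if 0 in ids:
        raise PedigreeError("0 is reserved for unknown parents and cannot be an id")
    seen = set()
    dups = [v for v in ids if v in seen or seen.add(v)]
    if dups:
        raise PedigreeError(f"duplicate individual ids: {sorted(set(dups), key=str)[:10]}")
    known = set(ids)
    missing = sorted(
        {p for p in sires + dams if p != 0 and p not in known}, key=str
    )
    if missing:
        raise PedigreeError(f"parents not present in pedigree and not 0: {missing[:10]}")

    order = _toposort(ids, sires, dams)
    code = {}
    for new, i in enumerate(order, start=1):
        code[ids[i]] = new
    code[0] = 0

    gen_col = cols.get("year") or cols.get("generation")
    gen_raw = list(frame[gen_col]) if gen_col else None

    n = len(ids)
    out_id = np.arange(1, n + 1)
    out_sire = np.array([code[sires[i]] for i in order], dtype=int)
    out_dam = np.array([code[dams[i]] for i in order], dtype=int)
    out_orig = np.array([ids[i] for i in order], dtype=object)
    out_gen = np.array([gen_raw[i] for i in order], dtype=object) if gen_raw else None
    return Pedigree(out_id, out_sire, out_dam, out_orig, out_gen)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a delimited pedigree file (comma or tab, header ``id,sire,dam[,year]``)."""
    frame = pd.read_csv(path, sep=None, engine="python", dtype=object)
    return make_pedigree(frame)


def write_pedigree(ped: Pedigree, path: str | Path, sep: str = ",") -> None:
    """Write the recoded pedigree, keeping the original ids in a column."""
    ped.to_frame().to_csv(path, sep=sep, index=False)


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Row/column ``i`` (0-based) corresponds to internal id ``i+1``.  For a
    sorted pedigree the recursion is

    ``a[i, j] = (a[j, sire(i)] + a[j, dam(i)]) / 2``   for j < i,
    ``a[i, i] = 1 + a[sire(i), dam(i)] / 2``,

    with unknown parents contributing zero.
    """
    n = len(ped)
    sire = ped.sire
    dam = ped.dam
    # sortedness guard: every parent code must be smaller than the offspring code
    if np.any(sire >= ped.id) or np.any(dam >= ped.id):
        raise PedigreeError("pedigree is not sorted parents-first")
    A = np.zeros((n + 1, n + 1))  # row/col 0 is the unknown-parent phantom (all zeros)
    for i in range(1, n + 1):
        s, d = sire[i - 1], dam[i - 1]
        if i > 1:
            row = 0.5 * (A[s, 1:i] + A[d, 1:i])
            A[i, 1:i] = row
            A[1:i, i] = row
        A[i, i] = 1.0 + 0.5 * A[s, d]
    return A[1:, 1:]


def inbreeding(ped: Pedigree, A: np.ndarray | None = None) -> np.ndarray:
    """Inbreeding coefficient per individual: ``F_i = a(sire_i, dam_i)/2``.

    Zero whenever either parent is unknown.
    """
    if A is None:
        A = relationship_matrix(ped)
    F = np.zeros(len(ped))
    both = (ped.sire > 0) & (ped.dam > 0)
    F[both] = 0.5 * A[ped.sire[both] - 1, ped.dam[both] - 1]
    return F


def prospective_inbreeding(
    ped: Pedigree, sire_id, dam_id, A: np.ndarray | None = None, *, coded: bool = False
) -> float:
    """Inbreeding coefficient of a hypothetical progeny of two candidates.

    Equal to half the additive relationship between the candidates; the
    pedigree is not modified.  Pass ``coded=True`` if the ids are already
    internal codes.
    """
    s = sire_id if coded else ped.code_of(sire_id)
    d = dam_id if coded else ped.code_of(dam_id)
    if not (1 <= s <= len(ped)) or not (1 <= d <= len(ped)):
        raise PedigreeError(f"candidate ids out of range: {sire_id!r}, {dam_id!r}")
    if A is None:
        A = relationship_matrix(ped)
    return float(0.5 * A[s - 1, d - 1])
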