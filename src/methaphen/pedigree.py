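"""Pedigree container, validation, inbreeding, and relationship matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "inbreeding_coefficients", "relationship_matrix"]


@dataclass(frozen=True)
class Pedigree:
    """Animal/sire/dam triples with ancestors listed before descendants.

    ``0`` denotes an unknown parent.  Ids are arbitrary positive integers;
    internally animals are addressed by their position in ``records``.
    """

    records: tuple

    def __post_init__(self) -> None:
        seen: dict[int, int] = {}
        for pos, (animal, sire, dam) in enumerate(self.records):
            if animal <= 0:
                raise ValueError(f"animal id must be positive, got {animal}")
            if animal in seen:
                raise ValueError(f"duplicate animal id {animal}")
            for parent in (sire, dam):
                if parent != 0 and parent not in seen:
                    raise ValueError(
                        f"parent {parent} of animal {animal} not listed earlier "
                        "(unknown id or pedigree cycle)")
            seen[animal] = pos
        object.__setattr__(self, "_index", seen)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=np.int64)

    def index_of(self, animal_id: int) -> int:
        return self._index[animal_id]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based sire/dam positions, -1 for unknown."""
        sires = np.empty(len(self.records), dtype=np.int64)
        dams = np.empty(len(self.records), dtype=np.int64)
        for i, (_, s, d) in enumerate(self.records):
            sires[i] = self._index[s] if s != 0 else -1
            dams[i] = self._index[d] if d != 0 else -1
        return sires, dams

    def ancestor_generations(self, animal_id: int) -> int:
        """Number of complete known ancestor generations above an animal."""
        sires, dams = self.parent_indices()

        def depth(i: int) -> int:
            s, d = sires[i], dams[i]
            if s < 0 or d < 0:
                return 0
            return 1 + min(depth(s), depth(d))

        return depth(self.index_of(animal_id))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(tuple((int(a), int(s), int(d))
                         for a, s, d in df.iloc[:, :3].itertuples(index=False)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.records), columns=["animal", "sire", "dam"])

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, header=None,
                                          names=["animal", "sire", "dam"]))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, header=False, index=False)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (Meuwissen–Luo recursion).

    Computes the diagonal of the numerator relationship matrix as
    ``A_ii = 1 + F_i`` by tracing, for each animal, the contributions of its
    ancestors through the L factor of A = L D L'.
    """
    n = len(ped)
    sires, dams = ped.parent_indices()
    f = np.zeros(n)
    # Mendelian-sampling variances D given parental inbreeding.
    d = np.empty(n)
    point = np.full(n, -1, dtype=np.int64)
    l_row = np.zeros(n)
    for i in range(n):
        s, dd = sires[i], dams[i]
        if s < 0 and dd < 0:
            d[i] = 1.0
        elif s < 0:
            d[i] = 0.75 - 0.25 * f[dd]
        elif dd < 0:
            d[i] = 0.75 - 0.25 * f[s]
        else:
            d[i] = 0.5 - 0.25 * (f[s] + f[dd])
        if s < 0 or dd < 0:
            f[i] = 0.0
            continue
        # accumulate A_ii = sum_j L_ij^2 D_j over ancestors j, maintaining a
        # linked list of pending ancestors in descending pedigree order
        fi = -1.0
        l_row[i] = 1.0
        j = i
        while j != -1:
            k = j
            r = 0.5 * l_row[j]
            ks, kd = sires[j], dams[j]
            hi, lo = (ks, kd) if ks >= kd else (kd, ks)
            for p in (hi, lo):  # larger index first so insertion scans forward
                if p >= 0:
                    l_row[p] += r
                    while point[k] > p:
                        k = point[k]
                    if point[k] != p:
                        point[p] = point[k]
                        point[k] = p
            fi += l_row[j] * l_row[j] * d[j]
            l_row[j] = 0.0
            nxt = point[j]
            point[j] = -1
            j = nxt
        f[i] = fi
    return f


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Quadratic in pedigree size; intended for small pedigrees and as an
    independent cross-check of the sparse A-inverse construction.
    """
    n = len(ped)
    sires, dams = ped.parent_indices()
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            a[i, i] = 1.0 + 0.5 * a[s, d]
        else:
            a[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * a[j, s]
            if d >= 0:
                val += 0.5 * a[j, d]
            a[i, j] = a[j, i] = val
    return a
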