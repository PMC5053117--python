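"""Pedigree validation and the numerator relationship matrix.

The mixed model used to decorrelate expression data represents relatedness
through the numerator relationship matrix ``A``: the matrix of expected
additive-genetic relationships implied by the pedigree, with diagonal
``1 + F_i`` (``F_i`` the inbreeding coefficient) and off-diagonal entries
equal to twice the kinship coefficient.  ``A`` is built with the classic
tabular (recursive) method: processing animals with parents before
offspring,

    A[i, i] = 1 + 0.5 * A[f, m]
    A[i, j] = 0.5 * (A[j, f] + A[j, m])    for j processed before i,

where ``f``/``m`` are the sire/dam of ``i`` and unknown parents contribute
zero (they are treated as unrelated, non-inbred founders).

Animals whose expression is analysed load half on each parent's additive
effect, so the model only ever consumes the sub-matrix of ``A`` for the
parent generations together with the 0.5/0.5 parent incidence built by
:func:`parent_incidence`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN_PARENT",
    "PedigreeTable",
    "RelationshipMatrix",
    "validate_pedigree",
    "build_relationship_matrix",
    "parent_incidence",
    "read_pedigree_csv",
    "write_pedigree_csv",
]

#: Canonical in-memory sentinel for an unknown parent.
UNKNOWN_PARENT = None

_UNKNOWN_TOKENS = {"", "0", ".", "na", "nan", "none", "unknown"}


def _normalize_parent(value) -> str | None:
    """Map the accepted on-disk unknown-parent spellings to ``None``."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if text.lower() in _UNKNOWN_TOKENS:
        return None
    return text


@dataclass(frozen=True)
class PedigreeTable:
    """A validated pedigree, topologically ordered (parents before offspring).

    ``df`` has columns ``animal``, ``sire``, ``dam`` (``None`` when unknown)
    and ``generation`` (optional label, ``None`` when absent). Animal ids are
    strings compared exactly; no numeric coercion is performed.
    """

    df: pd.DataFrame

    @property
    def animals(self) -> list[str]:
        return self.df["animal"].tolist()

    def parents_of(self, animal: str) -> tuple[str | None, str | None]:
        row = self.df.loc[self.df["animal"] == animal]
        if row.empty:
            raise KeyError(f"animal {animal!r} not in pedigree")
        return row["sire"].iloc[0], row["dam"].iloc[0]

    @property
    def founders(self) -> list[str]:
        mask = self.df["sire"].isna() & self.df["dam"].isna()
        return self.df.loc[mask, "animal"].tolist()

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator relationship matrix ``A`` over an ordered id list.

    Invariants: symmetric, positive semidefinite, diagonal ``1 + F_i`` with
    ``F_i >= 0`` (founders exactly 1), off-diagonals in ``[0, 2]``.
    """

    ids: list[str]
    A: np.ndarray

    def __post_init__(self):
        if self.A.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")

    def index_of(self, animal: str) -> int:
        return self.ids.index(animal)

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        """Sub-matrix for ``ids`` (order preserved)."""
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[a] for a in ids])
        return RelationshipMatrix(list(ids), self.A[np.ix_(idx, idx)])

    def inbreeding(self) -> pd.Series:
        """Inbreeding coefficient ``F_i = A_ii - 1`` per animal."""
        return pd.Series(np.diag(self.A) - 1.0, index=self.ids, name="F")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.ids, columns=self.ids)


def _coerce_records(records) -> pd.DataFrame:
    if isinstance(records, PedigreeTable):
        return records.df.copy()
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        df.columns = [str(c).lower() for c in df.columns]
        if "animal" not in df.columns:
            # positional: animal, sire, dam[, generation]
            names = ["animal", "sire", "dam", "generation"][: df.shape[1]]
            df.columns = names
    else:
        rows = []
        for rec in records:
            if isinstance(rec, Mapping):
                rows.append(
                    [
                        rec.get("animal"),
                        rec.get("sire"),
                        rec.get("dam"),
                        rec.get("generation"),
                    ]
                )
            else:
                rec = list(rec)
                if len(rec) < 3:
                    raise ValueError(
                        f"pedigree row needs >= 3 columns, got {rec!r}"
                    )
                rows.append(rec[:3] + [rec[3] if len(rec) > 3 else None])
        df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation"])
    if "generation" not in df.columns:
        df["generation"] = None
    df["animal"] = df["animal"].astype(str).str.strip()
    df["sire"] = df["sire"].map(_normalize_parent)
    df["dam"] = df["dam"].map(_normalize_parent)
    return df[["animal", "sire", "dam", "generation"]]


def validate_pedigree(records) -> PedigreeTable:
    """Validate raw pedigree rows and return a topologically ordered table.

    Parameters
    ----------
    records
        A DataFrame, an iterable of ``(animal, sire, dam[, generation])``
        rows, or an iterable of mappings. Empty fields, ``"0"`` and the
        usual NA spellings denote an unknown parent.

    Raises
    ------
    ValueError
        On duplicate animal ids, on a parent id that is neither a listed
        animal nor unknown, or on an ancestry cycle (named in the message).
    """
    df = _coerce_records(records)
    dup = df.loc[df["animal"].duplicated(), "animal"]
    if len(dup):
        raise ValueError(f"duplicate animal id(s): {sorted(set(dup))}")
    known = set(df["animal"])
    for col in ("sire", "dam"):
        orphan = {p for p in df[col] if p is not None and p not in known}
        if orphan:
            raise ValueError(
                f"{col} id(s) {sorted(orphan)} do not appear as animals "
                "and are not marked unknown"
            )

    graph = nx.DiGraph()
    graph.add_nodes_from(df["animal"])
    for _, row in df.iterrows():
        for parent in (row["sire"], row["dam"]):
            if parent is not None:
                graph.add_edge(parent, row["animal"])
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        pass
    else:
        path = " -> ".join([edge[0] for edge in cycle] + [cycle[-1][1]])
        raise ValueError(f"pedigree cycle detected: {path}")

    # lexicographic tie-break makes the order independent of input row order
    order = list(nx.lexicographical_topological_sort(graph))
    rank = {a: i for i, a in enumerate(order)}
    df = df.sort_values("animal", key=lambda s: s.map(rank), kind="mergesort")
    return PedigreeTable(df.reset_index(drop=True))


def build_relationship_matrix(ped: PedigreeTable) -> RelationshipMatrix:
    """Compute the numerator relationship matrix by the tabular method.

    Unknown parents are treated as unrelated, non-inbred founders: their
    terms simply drop out of the recursion.
    """
    ids = ped.animals
    index = {a: i for i, a in enumerate(ids)}
    sire = np.array(
        [index[s] if s is not None else -1 for s in ped.df["sire"]], dtype=int
    )
    dam = np.array(
        [index[d] if d is not None else -1 for d in ped.df["dam"]], dtype=int
    )
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        f, m = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if f >= 0:
                row += 0.5 * A[:i, f]
            if m >= 0:
                row += 0.5 * A[:i, m]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[f, m] if f >= 0 and m >= 0 else 0.0)
    return RelationshipMatrix(ids, A)


def parent_incidence(
    ped: PedigreeTable, phenotyped_ids: Sequence[str]
) -> pd.DataFrame:
    """Incidence of phenotyped animals on their parents' additive effects.

    Each phenotyped animal loads 0.5 on its sire's and 0.5 on its dam's
    additive-genetic effect (its expected breeding value is half the parent
    sum; the Mendelian-sampling remainder stays in the residual). Returns a
    DataFrame with one row per phenotyped animal and one column per parent,
    columns ordered by pedigree (topological) order. Rows sum to 1.

    Raises
    ------
    ValueError
        If a phenotyped animal has an unknown sire or dam.
    """
    lookup = {
        row.animal: (row.sire, row.dam) for row in ped.df.itertuples()
    }
    pairs: dict[str, tuple[str, str]] = {}
    for animal in phenotyped_ids:
        if animal not in lookup:
            raise ValueError(f"phenotyped animal {animal!r} not in pedigree")
        s, d = lookup[animal]
        if s is None or d is None:
            raise ValueError(
                f"phenotyped animal {animal!r} has an unknown parent "
                f"(sire={s!r}, dam={d!r})"
            )
        pairs[animal] = (s, d)
    parent_set = {p for pair in pairs.values() for p in pair}
    parents = [a for a in ped.animals if a in parent_set]
    Z = pd.DataFrame(
        0.0, index=list(phenotyped_ids), columns=parents, dtype=float
    )
    for animal, (s, d) in pairs.items():
        Z.loc[animal, s] += 0.5
        Z.loc[animal, d] += 0.5
    return Z


def read_pedigree_csv(path) -> PedigreeTable:
    """Read and validate ``animal,sire,dam[,generation]`` CSV."""
    df = pd.read_csv(path, dtype=str)
    return validate_pedigree(df)


def write_pedigree_csv(ped: PedigreeTable, path) -> None:
    out = ped.df.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].fillna("0")
    if out["generation"].isna().all():
        out = out.drop(columns=["generation"])
    out.to_csv(path, index=False)
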