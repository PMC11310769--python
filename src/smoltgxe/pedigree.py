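"""Pedigree container.

A pedigree is a table of (id, sire, dam, sex) records. Unknown parents are
coded with the sentinel ``"0"`` (PLINK convention). Founders are records whose
parents are both unknown.
"""

from __future__ import annotations

import pandas as pd

UNKNOWN = "0"


class PedigreeError(ValueError):
    pass


class Pedigree:
    """Ordered pedigree with founder support.

    Parameters
    ----------
    table:
        DataFrame with columns ``id, sire, dam`` (and optionally ``sex``).
        Ids are coerced to strings; missing parents to ``"0"``.
    """

    def __init__(self, table: pd.DataFrame):
        tab = table.copy()
        for col in ("id", "sire", "dam"):
            if col not in tab.columns:
                raise PedigreeError(f"pedigree table missing column {col!r}")
            tab[col] = tab[col].fillna(UNKNOWN).astype(str)
        if "sex" not in tab.columns:
            tab["sex"] = UNKNOWN
        if tab["id"].duplicated().any():
            dups = tab.loc[tab["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicate pedigree ids: {dups[:5]}")
        self.table = tab.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, ind: str) -> bool:
        return ind in set(self.table["id"])

    def parents(self, ind: str) -> tuple[str, str]:
        row = self.table.loc[self.table["id"] == ind]
        if row.empty:
            raise PedigreeError(f"unknown individual {ind!r}")
        return row["sire"].iloc[0], row["dam"].iloc[0]

    def founders(self) -> list[str]:
        tab = self.table
        mask = (tab["sire"] == UNKNOWN) & (tab["dam"] == UNKNOWN)
        return tab.loc[mask, "id"].tolist()

    def sorted_topologically(self) -> "Pedigree":
        """Return a copy ordered parents-before-offspring.

        Raises ``PedigreeError`` naming a cycle if the pedigree is cyclic.
        Parents that never appear as ids are treated as unknown founders.
        """
        tab = self.table
        known = set(tab["id"])
        deps = {
            r.id: [p for p in (r.sire, r.dam) if p != UNKNOWN and p in known]
            for r in tab.itertuples()
        }
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        for root in tab["id"]:
            if root in state:
                continue
            stack = [(root, iter(deps[root]))]
            state[root] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 0:
                        raise PedigreeError(f"pedigree cycle involving {p!r}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(deps[p])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    order.append(node)
                    stack.pop()
        pos = {ind: i for i, ind in enumerate(order)}
        out = tab.iloc[sorted(range(len(tab)), key=lambda i: pos[tab["id"].iloc[i]])]
        return Pedigree(out.reset_index(drop=True))

    def extended_with(self, other: pd.DataFrame) -> "Pedigree":
        return Pedigree(pd.concat([self.table, other], ignore_index=True))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, sep="\t", dtype=str))
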