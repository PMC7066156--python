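"""Weighted bivariate pair sets for familial regression.

Four pair kinds are built from per-individual adjusted phenotype values and
the pedigree:

* ``OP`` — offspring on parent.  Offspring with both parents measured
  contribute two pairs weighted 1/2 each; with a single measured parent, one
  pair of weight 1.  Each offspring therefore carries total weight 1.
* ``MIDPARENT`` — offspring on the mean of both parents' values, restricted
  to families with both parents measured; weight 1.
* ``FS`` — all ordered sib-co-sib combinations within full sibships (shared
  father and mother), k(k-1) pairs for a sibship of size k.  Each ordered
  pair gets weight 1/(k-1) so every sibling contributes total weight 1 as
  the dependent member; a flat per-pair weight of 1 is available as an
  option.
* ``SPOUSE`` — one pair per parental couple with both members measured.

Degrees of freedom follow the familial-regression convention:
``sum(k_i) - 2`` for offspring-parent style sets (k_i offspring per family)
and ``sum(k_i - 1)`` for full-sib sets (k_i sibs per sibship).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairSet",
    "build_op_pairs",
    "build_midparent_pairs",
    "build_fullsib_pairs",
    "build_spouse_pairs",
    "weighted_correlation",
]

PAIR_COLUMNS = ["y_id", "x_id", "y", "x", "weight", "family_id"]


@dataclass
class PairSet:
    kind: str
    pairs: pd.DataFrame
    df: int
    family_sizes: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def total_weight(self) -> float:
        return float(self.pairs["weight"].sum())

    def to_tsv(self, path) -> None:
        out = self.pairs.copy()
        out["kind"] = self.kind
        out.to_csv(path, sep="\t", index=False)


def _value_map(adjusted: pd.DataFrame) -> pd.Series:
    if isinstance(adjusted, pd.Series):
        return adjusted
    return adjusted.set_index("individual_id")["value"]


def _finish(kind, rows, df, family_sizes) -> PairSet:
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if len(pairs) == 0:
        raise ValueError(f"no {kind} pairs could be formed")
    pairs = pairs.sort_values(["family_id", "y_id", "x_id"], kind="stable").reset_index(
        drop=True
    )
    return PairSet(kind=kind, pairs=pairs, df=int(df), family_sizes=dict(family_sizes))


def _family_key(father, mother) -> str:
    return f"{father or '?'}|{mother or '?'}"


def _iter_offspring(pedigree: pd.DataFrame, values: pd.Series):
    """Yield (child_id, father_id, mother_id) with the child measured."""
    for row in pedigree.itertuples(index=False):
        if row.individual_id not in values.index:
            continue
        f = row.father_id if isinstance(row.father_id, str) and row.father_id else None
        m = row.mother_id if isinstance(row.mother_id, str) and row.mother_id else None
        yield row.individual_id, f, m


def build_op_pairs(adjusted, pedigree: pd.DataFrame) -> PairSet:
    """Offspring-parent pairs with the half/half (both parents) weighting."""
    values = _value_map(adjusted)
    rows = []
    fam_sizes: dict[str, int] = {}
    for child, f, m in _iter_offspring(pedigree, values):
        parents = [p for p in (f, m) if p is not None and p in values.index]
        if not parents:
            continue
        fam = _family_key(f, m)
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1
        w = 0.5 if len(parents) == 2 else 1.0
        for p in parents:
            rows.append((child, p, values[child], values[p], w, fam))
    df = sum(fam_sizes.values()) - 2
    return _finish("OP", rows, df, fam_sizes)


def build_midparent_pairs(adjusted, pedigree: pd.DataFrame) -> PairSet:
    """Offspring on the average of both parents, families with both measured."""
    values = _value_map(adjusted)
    rows = []
    fam_sizes: dict[str, int] = {}
    for child, f, m in _iter_offspring(pedigree, values):
        if f is None or m is None or f not in values.index or m not in values.index:
            continue
        fam = _family_key(f, m)
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1
        mid = 0.5 * (values[f] + values[m])
        rows.append((child, f"{f}+{m}", values[child], mid, 1.0, fam))
    df = sum(fam_sizes.values()) - 2
    return _finish("MIDPARENT", rows, df, fam_sizes)


def build_fullsib_pairs(adjusted, pedigree: pd.DataFrame, flat_weights: bool = False) -> PairSet:
    """All ordered sib pairs within full sibships (both parent ids shared)."""
    values = _value_map(adjusted)
    sibships: dict[str, list[str]] = {}
    for child, f, m in _iter_offspring(pedigree, values):
        if f is None or m is None:
            continue
        sibships.setdefault(_family_key(f, m), []).append(child)
    rows = []
    fam_sizes = {}
    for fam, sibs in sibships.items():
        k = len(sibs)
        if k < 2:
            continue
        fam_sizes[fam] = k
        w = 1.0 if flat_weights else 1.0 / (k - 1)
        for a in sibs:
            for b in sibs:
                if a != b:
                    rows.append((a, b, values[a], values[b], w, fam))
    df = sum(k - 1 for k in fam_sizes.values())
    return _finish("FS", rows, df, fam_sizes)


def build_spouse_pairs(adjusted, pedigree: pd.DataFrame) -> PairSet:
    """One pair per parental couple with both members measured."""
    values = _value_map(adjusted)
    couples = set()
    for row in pedigree.itertuples(index=False):
        f = row.father_id if isinstance(row.father_id, str) and row.father_id else None
        m = row.mother_id if isinstance(row.mother_id, str) and row.mother_id else None
        if f is None or m is None:
            continue
        if f in values.index and m in values.index:
            couples.add((f, m))
    rows = [
        (f, m, values[f], values[m], 1.0, _family_key(f, m)) for f, m in sorted(couples)
    ]
    fam_sizes = {_family_key(f, m): 2 for f, m in couples}
    df = max(len(rows) - 2, 1)
    return _finish("SPOUSE", rows, df, fam_sizes)


def weighted_correlation(pairs) -> float:
    """Weight-aware Pearson correlation (weights as frequency weights)."""
    if isinstance(pairs, PairSet):
        x = pairs.pairs["x"].to_numpy(float)
        y = pairs.pairs["y"].to_numpy(float)
        w = pairs.pairs["weight"].to_numpy(float)
    else:
        x, y, w = pairs
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        w = np.ones_like(x) if w is None else np.asarray(w, float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    sw = w.sum()
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    syy = np.sum(w * (y - my) ** 2)
    if sxx <= 0.0 or syy <= 0.0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.sum(w * (x - mx) * (y - my)) / np.sqrt(sxx * syy))
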