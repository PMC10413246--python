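"""Corresponding-feature encoding of ordered disease triplets.

An ordered triplet A→B→C is expanded into 7 feature groups — 4 ordinal
(order-sensitive) and 3 nonordinal (order-free) — 15 binary features in all:

====== ========== =======================================================
group  type       tokens for (A, B, C)
====== ========== =======================================================
1      ordinal    A→B→C                    (the full ordered pathway)
2      ordinal    A→B, B→C                 (consecutive ordered doublets)
3      ordinal    1_A→B, 2_B→C             (doublets tagged with position)
4      ordinal    1_A, 2_B, 3_C            (single diseases with position)
5      nonordinal A, B, C                  (single diseases, order-free)
6      nonordinal A&B, A&C, B&C            (disease pairs, order-free)
7      nonordinal A&B&C                    (the disease set, order-free)
====== ========== =======================================================

Nonordinal tokens canonicalise their categories by lexicographic sort, so
(A,B,C) and (C,B,A) share all group-5..7 keys and none of group 1–4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .preprocessing import PersonTimeline, Triplet, enumerate_triplets

ARROW = "→"
AMP = "&"

ORDINAL_GROUPS = (1, 2, 3, 4)
NONORDINAL_GROUPS = (5, 6, 7)
GROUP_SIZES = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 3, 7: 1}


@dataclass(frozen=True, order=True)
class FeatureKey:
    """One binary feature: its group (1-7) and canonical token string."""

    group: int
    token: str

    def __str__(self) -> str:  # round-trips through parse_key
        return f"g{self.group}:{self.token}"


def parse_key(text: str) -> FeatureKey:
    """Inverse of ``str(FeatureKey)``."""
    head, _, token = text.partition(":")
    if not head.startswith("g") or not token:
        raise ValueError(f"malformed feature key {text!r}")
    return FeatureKey(group=int(head[1:]), token=token)


def encode_triplet(triplet: Triplet) -> tuple[FeatureKey, ...]:
    """The 15 corresponding-feature keys of one ordered triplet.

    Group sizes are (1, 2, 2, 3, 3, 3, 1). Raises on repeated categories.
    """
    a, b, c = triplet
    if len({a, b, c}) != 3:
        raise ValueError(f"triplet categories must be distinct, got {triplet}")
    pairs = [tuple(sorted(p)) for p in ((a, b), (a, c), (b, c))]
    keys = (
        FeatureKey(1, f"{a}{ARROW}{b}{ARROW}{c}"),
        FeatureKey(2, f"{a}{ARROW}{b}"),
        FeatureKey(2, f"{b}{ARROW}{c}"),
        FeatureKey(3, f"1_{a}{ARROW}{b}"),
        FeatureKey(3, f"2_{b}{ARROW}{c}"),
        FeatureKey(4, f"1_{a}"),
        FeatureKey(4, f"2_{b}"),
        FeatureKey(4, f"3_{c}"),
        FeatureKey(5, a),
        FeatureKey(5, b),
        FeatureKey(5, c),
        FeatureKey(6, AMP.join(pairs[0])),
        FeatureKey(6, AMP.join(pairs[1])),
        FeatureKey(6, AMP.join(pairs[2])),
        FeatureKey(7, AMP.join(sorted((a, b, c)))),
    )
    return keys


@dataclass
class FeatureVocabulary:
    """Deduplicated feature keys with provenance back to their triplets."""

    keys: list[FeatureKey]
    provenance: dict[FeatureKey, set[Triplet]]
    index: dict[FeatureKey, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {k: i for i, k in enumerate(self.keys)}

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def groups(self) -> np.ndarray:
        return np.array([k.group for k in self.keys])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "key": [str(k) for k in self.keys],
                "group": [k.group for k in self.keys],
                "triplets": [
                    ";".join(ARROW.join(t) for t in sorted(self.provenance[k]))
                    for k in self.keys
                ],
            }
        )


def build_vocabulary(triplets: set[Triplet] | list[Triplet]) -> FeatureVocabulary:
    """Union of encode_triplet over the selected triplets, deduplicated.

    Keys are ordered by (group, token) for determinism; each key remembers
    every triplet that generates it, enabling back-mapping from a fitted
    model's selected features to disease pathways.
    """
    if not triplets:
        raise ValueError("cannot build a vocabulary from an empty triplet selection")
    prov: dict[FeatureKey, set[Triplet]] = {}
    for t in triplets:
        for k in encode_triplet(t):
            prov.setdefault(k, set()).add(t)
    keys = sorted(prov)
    return FeatureVocabulary(keys=keys, provenance=prov)


@dataclass
class FeatureMatrix:
    """Persons x features binary design matrix with labels."""

    matrix: sparse.csr_matrix
    person_ids: list[str]
    vocabulary: FeatureVocabulary
    y: np.ndarray  # case labels aligned with person_ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def assign_features_row(
    timeline: PersonTimeline,
    selected: set[Triplet],
    vocabulary: FeatureVocabulary,
    mode: str = "selected",
) -> set[int]:
    """Column indices set to 1 for one person.

    mode="selected" (default): a key fires iff some triplet in the person's
    enumerated set INTERSECTED with the selected set generates it.
    mode="all": the selection is ignored; any enumerated triplet that
    generates a vocabulary key fires it (pattern-in-raw-sequence semantics).
    """
    if mode not in ("selected", "all"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    enumerated = enumerate_triplets(timeline)
    active = enumerated & selected if mode == "selected" else enumerated
    cols: set[int] = set()
    for t in active:
        for k in encode_triplet(t):
            j = vocabulary.index.get(k)
            if j is not None:
                cols.add(j)
    return cols


def assign_features(
    timelines: list[PersonTimeline],
    selected: set[Triplet],
    vocabulary: FeatureVocabulary,
    mode: str = "selected",
) -> FeatureMatrix:
    """Build the persons x features binary matrix over a cohort."""
    rows: list[int] = []
    cols: list[int] = []
    y = np.zeros(len(timelines), dtype=int)
    ids = []
    for i, tl in enumerate(timelines):
        ids.append(tl.person_id)
        y[i] = int(tl.is_case)
        for j in assign_features_row(tl, selected, vocabulary, mode=mode):
            rows.append(i)
            cols.append(j)
    m = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(timelines), len(vocabulary)),
    )
    return FeatureMatrix(matrix=m, person_ids=ids, vocabulary=vocabulary, y=y)


def write_feature_matrix(fm: FeatureMatrix, out_dir) -> None:
    """Write matrix.mtx plus persons.txt / features.csv label files."""
    from pathlib import Path

    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), fm.matrix)
    pd.DataFrame({"person_id": fm.person_ids, "is_case": fm.y}).to_csv(
        out / "persons.csv", index=False
    )
    fm.vocabulary.to_frame().to_csv(out / "features.csv", index=False)
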