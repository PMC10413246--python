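"""Incident-diagnosis validation, category mapping, sequences and triplets.

A diagnosis category is accepted as a true incident condition for a person
only if it is documented at least ``min_outpatient`` times in outpatient
claims within a ``window_days`` window, or appears on at least one
inpatient (admission) claim — the standard claims-validation rule that
filters rule-out and miscoded visits. The incident date is the first claim
of the category in any setting. Validated categories are sorted by incident
date into a per-person disease sequence, from which every ordered triple of
distinct categories with strictly increasing dates ("hierarchical disease
triplet cluster") is enumerated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"

Triplet = tuple[str, str, str]


@dataclass(frozen=True)
class DiagnosisEvent:
    """One dated diagnosis claim for one person."""

    person_id: str
    date: pd.Timestamp
    code: str
    setting: str


@dataclass
class PersonTimeline:
    """A person's validated incident diagnoses as a strictly dated sequence.

    ``incidents`` is sorted ascending by incident date (ties sorted by
    category for determinism); categories are distinct. Diseases sharing an
    incident date are mutually unordered: they contribute no ordered pair
    between themselves, only with strictly earlier / later diseases.
    """

    person_id: str
    is_case: bool
    index_date: pd.Timestamp
    incidents: list[tuple[str, pd.Timestamp]]

    @property
    def categories(self) -> list[str]:
        return [c for c, _ in self.incidents]

    def date_of(self) -> dict[str, pd.Timestamp]:
        return {c: d for c, d in self.incidents}

    def __len__(self) -> int:
        return len(self.incidents)


@dataclass
class TripletCluster:
    """An ordered disease triple with case/control exposure counts."""

    d1: str
    d2: str
    d3: str
    n_case_exposed: int
    n_case_unexposed: int
    n_ctrl_exposed: int
    n_ctrl_unexposed: int

    @property
    def triplet(self) -> Triplet:
        return (self.d1, self.d2, self.d3)


def map_to_ccs(
    events: pd.DataFrame,
    mapping: pd.DataFrame | dict[str, str],
    strict: bool = False,
) -> pd.DataFrame:
    """Map diagnosis codes to grouper categories by longest-prefix match.

    ``mapping`` is a two-column table (code prefix -> category label) in the
    style of the Clinical Classifications Software crosswalk, which collapses
    ICD-9 codes into ~253 clinically coherent categories. Codes matching no
    prefix are routed to the sentinel category ``UNMAPPED`` and counted in
    the log.
    """
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] < 2:
            raise ValueError("mapping table needs two columns: prefix, category")
        pairs = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    else:
        pairs = {str(k): str(v) for k, v in mapping.items()}
    if not pairs and strict:
        raise ValueError("empty code mapping in strict mode")
    prefixes = {p.replace(".", ""): v for p, v in pairs.items()}

    def lookup(code: str) -> str:
        code = str(code).replace(".", "").strip()
        for ln in range(len(code), 0, -1):
            cat = prefixes.get(code[:ln])
            if cat is not None:
                return cat
        return UNMAPPED

    uniq = pd.unique(events["code"].astype(str))
    table = {c: lookup(c) for c in uniq}
    out = events.copy()
    out["category"] = out["code"].astype(str).map(table)
    n_unmapped = int((out["category"] == UNMAPPED).sum())
    if n_unmapped:
        logger.info("map_to_ccs: %d claims routed to %s", n_unmapped, UNMAPPED)
    return out


def validate_diagnoses(
    events: pd.DataFrame,
    window_days: int = 365,
    min_outpatient: int = 3,
) -> dict[str, dict[str, pd.Timestamp]]:
    """Per-person map of validated category -> incident (first-claim) date.

    A (person, category) pair is valid iff some ``window_days`` window
    contains >= ``min_outpatient`` outpatient claims of the category, OR the
    category appears on >= 1 inpatient claim. Given validity, the incident
    date is the earliest claim of the category in ANY setting. Categories
    failing the rule are excluded (count reported at INFO level).
    """
    cat_col = "category" if "category" in events.columns else "code"
    ev = events[["person_id", cat_col, "date", "setting"]].rename(
        columns={cat_col: "category"}
    )
    ev = ev.sort_values(["person_id", "category", "date"], kind="stable")

    inpat = ev.loc[ev["setting"] == "inpatient", ["person_id", "category"]]
    valid_inpat = set(map(tuple, inpat.drop_duplicates().to_numpy()))

    outp = ev[ev["setting"] == "outpatient"]
    valid_outp: set[tuple[str, str]] = set()
    if len(outp) >= min_outpatient:
        grp = outp.groupby(["person_id", "category"], sort=False)
        anchor = grp["date"].shift(min_outpatient - 1)
        ok = (outp["date"] - anchor).dt.days < window_days
        hit = outp.loc[ok.fillna(False), ["person_id", "category"]]
        valid_outp = set(map(tuple, hit.drop_duplicates().to_numpy()))

    valid = valid_inpat | valid_outp
    first = ev.groupby(["person_id", "category"], sort=False)["date"].min()
    n_dropped = len(first) - len(valid & set(first.index))
    if n_dropped:
        logger.info("validate_diagnoses: %d (person, category) pairs failed validation", n_dropped)

    result: dict[str, dict[str, pd.Timestamp]] = {}
    for (pid, cat), d in first.items():
        if (pid, cat) in valid:
            result.setdefault(pid, {})[cat] = d
    return result


def build_sequence(
    incident_map: dict[str, pd.Timestamp],
    index_date: pd.Timestamp,
    person_id: str = "",
    is_case: bool = False,
    exclude_categories: frozenset[str] | set[str] = frozenset(),
) -> PersonTimeline:
    """Sort a person's validated incidents into a dated disease sequence.

    Incidents on or after the index date are dropped (logged), as are
    outcome-defining categories passed via ``exclude_categories`` so that
    the outcome cannot leak into its own predictors.
    """
    index_date = pd.Timestamp(index_date)
    kept: list[tuple[str, pd.Timestamp]] = []
    n_late = 0
    for cat, d in incident_map.items():
        if cat in exclude_categories:
            continue
        if pd.Timestamp(d) < index_date:
            kept.append((cat, pd.Timestamp(d)))
        else:
            n_late += 1
    if n_late:
        logger.info(
            "build_sequence(%s): dropped %d incidents on/after index date", person_id, n_late
        )
    kept.sort(key=lambda cd: (cd[1], cd[0]))
    return PersonTimeline(person_id=person_id, is_case=is_case, index_date=index_date, incidents=kept)


def build_timelines(
    events: pd.DataFrame,
    registry: pd.DataFrame,
    mapping: pd.DataFrame | dict[str, str] | None = None,
    window_days: int = 365,
    min_outpatient: int = 3,
    exclude_categories: frozenset[str] | set[str] = frozenset(),
) -> list[PersonTimeline]:
    """End-to-end: map codes (optional), validate, and build all sequences.

    Every registry person gets a timeline (possibly empty), in registry
    order.
    """
    if mapping is not None:
        events = map_to_ccs(events, mapping)
    incidents = validate_diagnoses(events, window_days=window_days, min_outpatient=min_outpatient)
    timelines = []
    for row in registry.itertuples(index=False):
        timelines.append(
            build_sequence(
                incidents.get(row.person_id, {}),
                index_date=row.index_date,
                person_id=row.person_id,
                is_case=bool(row.is_case),
                exclude_categories=exclude_categories,
            )
        )
    return timelines


def enumerate_triplets(timeline: PersonTimeline) -> set[Triplet]:
    """All ordered disease triples with strictly increasing incident dates.

    For a sequence of n strictly dated diseases this yields exactly
    n(n-1)(n-2)/6 triples; diseases sharing a date contribute no order
    relation between themselves.
    """
    cats = [c for c, _ in timeline.incidents]
    dates = [d for _, d in timeline.incidents]
    n = len(cats)
    out: set[Triplet] = set()
    for i, j, k in combinations(range(n), 3):
        if dates[i] < dates[j] < dates[k]:
            out.add((cats[i], cats[j], cats[k]))
    return out


def count_support(
    timelines: list[PersonTimeline],
    min_case_support: int = 10,
) -> pd.DataFrame:
    """Triplet support table over a cohort, thresholded on case support.

    A person is exposed to a triple iff it is in their enumerated set. Only
    triples enumerated in >= ``min_case_support`` CASE timelines are kept;
    control exposure is then counted for the surviving triples. Columns:
    d1, d2, d3, n_case_exposed, n_case_unexposed, n_ctrl_exposed,
    n_ctrl_unexposed.
    """
    case_counts: dict[Triplet, int] = {}
    n_cases = 0
    n_ctrls = 0
    control_sets: list[set[Triplet]] = []
    for tl in timelines:
        if tl.is_case:
            n_cases += 1
            for t in enumerate_triplets(tl):
                case_counts[t] = case_counts.get(t, 0) + 1
        else:
            n_ctrls += 1
            control_sets.append(enumerate_triplets(tl))

    kept = {t: c for t, c in case_counts.items() if c >= min_case_support}
    ctrl_counts = {t: 0 for t in kept}
    for s in control_sets:
        for t in s & kept.keys():
            ctrl_counts[t] += 1

    rows = [
        (t[0], t[1], t[2], a, n_cases - a, ctrl_counts[t], n_ctrls - ctrl_counts[t])
        for t, a in kept.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "d1",
            "d2",
            "d3",
            "n_case_exposed",
            "n_case_unexposed",
            "n_ctrl_exposed",
            "n_ctrl_unexposed",
        ],
    )
    return df.sort_values(
        ["n_case_exposed", "d1", "d2", "d3"], ascending=[False, True, True, True]
    ).reset_index(drop=True)


def read_mapping(path: str | Path) -> pd.DataFrame:
    """Read a two-column prefix -> category mapping from delimited text."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"mapping file {path} must have two columns")
    return df.iloc[:, :2]


def toy_mapping() -> pd.DataFrame:
    """The small bundled ICD-9-prefix -> category crosswalk fixture."""
    return read_mapping(Path(__file__).parent / "data" / "toy_ccs.csv")
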