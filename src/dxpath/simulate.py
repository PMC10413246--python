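"""Synthetic matched case-control claims cohorts with planted ordered pathways.

Real claims databases suitable for disease-trajectory mining (national
insurance claims, EHR registries) are access-restricted, so this module
generates cohorts with the same shape: per-person dated diagnosis streams
over a multi-year window, heavy outpatient utilisation typical of older
adults, 1:1 case-control matching on age, sex and index year, and ordered
disease-triplet pathways planted with an elevated probability in cases.

All randomness flows from a single seed through independent per-stage
substreams (registry, background diagnoses, pathway planting, claim
emission), so cohorts are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

OUTPATIENT = "outpatient"
INPATIENT = "inpatient"

# A planted triple spans at most END_MARGIN_MAX + 2 * GAP_MAX days before
# the index date; the lookback must accommodate that span.
GAP_MIN, GAP_MAX = 30, 365
END_MARGIN_MIN, END_MARGIN_MAX = 30, 180
_MAX_PLANT_SPAN = END_MARGIN_MAX + 2 * GAP_MAX


class InfeasibleConfigError(ValueError):
    """The configured study window cannot hold a planted pathway."""


@dataclass(frozen=True)
class PlantedPathway:
    """An ordered disease triple occurring with elevated probability in cases.

    ``p_case`` / ``p_control`` are the probabilities that the full ordered
    occurrence (first, second, third disease with strictly increasing
    incident dates) is planted in a case / control person's history.
    """

    categories: tuple[str, str, str]
    p_case: float
    p_control: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        if len(self.categories) != 3 or len(set(self.categories)) != 3:
            raise ValueError(f"pathway needs 3 distinct categories, got {self.categories}")
        for p in (self.p_case, self.p_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pathway probability {p} outside [0, 1]")
        if self.p_case < self.p_control:
            raise ValueError(
                f"pathway {self.categories}: p_case ({self.p_case}) must be "
                f">= p_control ({self.p_control})"
            )


def default_vocabulary(n_categories: int) -> list[str]:
    """Disease-category labels D001..Dnnn standing in for grouper categories."""
    return [f"D{i:03d}" for i in range(1, n_categories + 1)]


@dataclass
class SimConfig:
    """Cohort-generator configuration.

    Defaults emulate an older-adult claims cohort: ~30 outpatient visits per
    person-year, a multi-year observation window, and a modest stream of
    incident diagnoses drawn uniformly over the category vocabulary.
    """

    n_cases: int = 500
    control_ratio: int = 1
    n_categories: int = 40
    study_start: date = date(2003, 1, 1)
    study_end: date = date(2013, 12, 31)
    background_rate: float = 2.0  # incident diagnoses per person-year
    planted_pathways: list[PlantedPathway] = field(default_factory=list)
    visit_rate: float = 30.0  # outpatient visits per person-year
    admission_prob: float = 0.10  # probability a diagnosis episode is inpatient
    age_range: tuple[int, int] = (55, 90)
    sex_ratio: float = 0.5  # fraction female
    min_lookback_days: int = 1095
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.control_ratio < 1:
            raise ValueError("control_ratio must be >= 1")
        if self.n_categories < 3:
            raise ValueError("n_categories must be >= 3")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if not 0.0 <= self.admission_prob <= 1.0:
            raise ValueError("admission_prob outside [0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio outside [0, 1]")
        if self.background_rate < 0 or self.visit_rate < 0:
            raise ValueError("rates must be nonnegative")
        self.planted_pathways = [
            pw if isinstance(pw, PlantedPathway) else PlantedPathway(*pw)
            for pw in self.planted_pathways
        ]
        window = (self.study_end - self.study_start).days
        if window <= self.min_lookback_days:
            raise ValueError(
                "study window shorter than min_lookback_days; no index date fits"
            )
        vocab = set(default_vocabulary(self.n_categories))
        for pw in self.planted_pathways:
            if self.min_lookback_days < _MAX_PLANT_SPAN:
                raise InfeasibleConfigError(
                    f"pathway {'->'.join(pw.categories)} needs up to "
                    f"{_MAX_PLANT_SPAN} days of lookback but min_lookback_days="
                    f"{self.min_lookback_days}"
                )
            missing = [c for c in pw.categories if c not in vocab]
            if missing:
                raise InfeasibleConfigError(
                    f"pathway {'->'.join(pw.categories)} uses categories "
                    f"{missing} outside the {self.n_categories}-category vocabulary"
                )


def _emit_claims(
    rng: np.random.Generator,
    incidents: dict[str, int],
    index_off: int,
    cfg: SimConfig,
    obs_start: int,
) -> tuple[list[str], list[int], list[str]]:
    """Claims (category, day-offset, setting) realising a person's incidents.

    Each incident diagnosis is emitted so that it passes downstream
    validation: one inpatient claim with probability ``admission_prob``,
    otherwise three outpatient claims inside a 300-day window. Additional
    outpatient visits at ``visit_rate`` re-bill already-established
    categories, so repeat claims never move a first-diagnosis date.
    """
    cats: list[str] = []
    days: list[int] = []
    settings: list[str] = []
    for cat, d in incidents.items():
        if rng.random() < cfg.admission_prob:
            cats.append(cat)
            days.append(d)
            settings.append(INPATIENT)
        else:
            span = min(300, index_off - d - 1)
            offs = np.sort(rng.integers(0, max(span, 0) + 1, size=2))
            for o in (0, int(offs[0]), int(offs[1])):
                cats.append(cat)
                days.append(d + o)
                settings.append(OUTPATIENT)
    # repeat-visit stream: realistic utilisation volume, no new incidents
    years = (index_off - obs_start) / 365.25
    n_visits = int(rng.poisson(cfg.visit_rate * years)) if cfg.visit_rate > 0 else 0
    if n_visits > 0 and incidents:
        inc_cats = np.array(list(incidents.keys()))
        inc_days = np.array(list(incidents.values()))
        order = np.argsort(inc_days, kind="stable")
        inc_cats, inc_days = inc_cats[order], inc_days[order]
        visit_days = rng.integers(obs_start + 1, index_off, size=n_visits)
        n_eligible = np.searchsorted(inc_days, visit_days, side="right")
        keep = n_eligible > 0
        visit_days, n_eligible = visit_days[keep], n_eligible[keep]
        picks = (rng.random(len(visit_days)) * n_eligible).astype(np.int64)
        cats.extend(inc_cats[picks])
        days.extend(int(v) for v in visit_days)
        settings.extend([OUTPATIENT] * len(visit_days))
    return cats, days, settings


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (event table, person registry) for a matched cohort.

    Returns
    -------
    events : DataFrame with columns person_id, date, code, setting.
    registry : DataFrame with columns person_id, birth_year, sex, is_case,
        index_date, match_id. Each control row's match_id names its case.

    All event dates strictly precede the person's index date, and planted
    pathway diagnoses are emitted so each passes the incident-validation
    rule (>=3 outpatient claims within a year, or one inpatient claim).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_reg, rng_bg, rng_plant, rng_claims = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    vocab = np.array(default_vocabulary(cfg.n_categories))
    start = cfg.study_start
    earliest_index = cfg.min_lookback_days
    latest_index = (cfg.study_end - start).days

    reg_rows: list[tuple] = []
    persons: list[tuple[str, bool, int]] = []  # (pid, is_case, index_off)

    for i in range(cfg.n_cases):
        case_id = f"case_{i:05d}"
        age = int(rng_reg.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        sex = "F" if rng_reg.random() < cfg.sex_ratio else "M"
        index_off = int(rng_reg.integers(earliest_index, latest_index + 1))
        index_date = start + timedelta(days=index_off)
        birth_year = index_date.year - age
        reg_rows.append((case_id, birth_year, sex, True, index_date, case_id))
        persons.append((case_id, True, index_off))
        for j in range(cfg.control_ratio):
            ctrl_id = f"ctrl_{i:05d}_{j}"
            year = index_date.year
            lo = max((date(year, 1, 1) - start).days, earliest_index)
            hi = min((date(year, 12, 31) - start).days, latest_index)
            c_off = int(rng_reg.integers(lo, hi + 1))
            reg_rows.append(
                (ctrl_id, birth_year, sex, False, start + timedelta(days=c_off), case_id)
            )
            persons.append((ctrl_id, False, c_off))

    ev_pid: list[str] = []
    ev_day: list[int] = []
    ev_cat: list[str] = []
    ev_set: list[str] = []
    for pid, is_case, index_off in persons:
        years = index_off / 365.25
        k = min(int(rng_bg.poisson(cfg.background_rate * years)), cfg.n_categories)
        cats = rng_bg.choice(vocab, size=k, replace=False)
        max_off = index_off - 31
        offs = rng_bg.integers(0, max_off + 1, size=k)
        incidents = {str(c): int(o) for c, o in zip(cats, offs)}
        for pw in cfg.planted_pathways:
            p = pw.p_case if is_case else pw.p_control
            if rng_plant.random() < p:
                end_margin = int(rng_plant.integers(END_MARGIN_MIN, END_MARGIN_MAX + 1))
                g1 = int(rng_plant.integers(GAP_MIN, GAP_MAX + 1))
                g2 = int(rng_plant.integers(GAP_MIN, GAP_MAX + 1))
                d3 = index_off - end_margin
                d2 = d3 - g2
                d1 = d2 - g1
                if d1 < 0:
                    raise InfeasibleConfigError(
                        f"pathway {'->'.join(pw.categories)} does not fit before "
                        f"index day {index_off} of person {pid}"
                    )
                # planting overrides any background first-diagnosis of A, B, C
                for c, d in zip(pw.categories, (d1, d2, d3)):
                    incidents[c] = d
        cats_i, days_i, sets_i = _emit_claims(rng_claims, incidents, index_off, cfg, 0)
        ev_pid.extend([pid] * len(cats_i))
        ev_day.extend(days_i)
        ev_cat.extend(cats_i)
        ev_set.extend(sets_i)

    events = pd.DataFrame(
        {
            "person_id": ev_pid,
            "date": pd.to_datetime(start) + pd.to_timedelta(ev_day, unit="D"),
            "code": ev_cat,
            "setting": ev_set,
        }
    ).sort_values(["person_id", "date", "code", "setting"], kind="stable")
    events = events.reset_index(drop=True)
    registry = pd.DataFrame(
        reg_rows,
        columns=["person_id", "birth_year", "sex", "is_case", "index_date", "match_id"],
    )
    registry["index_date"] = pd.to_datetime(registry["index_date"])
    return events, registry


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    age_band: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """1:1 match controls to cases on sex, index year and year of age.

    Sampling is without replacement within each eligibility stratum. Cases
    whose stratum is exhausted are reported in the returned unmatched list,
    never silently dropped.

    Returns (matched registry of cases + their controls with match_id set,
    list of unmatched case person_ids).
    """
    rng = np.random.default_rng(seed)
    pool = pool.copy()
    pool["_year"] = pd.to_datetime(pool["index_date"]).dt.year
    cases = cases.copy()
    cases["_year"] = pd.to_datetime(cases["index_date"]).dt.year
    used: set[str] = set()
    rows: list[pd.Series] = []
    unmatched: list[str] = []
    for _, case in cases.sort_values("person_id").iterrows():
        elig = pool[
            (pool["sex"] == case["sex"])
            & (pool["_year"] == case["_year"])
            & (pool["birth_year"].sub(case["birth_year"]).abs() <= age_band)
            & (~pool["person_id"].isin(used))
        ]
        crow = case.drop(labels=["_year"]).copy()
        crow["match_id"] = case["person_id"]
        if len(elig) == 0:
            unmatched.append(case["person_id"])
            continue
        pick = elig.iloc[int(rng.integers(len(elig)))]
        used.add(pick["person_id"])
        prow = pick.drop(labels=["_year"]).copy()
        prow["match_id"] = case["person_id"]
        rows.append(crow)
        rows.append(prow)
    matched = (
        pd.DataFrame(rows).reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=list(cases.columns.drop("_year")) + ["match_id"])
    )
    return matched, unmatched


def split_train_test(
    registry: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Split matched case-control PAIRS into train / test person-id lists.

    The pair (shared match_id) is the unit of assignment, so both members
    always land in the same split. The train pair count is the target
    fraction rounded to the nearest integer, ties toward train.
    """
    pairs = sorted(registry["match_id"].unique())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    n_train = math.floor(len(pairs) * train_fraction + 0.5)
    train_pairs = {pairs[i] for i in perm[:n_train]}
    train_ids = sorted(
        registry.loc[registry["match_id"].isin(train_pairs), "person_id"]
    )
    test_ids = sorted(
        registry.loc[~registry["match_id"].isin(train_pairs), "person_id"]
    )
    return train_ids, test_ids


def write_cohort(events: pd.DataFrame, registry: pd.DataFrame, out_dir: str | Path) -> None:
    """Write events.csv and registry.csv with ISO-8601 dates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"]).dt.strftime("%Y-%m-%d")
    ev.to_csv(out / "events.csv", index=False)
    reg = registry.copy()
    reg["index_date"] = pd.to_datetime(reg["index_date"]).dt.strftime("%Y-%m-%d")
    reg.to_csv(out / "registry.csv", index=False)


def read_cohort(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read events.csv and registry.csv as written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    events = pd.read_csv(in_dir / "events.csv", parse_dates=["date"])
    registry = pd.read_csv(in_dir / "registry.csv", parse_dates=["index_date"])
    return events, registry
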