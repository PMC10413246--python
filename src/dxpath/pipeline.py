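"""End-to-end runner: simulate/load → preprocess → screen → featurize →
model → trees & network, with a manifest for reproducibility.

The four study stages are (1) data preprocessing, (2) pathway selection,
(3) model construction and optimisation, (4) visualisation. Each stage logs
its in/out counts so the funnel (triplets supported → screened → features →
selected) is auditable, and the manifest records content hashes of every
artifact plus the seed, so identical (config, inputs, seed) reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .features import assign_features, build_vocabulary, write_feature_matrix
from .models import (
    evaluate,
    lasso_select,
    restrict_matrix,
    select_final,
    train_classifier,
)
from .preprocessing import build_timelines, count_support, read_mapping
from .screening import screen_support_table, select_pathways
from .simulate import SimConfig, generate_cohort, split_train_test, write_cohort
from .trees import (
    build_temporal_network,
    build_trees,
    cumulative_coverage,
    export_graph,
    pathways_from_final_model,
    rank_forest,
    retain_parents,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run.

    Defaults mirror the study thresholds: validation needs 3 outpatient
    claims within 365 days (or one admission), triplets need support in >=10
    cases, screening keeps OR>1 with p<.05, 2/3 of pairs train, models use
    3-fold CV, trees keep the top 5 children per parent, and network edges
    need >=50 covering cases.
    """

    out_dir: str = "dxpath_run"
    seed: int = 0
    # input: either simulate, or point at events/registry CSVs
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    events_path: str | None = None
    registry_path: str | None = None
    ccs_mapping_path: str | None = None
    exclude_categories: list[str] = field(default_factory=list)
    # preprocessing
    window_days: int = 365
    min_outpatient: int = 3
    min_case_support: int = 10
    # screening
    alpha: float = 0.05
    # split & models
    train_fraction: float = 2.0 / 3.0
    cv_folds: int = 3
    selection_methods: list[str] = field(default_factory=lambda: ["one_model", "by_group"])
    classifiers: list[str] = field(default_factory=lambda: ["svm", "random_forest"])
    feature_mode: str = "selected"
    # visualisation
    top_children: int = 5
    min_edge_cases: int = 50
    coverage_epsilon: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.min_case_support < 1 or self.cv_folds < 2:
            raise ValueError("min_case_support >= 1 and cv_folds >= 2 required")
        if self.top_children < 1 or self.min_edge_cases < 0:
            raise ValueError("top_children >= 1 and min_edge_cases >= 0 required")
        # canonicalise sim overrides to YAML-native types so the config
        # round-trips through serialize/parse unchanged
        pws = self.sim.get("planted_pathways")
        if pws is not None:
            self.sim["planted_pathways"] = [
                [list(p[0]), float(p[1]), float(p[2])]
                for p in (
                    (pw.categories, pw.p_case, pw.p_control)
                    if hasattr(pw, "categories")
                    else pw
                    for pw in pws
                )
            ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(cfg: RunConfig) -> SimConfig:
    kwargs = dict(cfg.sim)
    kwargs.setdefault("seed", cfg.seed)
    return SimConfig(**kwargs)


@dataclass
class RunResult:
    """Paths and key outputs of a pipeline run."""

    out_dir: Path
    status: str
    manifest: dict
    reports: list = field(default_factory=list)
    final_report: object | None = None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order, writing artifacts + manifest to out_dir.

    Halts cleanly (status explains where) if screening selects no pathway;
    partial outputs are retained. Re-running with identical config, inputs
    and seed reproduces identical stage outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "files": {},
    }

    # stage 1a: inputs
    if config.simulate:
        events, registry = generate_cohort(_sim_config(config))
        write_cohort(events, registry, out)
    else:
        if not (config.events_path and config.registry_path):
            raise ValueError("events_path and registry_path required when simulate=false")
        events = pd.read_csv(config.events_path, parse_dates=["date"])
        registry = pd.read_csv(config.registry_path, parse_dates=["index_date"])
    manifest["stages"]["inputs"] = {
        "n_events": int(len(events)),
        "n_persons": int(len(registry)),
        "n_cases": int(registry["is_case"].sum()),
    }
    logger.info("inputs: %d events, %d persons", len(events), len(registry))

    mapping = read_mapping(config.ccs_mapping_path) if config.ccs_mapping_path else None

    # stage 1b: preprocessing
    timelines = build_timelines(
        events,
        registry,
        mapping=mapping,
        window_days=config.window_days,
        min_outpatient=config.min_outpatient,
        exclude_categories=set(config.exclude_categories),
    )
    tl_by_id = {tl.person_id: tl for tl in timelines}
    train_ids, test_ids = split_train_test(registry, config.train_fraction, seed=config.seed)
    train_tl = [tl_by_id[p] for p in train_ids]
    test_tl = [tl_by_id[p] for p in test_ids]
    support = count_support(train_tl, min_case_support=config.min_case_support)
    support.to_csv(out / "triplet_support.csv", index=False)
    manifest["stages"]["preprocessing"] = {
        "n_train_persons": len(train_ids),
        "n_test_persons": len(test_ids),
        "n_supported_triplets": int(len(support)),
    }
    logger.info("preprocessing: %d supported triplets (train)", len(support))

    # stage 2: screening
    screened = screen_support_table(support, alpha=config.alpha)
    screened.to_csv(out / "screened.csv", index=False)
    selected_triplets = select_pathways(screened, alpha=config.alpha)
    manifest["stages"]["screening"] = {"n_selected_triplets": len(selected_triplets)}
    logger.info("screening: %d positively associated triplets", len(selected_triplets))
    if not selected_triplets:
        msg = "no pathway passed screening (OR>1, p<alpha); pipeline stopped"
        logger.warning(msg)
        manifest["status"] = msg
        _finalise(out, manifest)
        return RunResult(out_dir=out, status=msg, manifest=manifest)

    # stage 3: features + models
    vocab = build_vocabulary(selected_triplets)
    fm_train = assign_features(train_tl, selected_triplets, vocab, mode=config.feature_mode)
    fm_test = assign_features(test_tl, selected_triplets, vocab, mode=config.feature_mode)
    write_feature_matrix(fm_train, out / "features_train")
    manifest["stages"]["features"] = {"n_features": len(vocab)}
    logger.info("features: %d corresponding features", len(vocab))

    reports = []
    selections = {}
    for method in config.selection_methods:
        sel = lasso_select(fm_train, mode=method, cv_folds=config.cv_folds, seed=config.seed)
        selections[method] = sel
        Xtr, kept = restrict_matrix(fm_train, sel.selected)
        Xte, _ = restrict_matrix(fm_test, sel.selected)
        for kind in config.classifiers:
            clf, cv_summary = train_classifier(
                Xtr, fm_train.y, kind=kind, cv_folds=config.cv_folds, seed=config.seed
            )
            report = evaluate(
                clf, Xte, fm_test.y,
                feature_selection=method, classifier=kind, n_features=len(kept),
            )
            reports.append(report)
            logger.info(
                "model %s + %s: sensitivity %.3f, AUC %.3f (%d features)",
                method, kind, report.sensitivity, report.auc, len(kept),
            )
    final = select_final(reports)
    comparison = pd.DataFrame([r.to_dict() for r in reports])
    comparison.to_csv(out / "model_comparison.csv", index=False)
    (out / "final_model.json").write_text(json.dumps(final.to_dict(), indent=2))
    manifest["stages"]["models"] = {
        "n_models": len(reports),
        "final": {"feature_selection": final.feature_selection, "classifier": final.classifier},
        "selected_per_method": {m: s.n_selected for m, s in selections.items()},
    }

    # stage 4: trees & network
    final_sel = selections[final.feature_selection]
    final_triplets = pathways_from_final_model(final_sel.selected, vocab)
    forest = build_trees(final_triplets, test_tl)
    case_ids = {tl.person_id for tl in test_tl if tl.is_case}
    coverage = cumulative_coverage(forest, case_ids, epsilon=config.coverage_epsilon)
    retained = retain_parents(forest, coverage)
    retained = rank_forest(retained, k=config.top_children)
    network = build_temporal_network(retained, min_cases=config.min_edge_cases)
    export_graph(retained, "json", out / "disease_trees.json")
    export_graph(coverage, "csv", out / "coverage_curve.csv")
    export_graph(network, "graphml", out / "temporal_network.graphml")
    export_graph(network, "dot", out / "temporal_network.dot")
    manifest["stages"]["visualization"] = {
        "n_final_triplets": len(final_triplets),
        "n_parents": len(forest),
        "chosen_parents": coverage.chosen_count,
        "n_network_edges": network.number_of_edges(),
    }
    logger.info(
        "trees: %d parents, %d chosen; network: %d edges",
        len(forest), coverage.chosen_count, network.number_of_edges(),
    )

    manifest["status"] = "complete"
    _finalise(out, manifest)
    return RunResult(
        out_dir=out, status="complete", manifest=manifest,
        reports=reports, final_report=final,
    )


def _finalise(out: Path, manifest: dict) -> None:
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
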