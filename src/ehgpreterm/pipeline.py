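"""Pipeline orchestration: extract -> select -> evaluate, with manifests.

Each stage writes its outputs plus a JSON manifest capturing every
parameter and seed, so a rerun with the same manifest reproduces the
outputs bit-exactly.  The leak audit accumulated across a run is written
alongside the evaluation outputs and must report zero violations.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

from .classify_eval import (
    ClassifierSpec,
    EvaluationSummary,
    average_boundary_2d,
    average_roc,
    average_threshold_1d,
    repeated_evaluation,
)
from .errors import EHGError
from .feature_selection import (
    FeatureSetDef,
    SelectionResult,
    build_feature_set,
    stabilized_selection,
    tally_top2,
)
from .records_io import (
    FeatureTable,
    RecordCollection,
    collection_feature_table,
    load_dataset,
    read_feature_table,
    write_feature_table,
)
from .resampling import LeakAudit, plans_from_json, plans_to_json, stratified_holdout
from .spectral_features import ExtractionConfig, extract_feature_vector
from .util import child_seed

log = logging.getLogger("ehgpreterm")


def _write_manifest(path: Path, stage: str, params: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"stage": stage, "params": params}, indent=1, default=str))


def extract_table(
    collection: RecordCollection,
    feature_set: FeatureSetDef | Sequence,
    config: ExtractionConfig | None = None,
    on_error: str = "raise",
) -> FeatureTable:
    """One row per record, one column per feature spec."""
    specs = feature_set.specs if isinstance(feature_set, FeatureSetDef) else list(feature_set)
    values = {}
    skipped = 0
    for rec in collection:
        try:
            values[rec.record_id] = extract_feature_vector(rec, specs, config)
        except EHGError:
            if on_error == "raise":
                raise
            skipped += 1
            log.warning("skipping record %s after extraction failure", rec.record_id)
    if skipped:
        log.warning("extraction skipped %d record(s)", skipped)
    kept = RecordCollection(records=[r for r in collection if r.record_id in values])
    return collection_feature_table(kept, values)


def run_extract(
    records_dir: str | Path,
    out_csv: str | Path,
    feature_set: str = "set1",
    trim_s: float = 15.0,
    se_decimate: bool = False,
    later_threshold: float = 26.0,
) -> FeatureTable:
    collection = load_dataset([records_dir], later_threshold=later_threshold)
    config = ExtractionConfig(trim_s=trim_s, se_decimate=se_decimate)
    table = extract_table(collection, build_feature_set(feature_set), config)
    write_feature_table(table, out_csv)
    _write_manifest(
        Path(out_csv).with_suffix(".manifest.json"),
        "extract",
        {
            "records_dir": str(records_dir),
            "feature_set": feature_set,
            "trim_s": trim_s,
            "se_decimate": se_decimate,
            "later_threshold": later_threshold,
        },
    )
    return table


def _histogram_figure(path: Path, res: SelectionResult) -> None:
    """Occurrence histogram ranked by count; top-two bars highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = res.ranked_features()
    counts = [res.histogram.counts.get(n, 0) for n in ranked]
    colors = ["black", "black"] + ["steelblue"] * (len(ranked) - 2)
    fig, ax = plt.subplots(figsize=(max(6, len(ranked) * 0.25), 3.5))
    ax.bar(range(len(ranked)), counts, color=colors)
    ax.set_xticks(range(len(ranked)))
    ax.set_xticklabels(ranked, rotation=90, fontsize=6)
    ax.set_ylabel("occurrences")
    ax.set_title(
        f"{res.classifier.display_name} / {res.feature_set}: "
        f"{res.m_final} features selected"
    )
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_select(
    table_csv: str | Path,
    out_dir: str | Path,
    classifiers: Sequence[str] = ("lda_pseudo", "qda_pseudo", "gnb_empirical", "svm_poly3", "svm_rbf"),
    feature_sets: Sequence[str] = ("set1", "set2", "set3", "set4"),
    n_reps: int = 200,
    seed: int = 0,
) -> tuple[list[SelectionResult], tuple[str, str]]:
    """Stabilized selection per (classifier x set); writes histograms, the
    top-two tally, and the per-repetition partition plans for reuse."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(table_csv).canonical()
    audit = LeakAudit()
    results = []
    plans = None
    for kind in classifiers:
        for set_name in feature_sets:
            fset = build_feature_set(set_name)
            missing = [n for n in fset.names if n not in table.feature_names]
            if missing:
                raise EHGError(
                    f"feature table lacks columns for {set_name}: {missing[:3]}..."
                )
            res = stabilized_selection(
                table,
                ClassifierSpec(kind),
                fset,
                n_reps=n_reps,
                base_seed=seed,  # same base seed -> identical partitions per rep
                audit=audit,
            )
            results.append(res)
            if plans is None:
                plans = res.plans
            payload = {
                "classifier": kind,
                "feature_set": set_name,
                "counts": res.histogram.counts,
                "average_mce_curve": res.histogram.average_mce_curve.tolist(),
                "m_final": res.m_final,
                "final_subset": list(res.final_subset),
                "per_run_k_min": [r.k_min for r in res.per_run],
            }
            (out_dir / f"selection_{kind}_{set_name}.json").write_text(
                json.dumps(payload, indent=1)
            )
            _histogram_figure(out_dir / f"selection_{kind}_{set_name}.png", res)
    tally, (feat_a, feat_b) = tally_top2(results)
    (out_dir / "top2_tally.json").write_text(
        json.dumps(
            {
                "first_place": tally.first_place,
                "second_place": tally.second_place,
                "n_runs": tally.n_runs,
                "feature_A": feat_a,
                "feature_B": feat_b,
            },
            indent=1,
        )
    )
    plans_to_json(plans, out_dir / "partition_plans.json")
    (out_dir / "leak_audit.json").write_text(
        json.dumps({"checked": audit.checked, "violations": audit.violations}, indent=1)
    )
    _write_manifest(
        out_dir / "select.manifest.json",
        "select",
        {
            "table": str(table_csv),
            "classifiers": list(classifiers),
            "feature_sets": list(feature_sets),
            "n_reps": n_reps,
            "seed": seed,
        },
    )
    if not audit.clean:
        raise EHGError(f"leak audit failed: {audit.violations} violation(s)")
    return results, (feat_a, feat_b)


def _evaluation_figures(out_dir, table, features, summaries, boundary) -> None:
    """Average ROC curves plus the feature scatter with decision boundary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for kind, summ in summaries.items():
        if not summ.test_curves:
            continue
        avg = average_roc(summ.test_curves)
        ax.errorbar(
            avg.grid[::10], avg.mean_se[::10], yerr=avg.sd_se[::10],
            label=summ.spec.display_name, capsize=2,
        )
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - Sp (false positive rate)")
    ax.set_ylabel("Se (true positive rate)")
    ax.legend(fontsize=8)
    fig.savefig(out_dir / "average_roc.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    y = table.y
    x0 = table.values[features[0]]
    x1 = table.values[features[1]] if len(features) > 1 else table.labels * 0
    ax.scatter(x0[y == 0], x1[y == 0], s=12, c="seagreen", label="term")
    ax.scatter(x0[y == 1], x1[y == 1], s=12, c="firebrick", label="premature")
    if boundary.mode == "threshold_1d" and boundary.threshold is not None:
        ax.axvline(boundary.threshold, color="saddlebrown", label="avg threshold")
    else:
        for c in boundary.contours:
            ax.plot(c[:, 0], c[:, 1], "b-", lw=1.2)
    ax.set_xlabel(features[0])
    ax.set_ylabel(features[1] if len(features) > 1 else "")
    ax.legend(fontsize=8)
    fig.savefig(out_dir / "decision_boundary.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_evaluate(
    table_csv: str | Path,
    out_dir: str | Path,
    features: Sequence[str],
    classifiers: Sequence[str] = ("lda_pseudo", "qda_pseudo", "gnb_empirical", "svm_poly3", "svm_rbf"),
    plans_json: str | Path | None = None,
    n_reps: int = 200,
    seed: int = 0,
) -> dict[str, EvaluationSummary]:
    """Tables-style summary + averaged ROC (+ 1-D threshold for one feature)."""
    if len(features) not in (1, 2):
        raise EHGError("evaluation uses one or two features")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(table_csv).canonical()
    if plans_json is not None:
        plans = plans_from_json(plans_json)[:n_reps]
    else:
        plans = [
            stratified_holdout(table, seed=child_seed(seed, i), repetition_index=i)
            for i in range(1, n_reps + 1)
        ]
    audit = LeakAudit()
    summaries: dict[str, EvaluationSummary] = {}
    rows = []
    for kind in classifiers:
        summ = repeated_evaluation(
            table, features, ClassifierSpec(kind), plans, base_seed=seed, audit=audit
        )
        summaries[kind] = summ
        avg = average_roc(summ.test_curves) if summ.test_curves else None
        payload = {
            "classifier": kind,
            "features": list(features),
            "test": {m: list(v) for m, v in summ.test_summary.items()},
            "train": {m: list(v) for m, v in summ.train_summary.items()},
            "average_roc": None
            if avg is None
            else {
                "fpr": avg.grid.tolist(),
                "mean_se": avg.mean_se.tolist(),
                "sd_se": avg.sd_se.tolist(),
            },
        }
        (out_dir / f"evaluation_{kind}.json").write_text(json.dumps(payload, indent=1))
        rows.append(summ.table_row())
    models = [m for s in summaries.values() for m in s.models]
    if len(features) == 1:
        col = table.values[features[0]]
        art = average_threshold_1d(models, float(col.min()), float(col.max()))
        (out_dir / "threshold_1d.json").write_text(
            json.dumps(
                {
                    "feature": features[0],
                    "threshold": art.threshold,
                    "n_models": art.n_models,
                    "n_skipped": art.n_skipped,
                },
                indent=1,
            )
        )
    else:
        cx, cy = (table.values[f] for f in features)
        pad = lambda c: 0.1 * (c.max() - c.min() or 1.0)  # noqa: E731
        art = average_boundary_2d(
            models,
            (float(cx.min() - pad(cx)), float(cx.max() + pad(cx))),
            (float(cy.min() - pad(cy)), float(cy.max() + pad(cy))),
        )
        (out_dir / "boundary_2d.json").write_text(
            json.dumps(
                {
                    "features": list(features),
                    "grid_x": art.grid_x.tolist(),
                    "grid_y": art.grid_y.tolist(),
                    "contours": [c.tolist() for c in art.contours],
                },
                indent=1,
            )
        )
    _evaluation_figures(out_dir, table, features, summaries, art)
    import pandas as pd

    pd.DataFrame(rows).to_csv(out_dir / "summary_table.csv", index=False)
    (out_dir / "leak_audit.json").write_text(
        json.dumps({"checked": audit.checked, "violations": audit.violations}, indent=1)
    )
    _write_manifest(
        out_dir / "evaluate.manifest.json",
        "evaluate",
        {
            "table": str(table_csv),
            "features": list(features),
            "classifiers": list(classifiers),
            "plans": str(plans_json),
            "n_reps": n_reps,
            "seed": seed,
        },
    )
    if not audit.clean:
        raise EHGError(f"leak audit failed: {audit.violations} violation(s)")
    return summaries
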