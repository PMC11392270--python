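"""Scaled-down end-to-end experiments on synthetic data.

These functions run the full pipeline (generate -> extract -> select ->
evaluate) at desk scale: 200 records (40 premature / 160 term across the
four delivery-mode groups), 300 s per record, 10 repetitions per stabilized
selection, two fast classifiers (LDA, Gaussian naive Bayes) and the two
compact feature sets (set3, set4).  The Welch spectrum estimator and
entropy decimation are enabled to keep a replicate around a minute; the
methods note discusses these choices.

They exist so that parameter recovery, the no-false-discovery null check
and the leak audit can be exercised reproducibly from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify_eval import ClassifierSpec, repeated_evaluation
from .feature_selection import (
    build_feature_set,
    stabilized_selection,
    tally_top2,
)
from .pipeline import extract_table
from .records_io import FeatureTable, GroupLabel
from .resampling import LeakAudit, stratified_holdout
from .spectral_features import ExtractionConfig, FeatureSpec
from .synthetic_data import (
    ClassEffectParams,
    SyntheticConfig,
    generate_dataset,
    null_effects,
)
from .util import child_seed

#: the two features the generator plants its class effects on
PLANTED_A = "PA_S3_B0Lp"
PLANTED_B = "MF_S2_B3"

#: 40 premature vs 160 term records across the delivery-mode groups
RECOVERY_GROUP_SIZES = {
    GroupLabel.PL: 40,
    GroupLabel.TL: 108,
    GroupLabel.IL: 35,
    GroupLabel.CL: 7,
    GroupLabel.ICL: 10,
}

RECOVERY_DURATION_S = 300.0
RECOVERY_N_REPS = 10
RECOVERY_CLASSIFIERS = ("lda_pseudo", "gnb_empirical")
RECOVERY_FEATURE_SETS = ("set3", "set4")

_EXTRACTION = ExtractionConfig(se_decimate=True, estimator="welch", welch_nperseg=512)


def _recovery_table(seed: int, effects: ClassEffectParams, specs) -> FeatureTable:
    config = SyntheticConfig(
        group_sizes=dict(RECOVERY_GROUP_SIZES),
        duration_s=RECOVERY_DURATION_S,
        effects=effects,
        seed=seed,
    )
    return extract_table(generate_dataset(config), specs, _EXTRACTION)


@dataclass
class RecoveryReplicate:
    seed: int
    feature_a: str
    feature_b: str
    per_run_top2: list[tuple[str, str]]

    @property
    def recovered(self) -> bool:
        return (self.feature_a, self.feature_b) == (PLANTED_A, PLANTED_B)


@dataclass
class RecoveryResult:
    replicates: list[RecoveryReplicate]
    audit: LeakAudit = field(default_factory=LeakAudit)

    @property
    def recovery_rate(self) -> float:
        return sum(r.recovered for r in self.replicates) / len(self.replicates)


def recovery_experiment(
    seed: int,
    n_replicates: int = 10,
    effects: ClassEffectParams | None = None,
) -> RecoveryResult:
    """Planted-biomarker recovery across seeded replicate experiments.

    Each replicate draws a fresh 40/160 synthetic dataset, runs the
    stabilized selection for every (classifier x feature set) combination
    with 10 holdout repetitions, and tallies the top-two features.
    """
    effects = effects or ClassEffectParams()
    sets = [build_feature_set(n) for n in RECOVERY_FEATURE_SETS]
    union: dict[str, FeatureSpec] = {s.name: s for fs in sets for s in fs.specs}
    audit = LeakAudit()
    replicates = []
    for rep in range(n_replicates):
        rep_seed = child_seed(seed, 100 + rep)
        table = _recovery_table(rep_seed, effects, list(union.values()))
        results = []
        for kind in RECOVERY_CLASSIFIERS:
            for fset in sets:
                results.append(
                    stabilized_selection(
                        table,
                        ClassifierSpec(kind),
                        fset,
                        n_reps=RECOVERY_N_REPS,
                        base_seed=child_seed(rep_seed, 1),
                        audit=audit,
                    )
                )
        _, (a, b) = tally_top2(results)
        replicates.append(
            RecoveryReplicate(
                seed=rep_seed,
                feature_a=a,
                feature_b=b,
                per_run_top2=[r.top_two() for r in results],
            )
        )
    return RecoveryResult(replicates=replicates, audit=audit)


def null_auc_experiment(seed: int, n_reps: int = 10, n_datasets: int = 8) -> float:
    """Mean test AUC of the headline feature under the null configuration.

    With no planted class contrast the pipeline must not discover one: the
    expected mean test AUC is 0.5.  The mean is taken over several
    independent null datasets because a single 40/160 cohort's sample AUC
    fluctuates with a standard deviation of about 0.05.
    """
    specs = [FeatureSpec.from_name(PLANTED_A), FeatureSpec.from_name(PLANTED_B)]
    aucs = []
    for d in range(n_datasets):
        table = _recovery_table(child_seed(seed, 201, d), null_effects(), specs)
        plans = [
            stratified_holdout(
                table, seed=child_seed(seed, 202, d, i), repetition_index=i
            )
            for i in range(1, n_reps + 1)
        ]
        summary = repeated_evaluation(
            table,
            [PLANTED_A],
            ClassifierSpec("lda_pseudo"),
            plans,
            base_seed=child_seed(seed, 203, d),
        )
        aucs.append(summary.test_summary["AUC"][0])
    return float(np.mean(aucs))


@dataclass
class LeakageResult:
    checked: int
    violations: int
    planted_auc: float


def leakage_experiment(seed: int) -> LeakageResult:
    """Full select + evaluate run with the provenance audit switched on.

    Returns the number of synthetic samples audited, the number whose
    parents fell outside the active training partition or fold (must be 0),
    and the planted single-feature test AUC as a side product.
    """
    fset = build_feature_set("set4")
    table = _recovery_table(child_seed(seed, 301), ClassEffectParams(), fset.specs)
    audit = LeakAudit()
    result = stabilized_selection(
        table,
        ClassifierSpec("lda_pseudo"),
        fset,
        n_reps=RECOVERY_N_REPS,
        base_seed=child_seed(seed, 302),
        audit=audit,
    )
    summary = repeated_evaluation(
        table,
        [PLANTED_A],
        ClassifierSpec("lda_pseudo"),
        result.plans,
        base_seed=child_seed(seed, 303),
        audit=audit,
    )
    return LeakageResult(
        checked=audit.checked,
        violations=audit.violations,
        planted_auc=summary.test_summary["AUC"][0],
    )
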