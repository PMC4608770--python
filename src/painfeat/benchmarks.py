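"""Seeded end-to-end benchmark runs used by the reproduction harness.

These helpers run the complete chain (simulate -> preprocess -> extract ->
z-normalize -> select -> grid-search -> evaluate) on reduced problem sizes
(10 subjects per run, two-class tasks restricted to the classes they need)
so that the full sweep stays at desk scale.
"""

from __future__ import annotations

import numpy as np

from painfeat.classify import PainClassificationTask, SplitSpec
from painfeat.pipeline import PipelineConfig, build_feature_matrix
from painfeat.simulate import SimConfig


def _run_seed(seed: int) -> int:
    # keep derived seeds well below 2**31
    return int(seed) % 1_000_000


def paired_task_run(seed: int, n_subjects: int = 10) -> dict:
    """B-vs-T4 and B-vs-T1 on one simulated dataset (default effect sizes)."""
    s = _run_seed(seed)
    cfg = PipelineConfig(sim=SimConfig(n_subjects=n_subjects, rng_seed=s),
                         keep_classes=("B", "T1", "T4"))
    matrix = build_feature_matrix(cfg)
    out: dict = {"seed": s}
    for task in ("B_vs_T4", "B_vs_T1"):
        res = PainClassificationTask(matrix, task,
                                     split=SplitSpec(rng_seed=s)).fit()
        out[task] = {
            "accuracy": res.report.accuracy,
            "cramers_v": res.report.cramers_v,
            "n_selected": len(res.report.selected_features),
            "selected": res.report.selected_features,
            "trace_accuracies": [a for _, _, a in res.selection.forward_trace],
        }
    return out


def paired_task_sweep(base_seed: int, n_seeds: int = 10,
                      n_subjects: int = 10) -> list[dict]:
    """The two-class difficulty-ordering sweep over independent seeds."""
    return [paired_task_run(base_seed * 101 + i, n_subjects=n_subjects)
            for i in range(n_seeds)]


def zero_effect_config(seed: int, n_subjects: int = 10) -> SimConfig:
    """Simulation with all stimulus effect sizes set to zero.

    Spontaneous (label-independent) activity stays on, so the recordings
    are not degenerate — there is simply nothing for a classifier to find.
    """
    return SimConfig(
        n_subjects=n_subjects,
        rng_seed=_run_seed(seed),
        emg_burst_gain=(1.0, 1.0, 1.0, 1.0),
        scl_phasic_amp=(0.0, 0.0, 0.0, 0.0),
        rr_shortening_ms=(0.0, 0.0, 0.0, 0.0),
    )


def zero_effect_run(seed: int, n_subjects: int = 10) -> dict:
    """B-vs-T4 on a zero-effect dataset; returns accuracy and confusion."""
    s = _run_seed(seed)
    cfg = PipelineConfig(sim=zero_effect_config(s, n_subjects),
                         keep_classes=("B", "T4"))
    matrix = build_feature_matrix(cfg)
    res = PainClassificationTask(matrix, "B_vs_T4",
                                 split=SplitSpec(rng_seed=s)).fit()
    return {"seed": s,
            "accuracy": res.report.accuracy,
            "cramers_v": res.report.cramers_v,
            "confusion": res.report.confusion.to_numpy().tolist()}


def zero_effect_sweep(base_seed: int, n_seeds: int = 5,
                      n_subjects: int = 10) -> dict:
    """Pooled zero-effect null: mean accuracy and pooled-confusion Cramer's V.

    Cramer's V is evaluated on the confusion matrix pooled over seeds: the
    per-seed test sets are small enough that estimator bias (V ~ 1/sqrt(n)
    under independence) would dominate a per-seed value.
    """
    from painfeat.classify import cramers_v

    runs = [zero_effect_run(base_seed * 211 + i, n_subjects=n_subjects)
            for i in range(n_seeds)]
    pooled = np.sum([np.asarray(r["confusion"]) for r in runs], axis=0)
    v, band = cramers_v(pooled)
    return {"runs": runs,
            "mean_accuracy": float(np.mean([r["accuracy"] for r in runs])),
            "pooled_cramers_v": v,
            "band": band}
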