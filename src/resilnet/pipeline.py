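"""End-to-end pipeline: cohort -> resilience scores -> per-group networks ->
connectivity comparison -> permutation network test -> descriptive tables.

Every stage receives its settings from one :class:`PipelineConfig`; the
resolved config and a machine-readable run log are written next to the
outputs. A single global seed is split deterministically into per-stage
seeds, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .connectivity import connectivity_metrics
from .groupstats import ttest_with_d, wilcoxon_items
from .nct import nct_global_strength
from .netest import (
    EBICGraphicalLasso,
    NetworkModel,
    ebic_consistent_threshold,
    unregularized_pcor,
)
from .preprocess import preprocess_design
from .resilience import ResilienceScorer
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


@dataclass
class PipelineConfig:
    """All settings of one pipeline run."""

    output_dir: str = "run"
    input_dir: str | None = None          # read a cohort instead of simulating
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # preprocessing
    normalize: str = "rank-inverse-normal"
    standardize_x: bool = False
    # resilience scoring
    n_components: int = 1
    n_perm: int = 1000
    # per-group network estimation
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    threshold: bool = True
    corr_method: str = "polychoric"
    # which variant feeds the connectivity comparison:
    # "selected" follows the threshold flag; "unthresholded" and
    # "unregularized" are the robustness variants
    connectivity_variant: str = "selected"
    # connectivity
    distance_convention: str = "inverse_abs"
    pairs: str = "unordered"
    # network comparison test
    nct_iterations: int = 1000
    nct_corr_method: str = "pearson"
    nct_n_lambda: int = 20
    nct_threshold: bool = False
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.nct_iterations < 1:
            raise ValueError("nct_iterations must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.connectivity_variant not in (
            "selected", "unthresholded", "unregularized"
        ):
            raise ValueError(
                f"unknown connectivity_variant {self.connectivity_variant!r}"
            )
        if self.input_dir is None:
            self.synthetic.validate()
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(**d)
        if syn is not None:
            syn = dict(syn)
            for key in ("precision_high", "precision_low"):
                if key in syn:
                    syn[key] = np.asarray(syn[key], float)
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("output_dir")     # location metadata, not an analysis setting
        syn = d["synthetic"]
        for key in ("precision_high", "precision_low"):
            syn[key] = np.asarray(syn[key]).tolist()
        syn["thresholds"] = {k: list(map(float, v))
                             for k, v in syn["thresholds"].items()}
        return d


def _stage_seeds(seed: int) -> dict:
    s = np.random.SeedSequence(seed).generate_state(4) & 0x7FFFFFFF
    return {"synthetic": int(s[0]), "plsr_permutation": int(s[1]),
            "nct": int(s[2])}


def _json_dump(obj, path: Path):
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full chain; returns the run directory.

    Artifacts: cohort CSVs (when simulated), design matrices, per-subject
    scores with group labels, one network per group, a connectivity table,
    the permutation-test result with its full null distribution, the
    descriptive comparison table, and a run log.
    """
    try:
        config.validate()
    except ValueError as e:
        raise PipelineError("config", str(e)) from e
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)

    # --- cohort -----------------------------------------------------------
    try:
        if config.input_dir is not None:
            cohort = rio.read_cohort(config.input_dir)
        else:
            syn = dataclasses.replace(config.synthetic,
                                      seed=seeds["synthetic"])
            cohort = generate_cohort(syn)
            rio.write_cohort(cohort, out / "cohort")
    except (ValueError, OSError) as e:
        raise PipelineError("cohort", str(e)) from e

    # --- preprocessing ----------------------------------------------------
    try:
        design = preprocess_design(
            cohort, normalize=config.normalize,
            standardize_x=config.standardize_x,
        )
    except ValueError as e:
        raise PipelineError("preprocess", str(e)) from e
    pd.DataFrame(design.X, columns=list(design.x_names)).to_csv(
        out / "design_X.csv", index=False
    )
    pd.DataFrame(design.Y, columns=list(design.y_names)).to_csv(
        out / "design_Y.csv", index=False
    )
    _json_dump(design.residualization, out / "preprocess.json")

    # --- resilience scores ------------------------------------------------
    try:
        scorer = ResilienceScorer(n_components=config.n_components)
        scorer.fit(design.X, design.Y)
        perm = scorer.permutation_test(
            design.X, design.Y, n_perm=config.n_perm,
            random_state=seeds["plsr_permutation"],
        )
    except ValueError as e:
        raise PipelineError("resilience", str(e)) from e
    scores = pd.DataFrame({
        "subject_id": np.arange(1, cohort.n_subjects + 1),
        "score": scorer.score_,
        "group": scorer.group_,
    })
    scores.to_csv(out / "scores.csv", index=False)
    _json_dump({
        "r2_total": scorer.r2_,
        "permutation_p": perm.p_value,
        "n_perm": perm.n_perm,
        "null_r2": perm.null_stats.tolist(),
        "n_high": scorer.n_high_,
        "n_low": scorer.n_low_,
    }, out / "plsr.json")

    high = scorer.group_ == "high"
    k_items = cohort.gse.shape[1]
    if min(scorer.n_high_, scorer.n_low_) <= k_items:
        raise PipelineError(
            "split", f"a group has <= {k_items} subjects; network "
            "estimation is not meaningful"
        )

    # --- per-group networks (all three variants written) ------------------
    nets = {}       # variant used for the connectivity comparison
    nets_all = {}
    pd_repaired = {}
    for label, mask in (("high", high), ("low", ~high)):
        try:
            est = EBICGraphicalLasso(
                gamma=config.gamma, n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio,
                threshold=False, corr_method=config.corr_method,
            ).fit(cohort.gse[mask])
            raw = est.get_network()
            thr = dataclasses.replace(
                raw, weights=raw.weights.copy(),
                settings={**raw.settings, "thresholded": True},
            )
            cut = ebic_consistent_threshold(raw.weights.shape[0], raw.n)
            thr.weights[np.abs(thr.weights) < cut] = 0.0
            unreg = NetworkModel(
                weights=unregularized_pcor(est.correlation_),
                precision=np.linalg.inv(est.correlation_),
                lambda_selected=0.0, ebic=float("nan"), gamma=config.gamma,
                lambda_path=np.array([]), ebic_path=np.array([]),
                n=raw.n,
                settings={"regularized": False, "thresholded": False,
                          "corr_method": config.corr_method},
            )
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as e:
            raise PipelineError(f"network[{label}]", str(e)) from e
        pd_repaired[label] = bool(est.pd_repaired_)
        nets_all[label] = {"unthresholded": raw, "thresholded": thr,
                           "unregularized": unreg}
        for vname, net in nets_all[label].items():
            rio.write_network(net, out / "networks",
                              f"network_{label}_{vname}")
        variant = config.connectivity_variant
        if variant == "selected":
            variant = "thresholded" if config.threshold else "unthresholded"
        nets[label] = nets_all[label][variant]

    # --- connectivity -----------------------------------------------------
    conn = {}
    for label, net in nets.items():
        try:
            conn[label] = connectivity_metrics(
                net.weights, convention=config.distance_convention,
                pairs=config.pairs,
            )
        except ValueError as e:
            raise PipelineError(f"connectivity[{label}]", str(e)) from e
    _json_dump({g: c.as_dict() for g, c in conn.items()},
               out / "connectivity.json")
    table2 = pd.DataFrame({
        "measure": ["strength", "expected_influence", "shortest_path_length"],
        "high": [conn["high"].avg_strength,
                 conn["high"].avg_expected_influence,
                 conn["high"].avg_shortest_path_length],
        "low": [conn["low"].avg_strength,
                conn["low"].avg_expected_influence,
                conn["low"].avg_shortest_path_length],
    })
    table2.to_csv(out / "table2_connectivity.csv", index=False)

    # --- network comparison test -----------------------------------------
    try:
        nct = nct_global_strength(
            cohort.gse[high], cohort.gse[~high],
            n_iterations=config.nct_iterations,
            random_state=seeds["nct"],
            corr_method=config.nct_corr_method,
            gamma=config.gamma,
            n_lambda=config.nct_n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            threshold=config.nct_threshold,
        )
    except (ValueError, RuntimeError) as e:
        raise PipelineError("nct", str(e)) from e
    _json_dump({
        "observed_diff": nct.observed_diff,
        "p_value": nct.p_value,
        "n_iterations": nct.n_iterations,
        "n_failed_iterations": nct.n_failed_iterations,
        "global_strength_high": nct.global_strength_a,
        "global_strength_low": nct.global_strength_b,
        "settings": nct.settings,
        "null_diffs": nct.null_diffs.tolist(),
    }, out / "nct.json")

    # --- descriptive comparisons (Table-1 style) --------------------------
    try:
        rows = [ttest_with_d(scorer.score_[high], scorer.score_[~high],
                             name="resilience_score")]
        for name, total in (
            ("dh_freq_sum", cohort.dh_freq.sum(axis=1)),
            ("dh_sev_sum", cohort.dh_sev.sum(axis=1)),
            ("le_sev_sum", cohort.le_sev.sum(axis=1)),
            ("age", cohort.age),
            ("gse_total", cohort.gse.sum(axis=1)),
        ):
            rows.append(ttest_with_d(total[high], total[~high], name=name))
        item_rows = wilcoxon_items(
            cohort.gse[high], cohort.gse[~high],
            item_names=list(rio.GSE_NODES),
        )
    except ValueError as e:
        raise PipelineError("groupstats", str(e)) from e
    table1 = pd.DataFrame([r.as_dict() for r in rows + item_rows])
    table1.to_csv(out / "table1_group_comparison.csv", index=False)

    # --- run log ----------------------------------------------------------
    _json_dump({
        "seeds": seeds,
        "n_subjects": cohort.n_subjects,
        "n_high": scorer.n_high_,
        "n_low": scorer.n_low_,
        "plsr_r2": scorer.r2_,
        "plsr_permutation_p": perm.p_value,
        "connectivity_variant": config.connectivity_variant,
        "lambda_high": nets["high"].lambda_selected,
        "lambda_low": nets["low"].lambda_selected,
        "edges_high": nets["high"].n_edges,
        "edges_low": nets["low"].n_edges,
        "nct_p": nct.p_value,
        "pd_repaired": pd_repaired,
    }, out / "run.json")
    return out
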