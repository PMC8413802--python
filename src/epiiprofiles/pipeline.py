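"""End-to-end analysis pipeline: score -> screen -> enumerate -> distal -> report.

Stages mirror the published workflow: dichotomize the EPII, score the
psychosocial battery, screen indicators (base rate, stress correlation),
enumerate latent class models with the fit-index battery, pick the
smallest-BIC solution, and compare classes on distal outcomes with
classification-error correction. Every stage logs its input/output
dimensions into a run record; a fixed master seed makes reruns
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, catalog, distal, screening, selection, tables
from .lca import StartPolicy
from .simulate import SyntheticConfig, generate_lca_data


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    input_path: str | None = None      # CSV in the wide survey schema
    simulate_n: int | None = None      # generate instead of reading
    base_rate_threshold: float = 0.05
    screening_alpha: float = 0.05
    screening_alternative: str = "greater"
    k_max: int = 7
    n_starts: int = 50
    max_iter: int = 1000
    tol: float = 1e-6
    bootstrap_B: int = 0
    family_alpha: float = 0.05
    seed: int = 0
    out_dir: str = "epii_run"

    def __post_init__(self):
        for name in ("base_rate_threshold", "screening_alpha", "family_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    @property
    def start_policy(self) -> StartPolicy:
        return StartPolicy(self.n_starts, self.max_iter, self.tol, self.seed)


@dataclass
class RunRecord:
    config: dict
    version: str = __version__
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def log(self, stage: str, **info):
        self.stages.append({"stage": stage, **info})


def load_or_simulate(config: RunConfig, record: RunRecord) -> pd.DataFrame:
    """Stage 0: read the wide survey CSV or generate a synthetic one."""
    if config.input_path is not None:
        df = pd.read_csv(config.input_path)
    elif config.simulate_n is not None:
        df = generate_lca_data(SyntheticConfig(n=config.simulate_n,
                                               seed=config.seed)).raw
    else:
        raise StageError("input", "neither input_path nor simulate_n given")
    record.log("input", rows=len(df), columns=len(df.columns))
    return df


def score_stage(df: pd.DataFrame, record: RunRecord):
    """Stage 1: dichotomize EPII items, domain counts, scale scores."""
    try:
        binary = catalog.dichotomize_responses(df)
        counts = catalog.domain_counts(binary)
        scores = catalog.score_scales(df)
    except (KeyError, ValueError) as exc:
        raise StageError("score", str(exc)) from exc
    record.log("score", items=binary.shape[1],
               nondisclosed_epii_cells=catalog.nondisclosure_count(df))
    return binary, counts, scores


def screen_stage(binary: pd.DataFrame, scores: pd.DataFrame,
                 config: RunConfig, record: RunRecord):
    """Stage 2: base-rate filter and stress-correlation screen."""
    report = screening.spearman_screen(
        binary, scores["pss_total"].to_numpy(),
        alpha=config.screening_alpha,
        alternative=config.screening_alternative,
        base_rate_threshold=config.base_rate_threshold)
    try:
        indicator_cols = screening.select_indicators(report)
    except ValueError as exc:
        raise StageError("screen", str(exc)) from exc
    record.log("screen", excluded=int(report["excluded_low_base_rate"].sum()),
               retained=len(indicator_cols))
    return report, indicator_cols


def enumerate_stage(Y: np.ndarray, config: RunConfig, record: RunRecord):
    """Stage 3: class enumeration with the fit-index battery."""
    try:
        enum = selection.class_enumeration(Y, config.k_max, config.start_policy,
                                           bootstrap_B=config.bootstrap_B)
    except RuntimeError as exc:
        raise StageError("enumerate", str(exc)) from exc
    record.log("enumerate", fitted=sorted(enum.fits), selected_K=enum.selected_K,
               stopped_early=enum.stopped_early)
    return enum


def distal_stage(enum: selection.EnumerationResult, outcomes: pd.DataFrame,
                 continuous: pd.DataFrame, config: RunConfig, record: RunRecord):
    """Stage 4: classification-error-corrected class comparisons."""
    fit = enum.selected
    K = fit.params.n_classes
    results: dict[str, distal.DistalEstimate] = {}
    if K < 2:
        record.log("distal", note="single-class solution; no comparisons")
        return results
    Q = distal.classification_error_matrix(fit.posteriors, fit.assignments)
    entropy = selection.relative_entropy(fit.posteriors)
    for col in outcomes.columns:
        results[col] = distal.dcat_categorical(
            outcomes[col].to_numpy(), fit.assignments, Q, fit.params.pi,
            family_alpha=config.family_alpha, entropy=entropy)
    for col in continuous.columns:
        results[col] = distal.du3step_continuous(
            continuous[col].to_numpy(), fit.assignments, Q, fit.params.pi,
            family_alpha=config.family_alpha, entropy=entropy)
    record.log("distal", outcomes=list(results), entropy=entropy)
    return results


def _fmt_pct(x):
    return "" if pd.isna(x) else f"{100 * x:.1f}"


def _fmt_prob(x):
    return "" if pd.isna(x) else f"{x:.2f}"


def significant_pairs_string(est: distal.DistalEstimate, direction_values) -> str:
    """Encode significant pairwise contrasts as e.g. ``C2>C1; C3>C5``."""
    if est.pairwise is None:
        return ""
    parts = []
    vals = np.asarray(direction_values, float)
    for _, row in est.pairwise[est.pairwise["significant"]].iterrows():
        a, b = int(row["class_a"]), int(row["class_b"])
        hi, lo = (a, b) if vals[a - 1] >= vals[b - 1] else (b, a)
        parts.append(f"C{hi}>C{lo}")
    return "; ".join(parts)


def write_report(out_dir, *, screening_report=None, enum=None,
                 distal_results=None, record=None,
                 catalog_table=None, indicator_ids=None) -> dict[str, Path]:
    """Write the table-shaped CSV bundle and the run record.

    Formatting follows survey-report conventions: percentages to one
    decimal, probabilities to two decimals; deterministic column order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cat = catalog_table if catalog_table is not None else tables.epii_items()

    if screening_report is not None:
        rep = screening_report.copy()
        rep.insert(0, "item", rep.index)
        items = [int(c[4:]) if isinstance(c, str) and c.startswith("EPII") else c
                 for c in rep["item"]]
        rep["domain"] = [cat.at[i, "domain"] if i in cat.index else "" for i in items]
        rep["base_rate_pct"] = rep.pop("base_rate").map(_fmt_pct)
        cols = ["item", "domain", "base_rate_pct", "rho", "p_value",
                "excluded_low_base_rate", "retained_indicator"]
        rep = rep[[c for c in cols if c in rep.columns]]
        paths["screening"] = out / "screening_table.csv"
        rep.to_csv(paths["screening"], index=False, float_format="%.4f")

    if enum is not None:
        tab = enum.table.reset_index()
        cols = ["K", "d", "LL", "BIC", "SABIC", "CAIC", "AWE", "blrt_p",
                "naive_LR", "entropy", "BF_vs_next", "cmP", "unique", "selected"]
        tab = tab[[c for c in cols if c in tab.columns]]
        paths["fit"] = out / "fit_table.csv"
        tab.to_csv(paths["fit"], index=False, float_format="%.3f")

        fit = enum.selected
        if fit.params.n_classes > 1:
            post = selection.avg_posterior_table(fit.posteriors, fit.assignments)
            paths["posteriors"] = out / "avg_posterior_table.csv"
            post.to_csv(paths["posteriors"], float_format="%.3f")

        prof = pd.DataFrame(
            fit.params.rho,
            columns=[f"class{k}" for k in range(1, fit.params.n_classes + 1)])
        if fit.params.n_classes > 1:
            prof.insert(0, "univariate_entropy", [
                selection.univariate_entropy(fit.params, j)
                for j in range(fit.params.n_items)])
        prof = prof.map(_fmt_prob)
        if indicator_ids is not None:
            prof.insert(0, "item", list(indicator_ids))
        paths["profiles"] = out / "profile_table.csv"
        prof.to_csv(paths["profiles"], index=False)

    if distal_results:
        rows = []
        for name, est in distal_results.items():
            e = np.atleast_2d(est.estimates)
            binary_like = e.shape[0] > 1 and e.shape[1] == 2
            row = {"outcome": name}
            K = e.shape[0] if e.shape[0] > 1 else len(np.ravel(est.estimates))
            for k in range(1, K + 1):
                if binary_like:
                    row[f"class{k}"] = _fmt_prob(e[k - 1, 1])
                    row[f"class{k}_se"] = _fmt_prob(
                        np.atleast_2d(est.ses)[k - 1, 1])
                else:
                    row[f"class{k}"] = f"{np.ravel(est.estimates)[k - 1]:.2f}"
                    row[f"class{k}_se"] = f"{np.ravel(est.ses)[k - 1]:.2f}"
            row["chi2"] = "" if est.overall_stat is None else f"{est.overall_stat:.2f}"
            row["p"] = "" if est.overall_p is None else f"{est.overall_p:.4g}"
            direction = e[:, 1] if binary_like else np.ravel(est.estimates)
            row["significant_pairs"] = significant_pairs_string(est, direction)
            rows.append(row)
        paths["distal"] = out / "class_comparisons.csv"
        pd.DataFrame(rows).to_csv(paths["distal"], index=False)

    if record is not None:
        paths["record"] = out / "run_record.json"
        with open(paths["record"], "w") as fh:
            json.dump(asdict(record), fh, indent=2, default=_json_default)
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns a dict with the stage outputs (``binary``, ``scores``,
    ``screening``, ``enumeration``, ``distal``, ``paths``, ``record``).
    """
    record = RunRecord(config=asdict(config))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        df = load_or_simulate(config, record)
        binary, counts, scores = score_stage(df, record)
        report, indicator_cols = screen_stage(binary, scores, config, record)
        Y = binary[indicator_cols].to_numpy(float)
        enum = enumerate_stage(Y, config, record)

        screen_cols = [c for c in scores.columns
                       if c.startswith(("phq9_ge", "gad7_ge", "pcptsd_ge"))]
        outcomes = scores[screen_cols].astype("float").fillna(0).astype(int)
        demo_cols = [c for c in df.columns
                     if c in tables.distal_rates().index]
        if demo_cols:
            outcomes = pd.concat([outcomes, df[demo_cols]], axis=1)
        continuous = pd.concat(
            [scores[["pss_total", "ssq_total"]], counts[["adverse_total", "positive"]]],
            axis=1)
        distal_results = distal_stage(enum, outcomes, continuous, config, record)
    record.warnings = [str(w.message) for w in caught]
    paths = write_report(config.out_dir, screening_report=report, enum=enum,
                         distal_results=distal_results, record=record,
                         indicator_ids=indicator_cols)
    return {"data": df, "binary": binary, "counts": counts, "scores": scores,
            "screening": report, "enumeration": enum, "distal": distal_results,
            "paths": paths, "record": record}
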