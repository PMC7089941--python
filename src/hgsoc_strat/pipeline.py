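"""End-to-end stratification: combine the genomic (LST) and transcriptomic
(Fibrosis/non-Fibrosis) calls into four prognostic strata and produce the
association and survival report.

The combined strata mirror the study's layout: LST_high/non_Fibrosis carries
the best prognosis and LST_low/Fibrosis the worst, with association tables
(counts, column percentages, Fisher p) and KM / log-rank / pairwise-BH / Cox
outputs for each requested endpoint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .classify import classify
from .lst import call_hrd
from .stats import (
    DEFAULT_HORIZON_MONTHS,
    cox_fit,
    fisher_exact,
    km_curve,
    logrank,
    median_survival,
    pairwise_logrank_bh,
)
from .types import (
    MISSING,
    ContingencyTable,
    LstCall,
    SubgroupAssignment,
    SurvivalRecord,
    TestResult,
)

logger = logging.getLogger(__name__)

STRATUM_LABELS = [
    "LST_high/Fibrosis",
    "LST_high/non_Fibrosis",
    "LST_low/Fibrosis",
    "LST_low/non_Fibrosis",
]


def combine_strata(
    lst_calls: dict[str, LstCall | str],
    fibrosis: SubgroupAssignment,
) -> SubgroupAssignment:
    """Cross the LST call with the Fibrosis call into four strata.

    Samples missing either call are excluded (count logged); stratum sizes
    partition the intersection.
    """
    lst_class = {
        s: (c.lst_class if isinstance(c, LstCall) else str(c))
        for s, c in lst_calls.items()
    }
    common = sorted(set(lst_class) & set(fibrosis.labels))
    if not common:
        raise ValueError("no sample has both an LST call and a subtype call")
    excluded = (set(lst_class) | set(fibrosis.labels)) - set(common)
    if excluded:
        logger.info("combine_strata: %d samples lack one of the calls", len(excluded))
    labels = {s: f"{lst_class[s]}/{fibrosis.labels[s]}" for s in common}
    sizes = pd.Series(labels).value_counts()
    logger.info("stratum sizes: %s", sizes.to_dict())
    return SubgroupAssignment("combined", labels)


def association_report(
    assignment: SubgroupAssignment,
    records: list[SurvivalRecord],
    variables: list[str],
) -> dict[str, dict]:
    """Per-variable contingency table + Fisher exact test against the groups.

    Missing values are dropped per variable (the table denominators may
    differ across variables); variables with a single observed level are
    skipped with a warning.  Tables carry variable levels as rows, groups as
    columns, with percentages within each group column.
    """
    rec_by_id = {r.sample_id: r for r in records}
    out: dict[str, dict] = {}
    for var in variables:
        pairs = [
            (rec_by_id[s].covariates.get(var, MISSING), g)
            for s, g in assignment.labels.items()
            if s in rec_by_id and rec_by_id[s].covariates.get(var, MISSING) != MISSING
        ]
        if not pairs:
            logger.warning("variable %r: no observed values; skipped", var)
            continue
        levels = pd.Series([p[0] for p in pairs], name=var)
        groups = pd.Series([p[1] for p in pairs], name=assignment.scheme_name)
        if levels.nunique() < 2:
            logger.warning("variable %r has a single observed level; skipped", var)
            continue
        if groups.nunique() < 2:
            logger.warning("groups degenerate for variable %r; skipped", var)
            continue
        table = hio.crosstab(levels, groups)
        out[var] = {
            "table": table,
            "percent": table.row_percentages(),
            "test": fisher_exact(table),
            "n": int(table.counts.sum()),
        }
    return out


def _survival_report(
    records: list[SurvivalRecord],
    groups: SubgroupAssignment,
    horizon: float | None,
    cox_covariates: list[str],
) -> dict:
    """KM per group, log-rank, pairwise BH (if >= 3 groups), and Cox models."""
    labels = groups.labels
    present = [r for r in records if r.sample_id in labels]
    report: dict = {"n": len(present), "groups": {}}
    for g in sorted(set(labels.values())):
        sub = [r for r in present if labels[r.sample_id] == g]
        curve = km_curve(sub, horizon_months=horizon)
        report["groups"][g] = {
            "n": len(sub),
            "median_survival": median_survival(sub, horizon_months=horizon),
            "km": {
                "times": curve.times.tolist(),
                "survival": curve.survival.tolist(),
                "n_at_risk": curve.n_at_risk.tolist(),
                "n_events": curve.n_events.tolist(),
            },
        }
    lr = logrank(present, labels, horizon_months=horizon)
    report["logrank"] = {"statistic": lr.statistic, "p_value": lr.p_value, "df": lr.df}
    if len(set(labels.values())) >= 3:
        mat = pairwise_logrank_bh(present, labels, horizon_months=horizon)
        report["pairwise_bh"] = {
            "groups": list(mat.index),
            "adjusted_p": mat.to_numpy().tolist(),
        }

    # Cox: group factor alone, then adjusted for the clinical covariates
    with_group = [
        SurvivalRecord(
            r.sample_id, r.time, r.event,
            {**r.covariates, "group": labels[r.sample_id]},
        )
        for r in present
    ]
    def cox_to_rows(results):
        return [
            {
                "factor": c.factor, "level": c.level, "reference": c.reference_level,
                "HR": c.hazard_ratio, "CI95_inf": c.ci95_low, "CI95_sup": c.ci95_high,
                "p_value": c.p_value,
            }
            for c in results
        ]
    try:
        report["cox_univariate"] = cox_to_rows(
            cox_fit(with_group, ["group"], horizon_months=horizon)
        )
        if cox_covariates:
            report["cox_multivariate"] = cox_to_rows(
                cox_fit(with_group, ["group"] + cox_covariates,
                        horizon_months=horizon)
            )
    except ValueError as exc:
        report["cox_error"] = str(exc)
    return report


@dataclass
class PipelineResult:
    """Artifacts of a full pipeline run."""

    lst_table: pd.DataFrame
    classification: SubgroupAssignment
    strata: SubgroupAssignment
    association: dict[str, dict]
    survival: dict
    outdir: Path | None = None


def run_pipeline(config: dict | str | Path) -> PipelineResult:
    """Execute the full stratification workflow from a config mapping/YAML.

    Config keys: ``inputs`` (segments, expr, signatures, clinical), ``scheme``,
    ``k``, ``distance``, ``horizon``, ``association_variables``,
    ``cox_covariates``, ``outdir``.  Every stage failure aborts with a
    stage-tagged message; re-running with the same config reproduces the
    numeric outputs exactly.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    inputs = config.get("inputs", {})
    for key in ("segments", "expr", "signatures", "clinical"):
        if key not in inputs:
            raise ValueError(f"[config] missing required input {key!r}")
    scheme = config.get("scheme", "mateescu")
    k = int(config.get("k", 2))
    distance = config.get("distance", "euclidean")
    horizon = config.get("horizon", DEFAULT_HORIZON_MONTHS) or None
    assoc_vars = config.get("association_variables", ["stage", "debulking"])
    cox_covs = config.get("cox_covariates", ["stage", "debulking"])
    outdir = Path(config["outdir"]) if config.get("outdir") else None

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    profiles = stage("read_segments", hio.read_seg, inputs["segments"])
    expr = stage("read_expression", hio.read_expression, inputs["expr"])
    signatures = stage("read_signatures", hio.read_gmt, inputs["signatures"])
    records = stage("read_clinical", hio.read_clinical, inputs["clinical"])

    sig = next((s for s in signatures if s.scheme_name == scheme), None)
    if sig is None:
        raise ValueError(
            f"[config] scheme {scheme!r} not in GMT "
            f"(available: {[s.scheme_name for s in signatures]})"
        )

    rows = []
    lst_calls: dict[str, LstCall] = {}
    for profile in profiles:
        ploidy, call = stage("lst", call_hrd, profile)
        lst_calls[profile.sample_id] = call
        rows.append(
            {
                "sample": profile.sample_id,
                "dna_index": ploidy.dna_index,
                "ploidy_class": ploidy.ploidy_class,
                "lst_count": call.lst_count,
                "cutoff": call.cutoff_used,
                "lst_class": call.lst_class,
            }
        )
    lst_table = pd.DataFrame(rows).set_index("sample")

    assignment = stage("classify", classify, expr, sig, k, distance)
    strata = stage("combine", combine_strata, lst_calls, assignment)
    association = stage("association", association_report, strata, records, assoc_vars)
    survival = stage("survival", _survival_report, records, strata, horizon, cox_covs)

    result = PipelineResult(lst_table, assignment, strata, association, survival, outdir)
    if outdir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    outdir = result.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    result.lst_table.to_csv(outdir / "lst_calls.tsv", sep="\t")
    hio.write_assignment(result.classification, outdir / "classification.tsv")
    hio.write_assignment(result.strata, outdir / "strata.tsv")
    assoc = {
        var: {
            "counts": entry["table"].to_frame().to_dict(),
            "percent": entry["percent"].round(2).to_dict(),
            "p_value": entry["test"].p_value,
            "method": entry["test"].method,
            "n": entry["n"],
        }
        for var, entry in result.association.items()
    }
    (outdir / "association.json").write_text(json.dumps(assoc, indent=2))
    (outdir / "survival.json").write_text(json.dumps(result.survival, indent=2))
    _plot_km(result, outdir / "km_strata.png")
    logger.info("wrote pipeline outputs to %s", outdir)


def _plot_km(result: PipelineResult, path: Path) -> None:
    """Basic KM step plot of the combined strata."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        logger.warning("matplotlib unavailable; skipping KM plot")
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, entry in result.survival["groups"].items():
        km = entry["km"]
        times = [0.0] + km["times"]
        surv = [1.0] + km["survival"]
        ax.step(times, surv, where="post", label=f"{g} (n={entry['n']})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    p = result.survival.get("logrank", {}).get("p_value")
    if p is not None:
        ax.set_title(f"log-rank p = {p:.2e}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
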