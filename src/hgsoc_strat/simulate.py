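"""Synthetic cohort generation with planted ground truth.

Every pipeline stage has a matching generator: copy-number profiles with an
exact planted number of large-scale transitions (all flanks >= 10 Mb) plus
sub-3 Mb variant noise, expression matrices with group mean shifts confined
to signature genes, and exponential proportional-hazards survival with
independent censoring.  The default cohort plants the study's structure:
four strata from the cross of an HRD (LST) call and a Fibrosis/non-Fibrosis
subtype, with additive log-hazards log(2.2) for LST-low and log(1.5) for
Fibrosis — so LST_high/non_Fibrosis has the best and LST_low/Fibrosis the
worst planted survival.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .types import MB, GeneSignature, Segment, SegmentProfile, SurvivalRecord

FLANK_MB = 10.0  # minimum region size flanking a planted transition
VARIANT_MAX_MB = 3.0  # planted variants stay strictly below this

DEFAULT_COHORT_CONFIG: dict = {
    "n_per_stratum": 50,
    "n_chromosomes": 22,
    "chrom_length_mb": 150.0,
    "tetraploid_fraction": 0.4,
    "lst_high_extra_max": 10,  # LST-high counts: cutoff .. cutoff+extra
    "n_small_variants_max": 20,
    "shift": 2.0,
    "noise_sd": 1.0,
    "n_background_genes": 200,
    "baseline_hazard": np.log(2) / 60.0,  # median OS ~ 60 months at baseline
    "log_hr_lst_low": float(np.log(2.2)),
    "log_hr_fibrosis": float(np.log(1.5)),
    "censor_rate": 0.3,
    "horizon_months": 120.0,
}

STRATA = [
    "LST_high/non_Fibrosis",
    "LST_high/Fibrosis",
    "LST_low/non_Fibrosis",
    "LST_low/Fibrosis",
]


def default_signature() -> GeneSignature:
    """Toy Fibrosis/non-Fibrosis scheme mirroring the published set sizes
    (16 fibrosis up-genes, 22 stress/non-fibrosis up-genes)."""
    return GeneSignature(
        "mateescu",
        {
            "Fibrosis": [f"FIB_{i:02d}" for i in range(1, 17)],
            "non_Fibrosis": [f"STR_{i:02d}" for i in range(1, 23)],
        },
    )


def dimp_signature(genes_per_set: int = 25) -> GeneSignature:
    """Toy four-subtype (D-I-M-P) scheme."""
    return GeneSignature(
        "verhaak",
        {
            lab: [f"{lab}_{i:02d}" for i in range(1, genes_per_set + 1)]
            for lab in ("D", "I", "M", "P")
        },
    )


def gen_cn_profile(
    n_chromosomes: int,
    chrom_length_mb: float,
    ploidy_base: int,
    n_lst: int,
    n_small_variants: int,
    seed: int | np.random.Generator,
    sample_id: str = "S1",
) -> tuple[SegmentProfile, dict]:
    """Copy-number profile with exactly ``n_lst`` planted transitions.

    Breakpoints are placed so that every resulting segment spans at least
    10 Mb; states alternate between the baseline ploidy and baseline + 1.
    Sub-3 Mb variants (state +/- 1) are inserted strictly inside planted
    segments with >= 3 Mb of host left on both sides, so smoothing removes
    them and restores the planted geometry exactly.
    """
    if ploidy_base not in (2, 4):
        raise ValueError("ploidy_base must be 2 or 4")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    flank_bp = int(FLANK_MB * MB)
    chrom_bp = int(chrom_length_mb * MB)
    per_chrom_cap = chrom_bp // flank_bp - 1
    capacity = n_chromosomes * max(per_chrom_cap, 0)
    if n_lst > capacity:
        raise ValueError(
            f"cannot place {n_lst} transitions: capacity is {capacity} "
            f"({n_chromosomes} chromosomes x {per_chrom_cap})"
        )

    # spread the transitions over chromosomes, respecting per-chromosome caps
    counts = np.zeros(n_chromosomes, dtype=int)
    for _ in range(n_lst):
        open_idx = np.flatnonzero(counts < per_chrom_cap)
        counts[open_idx[rng.integers(0, len(open_idx))]] += 1

    segments: list[Segment] = []
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1}"
        b = int(counts[ci])
        # b breakpoints with >= 10 Mb between them and to both chromosome ends
        slack = chrom_bp - (b + 1) * flank_bp
        offsets = np.sort(rng.integers(0, slack + 1, size=b)) if b else np.array([], int)
        cuts = [int(offsets[i] + (i + 1) * flank_bp) for i in range(b)]
        bounds = [1] + [c + 1 for c in cuts] + [chrom_bp + 1]
        # deviation direction alternates across chromosomes so the genome-wide
        # DNA index stays near ploidy_base / 2
        direction = 1 if ci % 2 == 0 else -1
        for si in range(len(bounds) - 1):
            cn = ploidy_base + direction * (si % 2)
            segments.append(
                Segment(chrom, bounds[si], bounds[si + 1] - 1, cn, cn - cn // 2)
            )

    var_bp = int(VARIANT_MAX_MB * MB)
    for _ in range(n_small_variants):
        var_len = int(rng.integers(int(0.5 * MB), var_bp))  # 0.5 .. <3 Mb
        need = 2 * var_bp + var_len
        eligible = [i for i, s in enumerate(segments) if s.length_bp >= need]
        if not eligible:
            raise ValueError(
                f"no segment can host a {var_len / MB:.1f} Mb variant "
                f"(needs >= {need / MB:.1f} Mb host)"
            )
        i = eligible[rng.integers(0, len(eligible))]
        host = segments[i]
        offset = int(rng.integers(var_bp, host.length_bp - var_bp - var_len + 1))
        v_start = host.start_bp + offset
        delta = 1 if host.total_cn == 0 else int(rng.choice([-1, 1]))
        v_cn = max(host.total_cn + delta, 0)
        pieces = [
            Segment(host.chrom, host.start_bp, v_start - 1, host.total_cn, host.major_cn),
            Segment(host.chrom, v_start, v_start + var_len - 1, v_cn, v_cn - v_cn // 2),
            Segment(host.chrom, v_start + var_len, host.end_bp, host.total_cn, host.major_cn),
        ]
        segments[i: i + 1] = pieces

    truth = {
        "lst_count_true": n_lst,
        "ploidy_true": "near_diploid" if ploidy_base == 2 else "near_tetraploid",
        "n_small_variants": n_small_variants,
    }
    return SegmentProfile(sample_id, segments), truth


def gen_expression(
    n_per_group: list[int],
    signature: GeneSignature,
    shift: float = 2.0,
    noise_sd: float = 1.0,
    n_background_genes: int = 200,
    seed: int | np.random.Generator = 0,
    sample_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix with group mean shifts confined to signature genes.

    Group g's up-genes are elevated by ``shift * noise_sd`` in group g's
    samples; background genes are pure Gaussian noise.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    labels = signature.labels
    if len(n_per_group) != len(labels):
        raise ValueError(
            f"n_per_group has {len(n_per_group)} entries for {len(labels)} sets"
        )
    if any(n < 2 for n in n_per_group):
        raise ValueError("each group needs at least 2 samples")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    genes = list(dict.fromkeys(signature.all_genes()))
    genes += [f"BG_{i:04d}" for i in range(1, n_background_genes + 1)]
    n_samples = int(sum(n_per_group))
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    if len(sample_ids) != n_samples:
        raise ValueError("sample_ids length mismatch")

    values = rng.normal(0.0, noise_sd, size=(len(genes), n_samples))
    expr = pd.DataFrame(values, index=genes, columns=sample_ids)
    truth = []
    start = 0
    for lab, n in zip(labels, n_per_group):
        cols = sample_ids[start: start + n]
        expr.loc[signature.gene_sets[lab], cols] += shift * noise_sd
        truth += [lab] * n
        start += n
    return expr, pd.Series(truth, index=sample_ids, name=signature.scheme_name)


def gen_survival(
    labels: pd.Series | dict,
    baseline_hazard: float,
    log_hr: dict[str, float],
    censor_rate: float = 0.3,
    horizon_months: float = 120.0,
    seed: int | np.random.Generator = 0,
    covariates: dict[str, dict[str, str]] | None = None,
) -> list[SurvivalRecord]:
    """Exponential proportional-hazards survival with independent censoring.

    Event times are exponential with hazard ``baseline * exp(log_hr[label])``;
    random censoring is exponential with rate calibrated so that, before
    administrative truncation at the horizon, the expected censored fraction
    approximates ``censor_rate``.
    """
    labels = pd.Series(dict(labels))
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if horizon_months is not None and horizon_months <= 0:
        raise ValueError("horizon must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rates = np.array(
        [baseline_hazard * np.exp(log_hr[lab]) for lab in labels], dtype=float
    )
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        mean_rate = rates.mean()
        censor_rate_param = censor_rate / (1.0 - censor_rate) * mean_rate
        censor_times = rng.exponential(1.0 / censor_rate_param, size=len(rates))
    else:
        censor_times = np.full(len(rates), np.inf)
    records = []
    for sid, t_event, t_cens in zip(labels.index, event_times, censor_times):
        limit = min(t_cens, horizon_months) if horizon_months else t_cens
        time = max(min(t_event, limit), 1e-6)
        event = int(t_event <= limit)
        cov = dict(covariates.get(sid, {})) if covariates else {}
        records.append(SurvivalRecord(str(sid), float(time), event, cov))
    return records


@dataclass
class SyntheticCohort:
    """A full synthetic cohort plus its planted truth."""

    profiles: list[SegmentProfile]
    expression: pd.DataFrame
    signature: GeneSignature
    clinical: list[SurvivalRecord]
    truth: pd.DataFrame
    config: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "segments": outdir / "segments.seg",
            "expression": outdir / "expression.tsv",
            "signatures": outdir / "signatures.gmt",
            "clinical": outdir / "clinical.csv",
            "truth": outdir / "truth.json",
        }
        hio.write_seg(self.profiles, paths["segments"])
        hio.write_expression(self.expression, paths["expression"])
        hio.write_gmt([self.signature], paths["signatures"])
        hio.write_clinical(self.clinical, paths["clinical"])
        payload = {
            "config": {k: v for k, v in self.config.items()},
            "samples": self.truth.to_dict(orient="index"),
        }
        paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
        return paths


def gen_cohort(config: dict | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a complete four-stratum cohort with consistent sample ids."""
    cfg = dict(DEFAULT_COHORT_CONFIG)
    if config:
        cfg.update(config)
    rng = np.random.default_rng(seed)
    n = int(cfg["n_per_stratum"])

    strata: list[str] = []
    for stratum in STRATA:
        strata += [stratum] * n
    sample_ids = [f"S{i:04d}" for i in range(1, len(strata) + 1)]
    stratum_of = dict(zip(sample_ids, strata))

    # --- segments -----------------------------------------------------
    profiles = []
    truth_rows = {}
    for sid in sample_ids:
        lst_part = stratum_of[sid].split("/")[0]
        tetra = rng.random() < cfg["tetraploid_fraction"]
        base = 4 if tetra else 2
        cutoff = 20 if tetra else 15
        if lst_part == "LST_high":
            n_lst = int(rng.integers(cutoff, cutoff + cfg["lst_high_extra_max"] + 1))
        else:
            n_lst = int(rng.integers(0, cutoff))
        n_var = int(rng.integers(0, cfg["n_small_variants_max"] + 1))
        profile, t = gen_cn_profile(
            int(cfg["n_chromosomes"]), float(cfg["chrom_length_mb"]),
            base, n_lst, n_var, rng, sample_id=sid,
        )
        profiles.append(profile)
        truth_rows[sid] = {
            **t,
            "lst_class_true": lst_part,
            "stratum_true": stratum_of[sid],
        }

    # --- expression ---------------------------------------------------
    signature = default_signature()
    fib_label = {sid: stratum_of[sid].split("/")[1] for sid in sample_ids}
    order = {"Fibrosis": 0, "non_Fibrosis": 1}
    by_group = sorted(sample_ids, key=lambda s: (order[fib_label[s]], s))
    n_fib = sum(1 for s in sample_ids if fib_label[s] == "Fibrosis")
    expr, expr_truth = gen_expression(
        [n_fib, len(sample_ids) - n_fib],
        signature,
        shift=float(cfg["shift"]),
        noise_sd=float(cfg["noise_sd"]),
        n_background_genes=int(cfg["n_background_genes"]),
        seed=rng,
        sample_ids=by_group,
    )
    expr = expr[sample_ids]  # restore cohort order
    for sid in sample_ids:
        truth_rows[sid]["subgroup_true"] = fib_label[sid]

    # --- clinical -----------------------------------------------------
    log_hr = {
        s: cfg["log_hr_lst_low"] * s.startswith("LST_low")
        + cfg["log_hr_fibrosis"] * s.endswith("/Fibrosis")
        for s in STRATA
    }
    # group-dependent categorical covariates (stage, debulking)
    covs = {}
    for sid in sample_ids:
        fib = fib_label[sid] == "Fibrosis"
        stage = "II" if rng.random() < (0.02 if fib else 0.07) else "III-IV"
        debulk = "full" if rng.random() < (0.16 if fib else 0.24) else "partial"
        covs[sid] = {"stage": stage, "debulking": debulk}
    clinical = gen_survival(
        {sid: stratum_of[sid] for sid in sample_ids},
        baseline_hazard=float(cfg["baseline_hazard"]),
        log_hr=log_hr,
        censor_rate=float(cfg["censor_rate"]),
        horizon_months=float(cfg["horizon_months"]),
        seed=rng,
        covariates=covs,
    )
    for sid in sample_ids:
        truth_rows[sid]["log_hr_true"] = float(log_hr[stratum_of[sid]])

    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    cfg_json = {k: (float(v) if isinstance(v, (np.floating,)) else v)
                for k, v in cfg.items()}
    cfg_json["seed"] = seed
    return SyntheticCohort(profiles, expr, signature, clinical, truth, cfg_json)
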