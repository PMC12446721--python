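"""Config-driven end-to-end validation run.

Reproduces the analysis shape of a scale-validation study: cohort in
(file or simulator) -> age filter -> completeness exclusions -> contrast
construction -> prevalence balancing -> scale scoring -> bootstrap AUCROC
test per (contrast x diagnosis reporter x scale), emitting a report table
with class sizes, AUCROC, 95% CI and one-/two-sided p-values against the
performance threshold, plus a sidecar log of every exclusion count and
every seed consumed.

Rows whose contrast cannot be constructed (e.g. no comorbidity-free cases
for strict specificity) are reported as NA with a reason rather than
dropped, so multi-contrast runs always complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from screenval import contrasts as ct
from screenval import rocboot
from screenval.scales import ScaleDefinition, default_affective_scale, score_scale
from screenval.synthetic_cohort import (
    CohortTable,
    ItemParams,
    SimConfig,
    read_cohort,
    sample_cohort,
)

REPORT_COLUMNS = (
    "contrast",
    "reporter",
    "scale",
    "sex",
    "n_pos",
    "n_neg",
    "threshold",
    "auc",
    "ci_low",
    "ci_high",
    "p_one_sided",
    "p_two_sided",
    "ratio_met",
    "note",
)


@dataclass
class RunConfig:
    """Everything a validation run needs; exactly one cohort source."""

    cohort_path: str | None = None
    sim: SimConfig | None = None
    age_bounds: tuple[int, int] | None = None
    reporters: tuple[str, ...] = ("parent", "child", "clinician")
    contrasts: tuple[str, ...] = ct.CONTRAST_KINDS
    scales: tuple[ScaleDefinition, ...] = field(
        default_factory=lambda: (default_affective_scale(),)
    )
    score_reporter: str = "parent"
    missing_policy: str = "exclude"
    target_ratio: float = ct.DEFAULT_TARGET_RATIO
    n_boot: int = rocboot.DEFAULT_N_BOOT
    threshold: float = rocboot.DEFAULT_THRESHOLD
    ci_level: float = rocboot.DEFAULT_CI_LEVEL
    seed: int = 0
    out_dir: str | None = None
    group_by_sex: bool = False

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.sim is None):
            raise ValueError("provide exactly one of cohort_path or sim")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        for kind in self.contrasts:
            if kind not in ct.CONTRAST_KINDS:
                raise ValueError(f"unknown contrast kind {kind!r}")
        if not self.scales:
            raise ValueError("at least one scale must be defined")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = sim_config_from_mapping(raw["sim"])
        if "scales" in raw and raw["scales"] is not None:
            raw["scales"] = tuple(
                ScaleDefinition(name=name, item_ids=tuple(items))
                for name, items in raw["scales"].items()
            )
        for key in ("age_bounds", "reporters", "contrasts"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def sim_config_from_mapping(raw: dict) -> SimConfig:
    """Build a SimConfig from a flat configuration mapping."""
    raw = dict(raw)
    if "item_params" in raw and raw["item_params"] is not None:
        raw["item_params"] = tuple(
            ItemParams(loading=float(a), thresholds=(float(b1), float(b2)))
            for a, b1, b2 in raw["item_params"]
        )
    if "liability_correlations" in raw and raw["liability_correlations"] is not None:
        raw["liability_correlations"] = np.asarray(raw["liability_correlations"], dtype=float)
    if "age_range" in raw and raw["age_range"] is not None:
        raw["age_range"] = tuple(raw["age_range"])
    return SimConfig(**raw)


@dataclass
class RunResult:
    report: pd.DataFrame
    log: list[str]


def _derive_seed(*parts: int) -> int:
    """Deterministic sub-seed below 2**31 from an integer key path."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _na_row(kind: str, reporter: str, scale: str, sex: str, threshold: float, note: str) -> dict:
    row = {c: pd.NA for c in REPORT_COLUMNS}
    row.update(
        contrast=kind,
        reporter=reporter,
        scale=scale,
        sex=sex,
        threshold=threshold,
        note=note,
    )
    return row


def run_validation(config: RunConfig) -> RunResult:
    """Run the full validation grid; deterministic given ``config.seed``."""
    log: list[str] = [f"seed: {config.seed}"]

    if config.sim is not None:
        cohort = sample_cohort(config.sim)
        log.append(f"simulated cohort: n={cohort.n} (sim seed {config.sim.seed})")
    else:
        cohort = read_cohort(config.cohort_path)
        log.append(f"loaded cohort from {config.cohort_path}: n={cohort.n}")

    if config.age_bounds is not None:
        before = cohort.n
        cohort = ct.filter_age(cohort, config.age_bounds)
        log.append(
            f"age filter {config.age_bounds}: kept {cohort.n} of {before} "
            f"(excluded {before - cohort.n})"
        )

    rows: list[dict] = []
    sex_groups: list[str] = ["pooled"] if not config.group_by_sex else ["F", "M"]
    row_idx = 0
    for sex in sex_groups:
        sub = cohort
        if sex != "pooled":
            sub = CohortTable(cohort.data[cohort.data["sex"] == sex].reset_index(drop=True))
            log.append(f"sex group {sex}: n={sub.n}")
        for scale in config.scales:
            before = sub.n
            complete = ct.exclude_incomplete(
                sub, config.reporters, scale, scale_reporter=config.score_reporter
            )
            log.append(
                f"completeness exclusions (scale {scale.name}, sex {sex}): "
                f"kept {complete.n} of {before} (excluded {before - complete.n})"
            )
            scores_table = score_scale(
                complete, scale, config.score_reporter, missing_policy=config.missing_policy
            )
            score_by_id = dict(
                zip(scores_table["id"], scores_table["raw_score"].to_numpy(dtype=float))
            )
            for kind in config.contrasts:
                for reporter in config.reporters:
                    row_idx += 1
                    try:
                        sample = ct.build_contrast(complete, kind, reporter)
                    except ct.ContrastUnconstructibleError as err:
                        log.append(f"row {row_idx}: {err}")
                        rows.append(
                            _na_row(kind, reporter, scale.name, sex, config.threshold, str(err))
                        )
                        continue
                    seed_bal = _derive_seed(config.seed, row_idx, 0)
                    seed_boot = _derive_seed(config.seed, row_idx, 1)
                    log.append(
                        f"row {row_idx} ({kind}/{reporter}/{scale.name}/{sex}): "
                        f"balance seed {seed_bal}, bootstrap seed {seed_boot}"
                    )
                    balanced = ct.balance_to_ratio(
                        sample, target_ratio=config.target_ratio, seed=seed_bal
                    )
                    ids = list(balanced.positives) + list(balanced.negatives)
                    labels = np.r_[
                        np.ones(balanced.n_positives, dtype=int),
                        np.zeros(balanced.n_negatives, dtype=int),
                    ]
                    scores = np.array([score_by_id[i] for i in ids])
                    res = rocboot.roc_test(
                        scores,
                        labels,
                        threshold=config.threshold,
                        n_boot=config.n_boot,
                        ci_level=config.ci_level,
                        seed=seed_boot,
                    )
                    rows.append(
                        {
                            "contrast": kind,
                            "reporter": reporter,
                            "scale": scale.name,
                            "sex": sex,
                            "n_pos": res.n_positives,
                            "n_neg": res.n_negatives,
                            "threshold": config.threshold,
                            "auc": res.auc,
                            "ci_low": res.ci[0],
                            "ci_high": res.ci[1],
                            "p_one_sided": str(res.p_one_sided),
                            "p_two_sided": str(res.p_two_sided),
                            "ratio_met": balanced.ratio_met,
                            "note": "" if balanced.ratio_met else "ratio not met: all controls used",
                        }
                    )

    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    result = RunResult(report=report, log=log)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        render_report(report, out / "report.csv")
        (out / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    return result


def _fmt(value, decimals: int = 3) -> str:
    if value is pd.NA or value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, float):
        return f"{value:.{decimals}f}"
    return str(value)


def render_report(report: pd.DataFrame, path=None) -> str:
    """Format the report (floats at 3 decimals, p-value floors preserved).

    Returns the delimited text; also writes it to ``path`` when given.
    The column order is stable and the output is byte-identical across
    runs with equal config and seed.
    """
    lines = [",".join(REPORT_COLUMNS)]
    for _, row in report.iterrows():
        lines.append(",".join(_fmt(row[c]) for c in REPORT_COLUMNS))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def parse_report(path) -> pd.DataFrame:
    """Read back a rendered report as strings (floors like '<0.001' survive)."""
    return pd.read_csv(path, dtype=str, na_values=["NA"], keep_default_na=False)
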