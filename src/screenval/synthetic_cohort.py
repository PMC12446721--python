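"""Synthetic multi-informant cohort generator.

Emulates the statistical structure of general-population child-psychiatry
cohorts in which the same participant is rated by a parent, by the child
themself, and by a clinician consensus: low disorder prevalences,
comorbidity among depression / anxiety / ADHD, strong parent-clinician
concordance and weak parent-child concordance.

Generative model (liability-threshold + graded response):

1. True liabilities ``L`` for the three disorders are multivariate standard
   normal with a configurable correlation matrix (the comorbidity
   structure).
2. Each informant ``r`` perceives disorder ``d`` through a noisy channel:
   ``P[r,d] = rho_r * L[d] + sqrt(1 - rho_r**2) * eps`` with independent
   standard-normal ``eps``, so ``rho_r`` is the correlation between truth
   and perception ("informant fidelity").
3. Informant ``r`` endorses a diagnosis of ``d`` iff ``P[r,d]`` exceeds the
   liability-threshold quantile ``Phi^{-1}(1 - prevalence_d)``.
4. A clinician consensus blends the two informants,
   ``C[d] = w * P[parent,d] + (1 - w) * P[child,d] + noise``, and applies
   the same quantile threshold.
5. Ordinal questionnaire items (three-point Likert, coded 0/1/2) follow a
   graded cumulative-logistic response model on the informant's perceived
   depression liability: ``Pr(response >= k) = expit(a_j * (P - b_jk))``
   with item loading ``a_j > 0`` and ordered thresholds ``b_j1 < b_j2``.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` substreams (one per generation stage), so
any sub-draw is reproducible in isolation.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

REPORTERS = ("parent", "child", "clinician")
SIMULATED_REPORTERS = ("parent", "child")
DISORDERS = ("depression", "anxiety", "adhd")
DX_FLAGS = DISORDERS + ("other",)
MISSING_MARKER = "NA"

# SeedSequence spawn order; appending stages keeps earlier draws stable.
_STAGES = ("liability", "perception", "clinician", "items", "demographics", "missingness")


@dataclass(frozen=True)
class ItemParams:
    """Graded-response parameters of one ordinal item.

    ``loading`` is the discrimination a_j (> 0); ``thresholds`` are the two
    ordered category boundaries (b_j1 < b_j2) on the liability scale, giving
    three response levels 0/1/2.
    """

    loading: float
    thresholds: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.loading > 0:
            raise ValueError(f"item loading must be positive, got {self.loading}")
        b1, b2 = self.thresholds
        if not b1 < b2:
            raise ValueError(f"item thresholds must be strictly ordered, got {b1} >= {b2}")


def _default_items(n_items: int = 13) -> tuple[ItemParams, ...]:
    # Moderate-to-strong loadings and mostly high thresholds: in a
    # general-population sample most items are endorsed rarely, so raw
    # scale scores pile up near zero, as observed in community cohorts.
    rng = np.random.default_rng(20240131)
    loadings = rng.uniform(1.2, 2.2, n_items)
    b1 = rng.uniform(0.6, 1.6, n_items)
    gaps = rng.uniform(0.8, 1.4, n_items)
    return tuple(
        ItemParams(round(float(a), 3), (round(float(lo), 3), round(float(lo + g), 3)))
        for a, lo, g in zip(loadings, b1, gaps)
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a general-population-like cohort: depression
    prevalence 5%, anxiety/ADHD 10% each, positive liability correlations
    (comorbidity), a high-fidelity parent informant (rho = 0.9), a
    low-fidelity child informant (rho = 0.3), and a clinician consensus
    weighted toward the parent — the regime that makes concordant
    parent/child positive diagnoses the rarest cell of the agreement table.
    """

    n_participants: int = 1000
    disorder_prevalences: dict[str, float] = field(
        default_factory=lambda: {"depression": 0.05, "anxiety": 0.10, "adhd": 0.10}
    )
    liability_correlations: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [1.0, 0.45, 0.30],
                [0.45, 1.0, 0.30],
                [0.30, 0.30, 1.0],
            ]
        )
    )
    informant_fidelities: dict[str, float] = field(
        default_factory=lambda: {"parent": 0.9, "child": 0.3}
    )
    clinician_parent_weight: float = 0.7
    clinician_noise_sd: float = 0.3
    item_params: tuple[ItemParams, ...] = field(default_factory=_default_items)
    age_range: tuple[int, int] = (8, 12)
    missing_rate_items: float = 0.0
    missing_rate_diagnoses: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.liability_correlations = np.asarray(self.liability_correlations, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be a positive integer")
        for d in DISORDERS:
            if d not in self.disorder_prevalences:
                raise ValueError(f"missing prevalence for disorder {d!r}")
            p = self.disorder_prevalences[d]
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {d!r} must lie strictly in (0, 1), got {p}")
        m = self.liability_correlations
        if m.shape != (3, 3):
            raise ValueError(f"liability_correlations must be 3x3, got shape {m.shape}")
        if not np.allclose(m, m.T):
            raise ValueError("liability_correlations must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("liability_correlations must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("liability_correlations must be positive semidefinite")
        for r in SIMULATED_REPORTERS:
            rho = self.informant_fidelities.get(r)
            if rho is None or not 0.0 <= rho <= 1.0:
                raise ValueError(f"informant fidelity for {r!r} must lie in [0, 1], got {rho}")
        if not 0.0 <= self.clinician_parent_weight <= 1.0:
            raise ValueError("clinician_parent_weight must lie in [0, 1]")
        if self.clinician_noise_sd < 0:
            raise ValueError("clinician_noise_sd must be nonnegative")
        if not self.item_params:
            raise ValueError("item_params must be non-empty")
        for rate in (self.missing_rate_items, self.missing_rate_diagnoses):
            if not 0.0 <= rate < 1.0:
                raise ValueError("missingness rates must lie in [0, 1)")
        lo, hi = self.age_range
        if lo > hi:
            raise ValueError("age_range bounds must be ordered")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


def default_sim_config(**overrides) -> SimConfig:
    """The generator's reference configuration (see class docstring)."""
    return SimConfig(**overrides)


@dataclass
class CohortTable:
    """Per-participant demographics, item responses and diagnosis flags.

    Thin wrapper over a :class:`pandas.DataFrame` with one row per
    participant and the column convention ``reporter.item_NN`` /
    ``reporter.dx_DISORDER``. Item responses are ordinal 0/1/2 (nullable),
    diagnosis flags 0/1 (nullable); the on-disk missing marker is ``NA``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in ("id", "age", "sex"):
            if col not in df.columns:
                raise ValueError(f"cohort is missing required column {col!r}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate participant id {dup!r}")
        for col in df.columns:
            if "." in col:
                reporter = col.split(".", 1)[0]
                if reporter not in REPORTERS:
                    raise ValueError(f"unknown reporter column {col!r}")
        for col in self.item_columns_all():
            vals = df[col].dropna()
            if len(vals) and not vals.isin([0, 1, 2]).all():
                bad = vals[~vals.isin([0, 1, 2])].iloc[0]
                raise ValueError(f"malformed ordinal value {bad!r} in column {col!r}")
        for col in self.dx_columns_all():
            vals = df[col].dropna()
            if len(vals) and not vals.isin([0, 1]).all():
                bad = vals[~vals.isin([0, 1])].iloc[0]
                raise ValueError(f"malformed diagnosis flag {bad!r} in column {col!r}")

    # -- column accessors -------------------------------------------------
    def item_columns(self, reporter: str) -> list[str]:
        prefix = f"{reporter}.item_"
        return [c for c in self.data.columns if c.startswith(prefix)]

    def item_columns_all(self) -> list[str]:
        return [c for c in self.data.columns if ".item_" in c]

    def dx_columns(self, reporter: str) -> list[str]:
        prefix = f"{reporter}.dx_"
        return [c for c in self.data.columns if c.startswith(prefix)]

    def dx_columns_all(self) -> list[str]:
        return [c for c in self.data.columns if ".dx_" in c]

    def reporters(self) -> list[str]:
        seen = []
        for col in self.data.columns:
            if "." in col:
                r = col.split(".", 1)[0]
                if r not in seen:
                    seen.append(r)
        return seen

    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {stage: np.random.default_rng(ss) for stage, ss in zip(_STAGES, children)}


def sample_cohort(config: SimConfig) -> CohortTable:
    """Draw a synthetic cohort from the liability-threshold model.

    Deterministic given ``config.seed``. See module docstring for the
    generative process.
    """
    config.validate()
    rngs = _substreams(config.seed)
    n = config.n_participants
    n_items = len(config.item_params)

    # (1) true liabilities, columns ordered as DISORDERS
    L = rngs["liability"].multivariate_normal(
        np.zeros(3), config.liability_correlations, size=n, method="eigh"
    )

    # (2) perceived liabilities per informant
    P: dict[str, np.ndarray] = {}
    for reporter in SIMULATED_REPORTERS:
        rho = config.informant_fidelities[reporter]
        eps = rngs["perception"].standard_normal((n, 3))
        P[reporter] = rho * L + np.sqrt(1.0 - rho**2) * eps

    # (3) informant diagnoses via the prevalence quantile
    z = np.array([norm.ppf(1.0 - config.disorder_prevalences[d]) for d in DISORDERS])
    dx = {r: (P[r] > z).astype(int) for r in SIMULATED_REPORTERS}

    # (4) clinician consensus
    w = config.clinician_parent_weight
    noise = config.clinician_noise_sd * rngs["clinician"].standard_normal((n, 3))
    C = w * P["parent"] + (1.0 - w) * P["child"] + noise
    dx["clinician"] = (C > z).astype(int)

    # (5) graded ordinal items on the perceived depression liability
    a = np.array([ip.loading for ip in config.item_params])
    b1 = np.array([ip.thresholds[0] for ip in config.item_params])
    b2 = np.array([ip.thresholds[1] for ip in config.item_params])
    dep_idx = DISORDERS.index("depression")
    items: dict[str, np.ndarray] = {}
    for reporter in SIMULATED_REPORTERS:
        p_dep = P[reporter][:, dep_idx][:, None]
        u = rngs["items"].random((n, n_items))
        # single uniform per item keeps the cumulative categories nested
        items[reporter] = (u < expit(a * (p_dep - b1))).astype(int) + (
            u < expit(a * (p_dep - b2))
        ).astype(int)

    rng_demo = rngs["demographics"]
    lo, hi = config.age_range
    ages = rng_demo.integers(lo, hi + 1, size=n)
    sexes = rng_demo.choice(np.array(["F", "M"]), size=n)

    width = max(6, len(str(n)))
    columns: dict[str, object] = {
        "id": [f"S{i:0{width}d}" for i in range(1, n + 1)],
        "age": ages,
        "sex": sexes,
    }
    for reporter in SIMULATED_REPORTERS:
        for j in range(n_items):
            columns[f"{reporter}.item_{j + 1:02d}"] = items[reporter][:, j]
    for reporter in REPORTERS:
        for k, d in enumerate(DISORDERS):
            columns[f"{reporter}.dx_{d}"] = dx[reporter][:, k]

    df = pd.DataFrame(columns)
    item_cols = [c for c in df.columns if ".item_" in c]
    dx_cols = [c for c in df.columns if ".dx_" in c]
    df[item_cols] = df[item_cols].astype("Int64")
    df[dx_cols] = df[dx_cols].astype("Int64")

    rng_miss = rngs["missingness"]
    if config.missing_rate_items > 0:
        mask = rng_miss.random((n, len(item_cols))) < config.missing_rate_items
        block = df[item_cols].to_numpy(dtype=object)
        block[mask] = pd.NA
        df[item_cols] = pd.DataFrame(block, columns=item_cols).astype("Int64")
    if config.missing_rate_diagnoses > 0:
        mask = rng_miss.random((n, len(dx_cols))) < config.missing_rate_diagnoses
        block = df[dx_cols].to_numpy(dtype=object)
        block[mask] = pd.NA
        df[dx_cols] = pd.DataFrame(block, columns=dx_cols).astype("Int64")

    return CohortTable(df)


# ---------------------------------------------------------------------------
# Delimited-text round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTable, destination, sep: str = ",") -> None:
    """Write a cohort as delimited text with the ``NA`` missing marker."""
    cohort.data.to_csv(destination, sep=sep, index=False, na_rep=MISSING_MARKER)


def _sniff_sep(source) -> str:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            header = fh.readline()
    else:
        pos = source.tell()
        header = source.readline()
        source.seek(pos)
    return "\t" if "\t" in header else ","


def read_cohort(source, sep: str | None = None) -> CohortTable:
    """Read a cohort written by :func:`write_cohort` (comma or tab)."""
    if sep is None:
        sep = _sniff_sep(source)
    df = pd.read_csv(
        source,
        sep=sep,
        na_values=[MISSING_MARKER],
        keep_default_na=False,
        dtype={"id": str, "sex": str},
    )
    item_cols = [c for c in df.columns if ".item_" in c]
    dx_cols = [c for c in df.columns if ".dx_" in c]
    for col in item_cols + dx_cols:
        try:
            df[col] = df[col].astype("Int64")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed ordinal value in column {col!r}: {exc}") from exc
    if "age" in df.columns:
        df["age"] = df["age"].astype("int64" if df["age"].notna().all() and len(df) else "Int64")
    return CohortTable(df)


def cohort_to_string(cohort: CohortTable, sep: str = ",") -> str:
    buf = io.StringIO()
    write_cohort(cohort, buf, sep=sep)
    return buf.getvalue()
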