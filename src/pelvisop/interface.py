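"""Descriptive statistics, hypothesis tests, study configuration and report
formatting shared by the command-line entry points."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "DescriptiveStats",
    "descriptive_stats",
    "paired_t",
    "two_sample_t",
    "one_way_anova",
    "StudyConfig",
    "selection_report",
]


@dataclass(frozen=True)
class DescriptiveStats:
    """Sample summary presented as "mean (SD, min to max)"."""

    mean: float
    sd: float
    min: float
    max: float
    n: int

    def formatted(self, fmt: str = ".1f") -> str:
        return (f"{self.mean:{fmt}} ({self.sd:{fmt}}, "
                f"{self.min:{fmt}} to {self.max:{fmt}})")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.formatted()


def descriptive_stats(values) -> DescriptiveStats:
    """Mean, sample SD (n-1 denominator), minimum and maximum of a column."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("descriptive statistics need at least 2 values")
    return DescriptiveStats(mean=float(v.mean()),
                            sd=float(v.std(ddof=1)),
                            min=float(v.min()), max=float(v.max()),
                            n=int(len(v)))


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired-sample t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired test needs two equal-length samples, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return (0.0, 1.0) if np.allclose(d.mean(), 0.0) else (np.inf, 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def two_sample_t(a, b) -> tuple[float, float]:
    """Two-sided two-sample (pooled-variance) t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA across two or more groups; returns (F, p)."""
    if len(groups) < 2 or any(len(np.asarray(g)) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Run configuration shared by the CLI subcommands."""

    seed: int = 0
    scenario: str = "B"
    n: int = 196
    alpha: float = 0.001
    coef_floor: float = 1e-3
    pick_noise_sd: float = 0.5
    phantom_repeats: int = 5
    grid_step: float = 2.0
    landmarks_path: str | None = None
    views_path: str | None = None
    cohort_path: str | None = None
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 0.05:
            raise ValueError("alpha must lie in (0, 0.05]")
        if self.scenario not in ("A", "B"):
            raise ValueError("scenario must be 'A' or 'B'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Short stable digest of the configuration, stamped into outputs."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def resolve_paths(self) -> None:
        for attr in ("landmarks_path", "views_path", "cohort_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} does not resolve: {p}")


def setup_logging(log_path: str | Path | None = None) -> logging.Logger:
    logger = logging.getLogger("pelvisop")
    logger.setLevel(logging.INFO)
    if log_path is not None:
        handler = logging.FileHandler(log_path)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    return logger


# ---------------------------------------------------------------------------
# Model report tables
# ---------------------------------------------------------------------------

def selection_report(models: Mapping[str, "object"],
                     comparisons: Mapping[str, "object"],
                     order: Sequence[str] = ("max", "minMSE", "oneSE", "min"),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shape a fitted model family into two report tables.

    The first table lists, per model, the number of predictors, LOOCV RMSE,
    adjusted R^2 and the Delta-AIC/Delta-BIC/p-value of the nested
    comparison against the next-larger model in the chain. The second lists
    the oneSE model's coefficients with SEs and p-values.
    """
    chain = {"minMSE": "minMSE_vs_max", "oneSE": "oneSE_vs_minMSE",
             "min": "min_vs_oneSE"}
    rows = []
    for model_id in order:
        m = models[model_id]
        row = {"model": model_id, "NoP": m.n_predictors,
               "RMSE": m.loocv_rmse, "R2_adj": m.r2_adj,
               "dAIC": np.nan, "dBIC": np.nan, "p_value": np.nan}
        cmp_key = chain.get(model_id)
        if cmp_key and cmp_key in comparisons:
            c = comparisons[cmp_key]
            row.update({"dAIC": c.delta_aic, "dBIC": c.delta_bic,
                        "p_value": c.lrt_p})
        rows.append(row)
    table_models = pd.DataFrame(rows)

    one_se = models["oneSE"]
    coef_rows = [{"parameter": "(Intercept)", "estimate": one_se.intercept,
                  "se": np.nan, "p_value": np.nan}]
    if one_se.fitted:
        for name in one_se.predictors:
            coef_rows.append({"parameter": name,
                              "estimate": one_se.coefficients[name],
                              "se": one_se.coef_se[name],
                              "p_value": one_se.p_values[name]})
    return table_models, pd.DataFrame(coef_rows)
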