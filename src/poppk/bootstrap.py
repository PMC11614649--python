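"""Nonparametric bootstrap of the fitted model.

The resampling unit is the subject (full event history), preserving
within-subject correlation.  Summaries report the original point
estimates, bootstrap medians, percentile intervals (default 5th-95th),
and the relative bias ``(median - estimate) * 100 / estimate``.
Non-converged replicates are excluded from summaries and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import TDMDataset
from .estimation import FitConfig, FitResult, fit
from .model import PopulationModel

__all__ = ["ParamSummary", "BootstrapSummary", "bootstrap",
           "bias_percent", "percentile_interval"]

logger = logging.getLogger(__name__)


def bias_percent(estimate: float, bootstrap_median: float) -> float:
    """Relative bias: (median - estimate) * 100 / estimate."""
    if estimate == 0:
        raise ValueError("bias is undefined for a zero estimate")
    return (bootstrap_median - estimate) * 100.0 / estimate


def percentile_interval(samples: Sequence[float], lower_pct: float = 5.0,
                        upper_pct: float = 95.0) -> tuple[float, float]:
    """Empirical percentile interval (linear interpolation between order
    statistics)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    lo, hi = np.percentile(samples, [lower_pct, upper_pct])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ParamSummary:
    estimate: float
    median: float
    ci_lower: float
    ci_upper: float
    bias_percent: float


@dataclass
class BootstrapSummary:
    parameters: dict[str, ParamSummary]
    n_requested: int
    n_converged: int
    seed: int
    replicates: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "seed": self.seed,
            "parameters": {k: vars(v) for k, v in self.parameters.items()},
        }

    def render(self) -> str:
        """Estimate / median / percentile-interval / bias table."""
        lines = [f"{'Parameter':<22}{'Estimate':>12}{'Median':>12}"
                 f"{'[5th, 95th]':>24}{'Bias (%)':>10}"]
        for name, s in self.parameters.items():
            ci = f"[{s.ci_lower:.6g}, {s.ci_upper:.6g}]"
            lines.append(f"{name:<22}{s.estimate:>12.6g}{s.median:>12.6g}"
                         f"{ci:>24}{s.bias_percent:>10.2f}")
        lines.append(f"converged replicates: {self.n_converged}/{self.n_requested}")
        return "\n".join(lines)


def _resample_dataset(ds: TDMDataset, indices: np.ndarray) -> TDMDataset:
    subjects = ds.subjects()
    records = []
    for k, i in enumerate(indices):
        sid = subjects[int(i)]
        for r in ds.subject_records(sid):
            records.append(replace(r, subject_id=f"{sid}#{k}"))
    return TDMDataset(records)


def bootstrap(ds: TDMDataset, model_structure: PopulationModel,
              n_reps: int = 1000, seed: int = 0,
              fit_config: FitConfig | None = None,
              original_fit: FitResult | None = None,
              resampler: Callable[[np.random.Generator, int, int], np.ndarray]
              | None = None,
              lower_pct: float = 5.0, upper_pct: float = 95.0) -> BootstrapSummary:
    """Subject-level bootstrap; reproducible given ``seed``.

    Each replicate resamples subjects with replacement to the original
    subject count and refits from the original estimates (warm start).
    ``resampler(rng, n_subjects, rep_index)`` can be overridden, e.g.
    with an identity resample for testing.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = fit_config or FitConfig(compute_se=False)
    if original_fit is None:
        original_fit = fit(ds, model_structure,
                           replace(cfg, compute_se=False))
    point = original_fit.parameter_values()
    names = list(point)

    rng = np.random.default_rng(seed)
    n_subj = ds.n_subjects
    rows = []
    n_converged = 0
    for rep in range(n_reps):
        if resampler is not None:
            idx = np.asarray(resampler(rng, n_subj, rep))
        else:
            idx = rng.integers(0, n_subj, n_subj)
        res_ds = _resample_dataset(ds, idx)
        try:
            rep_fit = fit(res_ds, original_fit.estimates,
                          replace(cfg, compute_se=False))
        except Exception as exc:  # noqa: BLE001 - failed replicates are counted
            logger.warning("replicate %d failed: %s", rep, exc)
            continue
        if not rep_fit.converged:
            logger.warning("replicate %d did not converge", rep)
            continue
        n_converged += 1
        rows.append(rep_fit.parameter_values())
    if not rows:
        raise RuntimeError("all bootstrap replicates failed to converge")

    reps_frame = pd.DataFrame(rows, columns=names)
    params: dict[str, ParamSummary] = {}
    for name in names:
        values = reps_frame[name].to_numpy()
        med = float(np.percentile(values, 50.0))
        lo, hi = percentile_interval(values, lower_pct, upper_pct)
        params[name] = ParamSummary(
            estimate=point[name], median=med, ci_lower=lo, ci_upper=hi,
            bias_percent=bias_percent(point[name], med))
    return BootstrapSummary(parameters=params, n_requested=n_reps,
                            n_converged=n_converged, seed=seed,
                            replicates=reps_frame)
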