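"""Goodness-of-fit quantities: population/individual predictions,
weighted residuals, and a visual predictive check.

Plots are out of scope; this module emits the plotted quantities as
tables.  All outputs are pure functions of (fit, dataset, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import draw_observation
from .dataset import TDMDataset
from .estimation import FitResult, _Packed, _make_data_terms
from .model import residual_variance

__all__ = ["PredictionRecord", "VPCResult", "predictions", "wres_fo", "vpc"]


@dataclass(frozen=True)
class PredictionRecord:
    subject_id: str
    time: float
    dv: float
    pred: float   # population prediction (eta = 0)
    ipred: float  # individual prediction (eta = eta_hat)
    iwres: float  # (dv - ipred) / g(ipred)


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    observed: pd.DataFrame   # one row per bin: p5, p50, p95, n
    simulated: pd.DataFrame  # per bin and level: band_lower, band_upper
    n_simulations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        obs = self.observed.melt(id_vars=["bin", "n"], var_name="level",
                                 value_name="observed")
        return obs.merge(self.simulated, on=["bin", "level"], how="left")


def predictions(fit: FitResult, ds: TDMDataset) -> list[PredictionRecord]:
    """PRED (eta=0), IPRED (eta=eta_hat) and iWRES per observation."""
    if not fit.converged:
        raise ValueError("fit did not converge; diagnostics unavailable")
    missing = [sid for sid in ds.subjects() if sid not in fit.eta_hat]
    if missing:
        raise KeyError(f"subjects missing from fit: {missing}")
    packed = _Packed(ds)
    predict, _ = _make_data_terms(packed, fit.estimates)
    eta = np.array([fit.eta_hat[sid] for sid in packed.subjects])
    pred = predict(np.zeros(packed.n))
    ipred = predict(eta)
    out: list[PredictionRecord] = []
    for i, sid in enumerate(packed.subjects):
        obs_recs = [r for r in ds.subject_records(sid) if not r.is_dose]
        for j, rec in enumerate(obs_recs):
            g2 = residual_variance(float(ipred[i, j]), fit.estimates)
            iwres = ((rec.concentration - ipred[i, j]) / np.sqrt(g2)
                     if g2 > 0 else np.nan)
            out.append(PredictionRecord(
                subject_id=sid, time=rec.time, dv=rec.concentration,
                pred=float(pred[i, j]), ipred=float(ipred[i, j]),
                iwres=float(iwres)))
    return out


def predictions_frame(fit: FitResult, ds: TDMDataset) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in predictions(fit, ds)])


def wres_fo(fit: FitResult, ds: TDMDataset) -> dict[str, np.ndarray]:
    """FO weighted residuals per subject.

    The population residual ``d - f(0)`` is decorrelated by the inverse
    Cholesky factor of ``G omega2 G' + diag(g2)`` with ``G`` the
    finite-difference gradient of the predictions with respect to eta
    at 0 and ``g2`` evaluated at the population prediction.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; diagnostics unavailable")
    packed = _Packed(ds)
    m = fit.estimates
    predict, _ = _make_data_terms(packed, m)
    zero = np.zeros(packed.n)
    f0 = predict(zero)
    h = 1e-4
    grad = (predict(zero + h) - predict(zero - h)) / (2.0 * h)
    omega2 = m.omega2_value
    out: dict[str, np.ndarray] = {}
    for i, sid in enumerate(packed.subjects):
        jmask = packed.mask[i].astype(bool)
        nobs = int(jmask.sum())
        if nobs == 0:
            out[sid] = np.zeros(0)
            continue
        fi = f0[i, jmask]
        gi = grad[i, jmask]
        g2 = np.maximum(m.sigma2_prop_value * fi * fi + m.sigma2_add_value,
                        1e-12)
        cov = omega2 * np.outer(gi, gi) + np.diag(g2)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance not positive definite for subject {sid}") from exc
        resid = packed.obs[i, jmask] - fi
        out[sid] = np.linalg.solve(chol, resid)
    return out


def vpc(fit: FitResult, ds: TDMDataset, n_sim: int = 500,
        bins: int | np.ndarray = 8, seed: int = 0,
        levels: tuple[float, ...] = (5.0, 50.0, 95.0)) -> VPCResult:
    """Visual predictive check quantities.

    Simulates ``n_sim`` replicate datasets under the fitted model with
    the original design (doses, times, covariates), then compares
    binned observed percentiles against the 2.5-97.5% band of each
    simulated percentile.  Deterministic given ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not fit.converged:
        raise ValueError("fit did not converge; diagnostics unavailable")
    packed = _Packed(ds)
    m = fit.estimates
    predict, _ = _make_data_terms(packed, m)
    jmask = packed.mask.astype(bool)
    times = np.concatenate([
        np.array([r.time for r in ds.subject_records(sid) if not r.is_dose])
        for sid in packed.subjects])
    observed_dv = packed.obs[jmask]

    if np.isscalar(bins):
        qs = np.linspace(0, 100, int(bins) + 1)
        edges = np.unique(np.percentile(times, qs))
        if len(edges) < 2:
            edges = np.array([times.min() - 0.5, times.max() + 0.5])
    else:
        edges = np.asarray(bins, dtype=float)
    edges = edges.copy()
    edges[-1] += 1e-9  # right-closed last bin
    bin_index = np.clip(np.digitize(times, edges) - 1, 0, len(edges) - 2)

    rng = np.random.default_rng(seed)
    omega2 = m.omega2_value
    s2p = m.sigma2_prop_value
    s2a = m.sigma2_add_value
    sim_percentiles = {lvl: [] for lvl in levels}
    n_bins = len(edges) - 1
    kept_bins = [b for b in range(n_bins) if np.any(bin_index == b)]
    for _ in range(n_sim):
        eta = (rng.normal(0.0, np.sqrt(omega2), packed.n)
               if omega2 > 0 else np.zeros(packed.n))
        f = predict(eta)[jmask]
        sim_dv = np.array([draw_observation(rng, fi, s2p, s2a)[0] for fi in f])
        for lvl in levels:
            sim_percentiles[lvl].append([
                np.percentile(sim_dv[bin_index == b], lvl) for b in kept_bins])

    obs_rows = []
    sim_rows = []
    for bi, b in enumerate(kept_bins):
        sel = bin_index == b
        row = {"bin": b, "n": int(sel.sum())}
        for lvl in levels:
            row[f"p{lvl:g}"] = float(np.percentile(observed_dv[sel], lvl))
            sims = np.array(sim_percentiles[lvl])[:, bi]
            sim_rows.append({
                "bin": b, "level": f"p{lvl:g}",
                "band_lower": float(np.percentile(sims, 2.5)),
                "band_upper": float(np.percentile(sims, 97.5)),
                "band_median": float(np.percentile(sims, 50.0)),
            })
        obs_rows.append(row)

    mids = 0.5 * (edges[:-1] + edges[1:])
    return VPCResult(
        bin_edges=edges,
        bin_mid=mids[kept_bins],
        observed=pd.DataFrame(obs_rows),
        simulated=pd.DataFrame(sim_rows),
        n_simulations=n_sim,
        seed=seed,
    )
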