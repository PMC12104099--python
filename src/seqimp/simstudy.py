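"""Simulation-study engine: resample → ampute → impute → pool → score.

Each repetition resamples the complete panel's sequences with
replacement, generates missingness with a configured amputer, imputes M
times with every method under comparison, computes the estimands and
their bootstrap variances on each completed panel, and pools the M
results with Rubin's rules.  Across repetitions the engine reports, per
estimand, the bias against the truth (the estimand value on the
original complete panel), the empirical coverage of the 95% pooled
intervals, the empirical variance, and Monte Carlo standard errors.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .estimands import bootstrap_variance, estimand_index, estimands
from .panel import SequencePanel


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PooledEstimate:
    Q_bar: float
    W_bar: float
    B: float
    T_var: float
    df: float
    ci95: tuple[float, float]
    M: int


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool M completed-data estimates with Rubin's rules.

    ``T = W̄ + (1 + 1/M)·B``; the 95% interval uses the t reference
    with ``df = (M-1)(1 + W̄ / ((1+1/M)B))²`` (∞ when B = 0).
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if (w < 0).any():
        raise ValueError("variances must be non-negative")
    M = q.size
    Q = float(q.mean())
    W = float(w.mean())
    if M < 2:
        return PooledEstimate(Q, W, 0.0, W, np.inf,
                              _ci(Q, W, np.inf), M)
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / M) * B
    if B == 0.0:
        df = np.inf
    else:
        df = (M - 1) * (1.0 + W / ((1.0 + 1.0 / M) * B)) ** 2
    return PooledEstimate(Q, W, B, T, df, _ci(Q, T, df), M)


def _ci(Q: float, T: float, df: float) -> tuple[float, float]:
    crit = 1.959963984540054 if not np.isfinite(df) else \
        float(_stats.t.ppf(0.975, df))
    half = crit * np.sqrt(T)
    return (Q - half, Q + half)


def _rubin_pool_vector(Qs: np.ndarray, Ws: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                  np.ndarray, np.ndarray]:
    """Vectorised Rubin pooling over estimands: Qs, Ws are (M, d)."""
    M = Qs.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        Q = np.nanmean(Qs, axis=0)
        W = np.nanmean(Ws, axis=0)
        B = np.nanvar(Qs, axis=0, ddof=1) if M > 1 else np.zeros_like(Q)
    T = W + (1.0 + 1.0 / M) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        df = np.where(B > 0,
                      (M - 1) * (1.0 + W / ((1.0 + 1.0 / M) * B)) ** 2,
                      np.inf)
    crit = np.where(np.isfinite(df), _stats.t.ppf(0.975, np.clip(df, 1e-6, None)),
                    1.959963984540054)
    half = crit * np.sqrt(T)
    return Q, T, df, Q - half, Q + half


# ---------------------------------------------------------------------------
# Method adapters
# ---------------------------------------------------------------------------

class OracleImputer:
    """Perfect imputation: returns the true (pre-amputation) panel M
    times.  Calibration baseline for the study engine."""

    needs_truth = True
    _method_name = "oracle"

    def impute_with_truth(self, panel, truth: SequencePanel, M: int):
        return [truth] * M


class MarginalImputer:
    """Naive baseline: every missing cell drawn independently from the
    panel-wide observed state distribution."""

    _method_name = "marginal_draw"

    def __init__(self, random_state: int | None = None):
        self.random_state = random_state

    def impute(self, panel: SequencePanel, M: int = 1):
        from .mict import MultipleImputation
        obs = panel.data[panel.data >= 0]
        K = panel.n_states
        p = np.bincount(obs, minlength=K) / obs.size
        panels = []
        ss = np.random.SeedSequence(self.random_state)
        for child in ss.spawn(M):
            rng = np.random.default_rng(child)
            W = panel.data.copy()
            mask = panel.missing_mask()
            W[mask] = rng.choice(K, size=int(mask.sum()), p=p)
            panels.append(panel.copy(data=W))
        return MultipleImputation(panels=panels, method=self._method_name,
                                  config={}, seed=self.random_state,
                                  fit_log=[])


# ---------------------------------------------------------------------------
# Study
# ---------------------------------------------------------------------------

def run_study(complete_panel: SequencePanel, amputer, methods: dict,
              n_rep: int = 100, M: int = 5, B_boot: int = 1000,
              families: tuple[str, ...] = ("timing", "duration", "sequencing"),
              truth: str = "original", seed: int | None = None,
              rare_floor: float = 0.0, cache_dir=None,
              ) -> dict[str, pd.DataFrame]:
    """Full comparison engine.

    Parameters
    ----------
    complete_panel : SequencePanel
        The complete source panel; its estimand values are the truth
        (``truth="original"``) unless ``truth="per_resample"`` scores
        each repetition against its own resample.
    amputer : estimator with a ``transform(panel)`` method and a
        ``random_state`` attribute.
    methods : dict name -> imputer (``impute(panel, M)`` with a
        ``random_state`` attribute, or an :class:`OracleImputer`).
    n_rep, M, B_boot : study sizes.
    families : estimand families to score.
    seed : master seed; every repetition/method stream derives from it.
    rare_floor : timing estimands whose true frequency is below this
        floor are excluded (their coverage is degenerate); 0 keeps all.
    cache_dir : optional directory for an on-disk per-repetition cache;
        reruns with the same seed and config resume from it.  Per-rep
        seeds derive from the master seed independently of execution
        order, so resumed runs match uninterrupted ones exactly.

    Returns a dict of per-method performance tables (one row per
    estimand): truth, bias, MCSE of bias, coverage, MCSE of coverage,
    empirical variance of the pooled estimates and mean model variance.
    """
    if not methods:
        raise ValueError("need at least one method")
    idx = estimand_index(complete_panel)
    all_est = estimands(complete_panel)["estimate"].to_numpy()
    keep_fam = idx["family"].isin(families).to_numpy()
    keep = keep_fam.copy()
    if rare_floor > 0:
        rare = (idx["family"] == "timing").to_numpy() & (all_est < rare_floor)
        keep &= ~rare
    # positions of kept estimands within the families-filtered frames
    # returned by bootstrap_variance
    sub_keep = keep[keep_fam]
    idx = idx[keep].reset_index(drop=True)
    d = len(idx)
    theta_full = all_est[keep]

    cache = None
    if cache_dir is not None:
        import pathlib
        cache = pathlib.Path(cache_dir)
        cache.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_rep)
    acc = {name: {"Q": [], "lo": [], "hi": [], "T": [], "theta": [],
                  "fail": 0} for name in methods}
    n = complete_panel.n
    for r in range(n_rep):
        rep_ss = rep_seeds[r]
        s_resample, s_ampute, *s_methods = rep_ss.spawn(2 + len(methods))
        rng = np.random.default_rng(s_resample)
        rows = rng.integers(0, n, size=n)
        resample = complete_panel.copy(data=complete_panel.data[rows])
        amputer.random_state = np.random.default_rng(s_ampute)
        incomplete = amputer.transform(resample)
        theta = theta_full if truth == "original" else \
            estimands(resample).loc[keep, "estimate"].to_numpy()
        for (name, method), s_m in zip(methods.items(), s_methods):
            cfile = None
            if cache is not None:
                cfile = cache / f"rep{r:04d}_{name}.npz"
                if cfile.exists():
                    z = np.load(cfile)
                    a = acc[name]
                    for key in ("Q", "lo", "hi", "T", "theta"):
                        a[key].append(z[key])
                    continue
            try:
                gen = np.random.default_rng(s_m)
                if getattr(method, "needs_truth", False):
                    panels = method.impute_with_truth(incomplete, resample, M)
                else:
                    method.random_state = int(gen.integers(2**31 - 1))
                    panels = method.impute(incomplete, M=M).panels
                Qs = np.empty((M, d))
                Ws = np.empty((M, d))
                for m, pnl in enumerate(panels):
                    bv = bootstrap_variance(pnl, B=B_boot, rng=gen,
                                            families=families)
                    Qs[m] = bv["estimate"].to_numpy()[sub_keep]
                    Ws[m] = bv["variance"].to_numpy()[sub_keep]
                Q, T, df, lo, hi = _rubin_pool_vector(Qs, Ws)
                a = acc[name]
                a["Q"].append(Q)
                a["lo"].append(lo)
                a["hi"].append(hi)
                a["T"].append(T)
                a["theta"].append(theta)
                if cfile is not None:
                    np.savez(cfile, Q=Q, lo=lo, hi=hi, T=T, theta=theta)
            except Exception:
                acc[name]["fail"] += 1
    out = {}
    for name, a in acc.items():
        used = len(a["Q"])
        if used == 0:
            raise RuntimeError(f"method {name!r} failed in every repetition")
        Q = np.stack(a["Q"])
        lo = np.stack(a["lo"])
        hi = np.stack(a["hi"])
        T = np.stack(a["T"])
        th = np.stack(a["theta"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bias = np.nanmean(Q - th, axis=0)
            mcse_bias = np.sqrt(np.nanvar(Q - th, axis=0, ddof=1) / used)
            covered = (lo <= th) & (th <= hi)
            ok = ~np.isnan(Q)
            n_ok = ok.sum(axis=0).astype(float)
            coverage = np.where(n_ok > 0,
                                np.where(ok, covered, False).sum(axis=0)
                                / np.maximum(n_ok, 1), np.nan)
            emp_var = np.nanvar(Q, axis=0, ddof=1)
            mean_T = np.nanmean(T, axis=0)
        mcse_cov = np.sqrt(coverage * (1 - coverage) / np.maximum(n_ok, 1))
        tab = idx.copy()
        tab["true_value"] = th[0] if truth == "original" else np.nanmean(th, axis=0)
        tab["bias"] = bias
        tab["mcse_bias"] = mcse_bias
        tab["coverage"] = coverage
        tab["mcse_coverage"] = mcse_cov
        tab["emp_variance"] = emp_var
        tab["mean_model_variance"] = mean_T
        tab["n_rep_used"] = used
        tab.attrs["failures"] = a["fail"]
        out[name] = tab
    return out


def summarize(perf_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per (method, family): mean absolute bias, the share of
    Monte Carlo intervals containing 0 bias, and the share containing
    the nominal 0.95 coverage."""
    rows = []
    for name, tab in perf_tables.items():
        for fam, g in tab.groupby("family"):
            g = g.dropna(subset=["bias"])
            if len(g) == 0:
                continue
            mab = float(g["bias"].abs().mean())
            bias_ok = (g["bias"].abs() <= 1.96 * g["mcse_bias"]).mean()
            cov_ok = ((g["coverage"] - 1.96 * g["mcse_coverage"] <= 0.95)
                      & (0.95 <= g["coverage"] + 1.96 * g["mcse_coverage"])
                      ).mean()
            rows.append({"method": name, "family": fam,
                         "mean_abs_bias": mab,
                         "prop_bias_ci_cover_zero": float(bias_ok),
                         "prop_cov_ci_cover_nominal": float(cov_ok),
                         "n_estimands": len(g)})
    return pd.DataFrame(rows)
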