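"""Seeded reproductions of the model-validation simulation experiments.

Each driver emits machine-readable tables (tidy DataFrames) and is
deterministic given its seed.  Default problem sizes are reduced relative to
the original large-scale simulations so that each experiment completes in
minutes on one CPU; the trends they assess are scale-free (see
docs/methods.md).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import ValidityWarning, approx_moments
from .dataset import PairObservations
from .fit import (bootstrap_rho_ci, classify_significance, fit_pair,
                  goodness_of_fit, independent_rog_fitter, pairwise_rog_fitter)
from .mapinf import _map_independent_vec, _solve_map_batch
from .simulate import (PRESET_CONTRASTS, _bvn, _draw_fig1_params, _rng,
                       _TUNING_RANGES, generate_parameter_grid, sample_trials)
from .tuning import build_pair_params

__all__ = [
    "exp_approximation_validation",
    "exp_normalization_vs_correlation",
    "exp_rho_inference",
    "exp_map_comparison",
    "exp_gof_vs_correlation",
    "save_validation_figure",
    "save_trend_figure",
]


# ---------------------------------------------------------------------------
# Moment-approximation validation (delta method vs Monte Carlo)
# ---------------------------------------------------------------------------

def exp_approximation_validation(n_experiments: int = 1000, n_trials: int = 100_000,
                                 seed: int = 0):
    """Compare closed-form moments against Monte-Carlo estimates.

    Draws pair-level parameters from the moment-validation preset, simulates
    ``n_trials`` responses per experiment, and reports the percent difference
    between the approximate and empirical covariance and correlation.

    Returns ``(table, summary)``: one row per experiment and a dict with the
    median percent differences.
    """
    rng = _rng(seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityWarning)
        for i in range(n_experiments):
            params = _draw_fig1_params(rng)
            m = approx_moments(params)
            R = sample_trials(params, n_trials, rng)
            emp_cov = float(np.cov(R.T, ddof=0)[0, 1])
            sd = R.std(axis=0, ddof=0)
            emp_corr = emp_cov / (sd[0] * sd[1])
            rows.append({
                "experiment": i,
                "cov_approx": m.cov_R, "cov_mc": emp_cov,
                "corr_approx": m.corr_R, "corr_mc": emp_corr,
                "cov_pct_diff": 100.0 * (m.cov_R - emp_cov) / abs(emp_cov)
                if emp_cov != 0 else np.nan,
                "corr_pct_diff": 100.0 * (m.corr_R - emp_corr) / abs(emp_corr)
                if emp_corr != 0 else np.nan,
            })
    table = pd.DataFrame(rows)
    summary = {
        "median_cov_pct_diff": float(np.nanmedian(table["cov_pct_diff"])) if len(table) else np.nan,
        "median_corr_pct_diff": float(np.nanmedian(table["corr_pct_diff"])) if len(table) else np.nan,
        "n_experiments": n_experiments, "n_trials": n_trials,
    }
    return table, summary


# ---------------------------------------------------------------------------
# Normalization strength vs noise correlation (binned-median trends)
# ---------------------------------------------------------------------------

def _draw_tuning_arrays(preset: str, n_pairs: int, rng) -> dict:
    r = _TUNING_RANGES[preset]
    return {
        "r_max": rng.uniform(*r["r_max"], size=(n_pairs, 2)),
        "epsilon": rng.uniform(*r["epsilon"], size=(n_pairs, 2)),
        "alpha_n": rng.uniform(*r["alpha"], size=(n_pairs, 2)),
        "beta_n": rng.uniform(*r["beta"], size=(n_pairs, 2)),
        "alpha_d": rng.uniform(*r["alpha"], size=(n_pairs, 2)),
        "beta_d": rng.uniform(*r["beta"], size=(n_pairs, 2)),
    }


def _simulate_corr_batch(arrs: dict, rho_n: float, rho_d: float, c: float,
                         n_trials: int, rng, chunk: int = 8000) -> np.ndarray:
    """Empirical noise correlation per pair at one contrast, vectorized.

    Processes pairs in chunks to bound peak memory at large grids.
    """
    mu_N_all = arrs["r_max"] * c**2
    mu_D_all = arrs["epsilon"] ** 2 + c**2
    sig_N_all = np.sqrt(arrs["alpha_n"] * mu_N_all ** arrs["beta_n"])
    sig_D_all = np.sqrt(arrs["alpha_d"] * mu_D_all ** arrs["beta_d"])
    P = len(mu_N_all)
    out = np.empty(P)
    for lo in range(0, P, chunk):
        sl = slice(lo, min(lo + chunk, P))
        n = sl.stop - sl.start
        N = _bvn(rng, mu_N_all[sl], sig_N_all[sl], np.full(n, rho_n), n_trials)
        D = _bvn(rng, mu_D_all[sl], sig_D_all[sl], np.full(n, rho_d), n_trials)
        R = N / D
        Rc = R - R.mean(axis=1, keepdims=True)
        cov = (Rc[..., 0] * Rc[..., 1]).mean(axis=1)
        sd = Rc.std(axis=1, ddof=0)
        denom = sd[:, 0] * sd[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sl] = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0),
                               np.nan)
    return out


def exp_normalization_vs_correlation(rho_pairs=((0.0, 0.5), (0.5, 0.0)),
                                     preset: str = "fig2", n_pairs: int = 4000,
                                     n_trials: int = 1000, contrasts=None,
                                     seed: int = 0, n_bins: int = 6,
                                     min_count: int = 100,
                                     quantile_bins: bool = False) -> pd.DataFrame:
    """Binned median noise correlation vs common normalization strength.

    For each (rho_N, rho_D) combination and contrast, pairs are binned by
    epsilon_1 x epsilon_2 (a contrast-independent measure of shared
    normalization strength; log-spaced bins by default) and the median
    simulated noise correlation is reported per bin; bins with fewer than
    ``min_count`` pairs are discarded.  ``quantile_bins`` switches to
    equal-count bins, which equalizes the medians' sampling error across the
    normalization-strength axis (the log-spaced edges leave the extreme bins
    sparse under uniform epsilon draws).
    """
    if contrasts is None:
        contrasts = PRESET_CONTRASTS["fig2"]
    rng = _rng(seed)
    arrs = _draw_tuning_arrays(preset, n_pairs, rng)
    eps_prod = arrs["epsilon"][:, 0] * arrs["epsilon"][:, 1]
    lo, hi = _TUNING_RANGES[preset]["epsilon"]
    if quantile_bins:
        edges = np.quantile(eps_prod, np.linspace(0.0, 1.0, n_bins + 1))
        edges[0], edges[-1] = lo**2, hi**2
    else:
        edges = np.geomspace(lo**2, hi**2, n_bins + 1)
    which = np.clip(np.digitize(eps_prod, edges) - 1, 0, n_bins - 1)
    rows = []
    for rho_n, rho_d in rho_pairs:
        for c in contrasts:
            corr = _simulate_corr_batch(arrs, rho_n, rho_d, float(c), n_trials, rng)
            for b in range(n_bins):
                sel = which == b
                if sel.sum() < min_count:
                    continue
                rows.append({
                    "rho_n": rho_n, "rho_d": rho_d, "contrast": float(c),
                    "bin": b, "eps_product": float(np.sqrt(edges[b] * edges[b + 1])),
                    "median_corr": float(np.nanmedian(corr[sel])),
                    "n_pairs": int(sel.sum()),
                })
    return pd.DataFrame(rows, columns=["rho_n", "rho_d", "contrast", "bin",
                                       "eps_product", "median_corr", "n_pairs"])


# ---------------------------------------------------------------------------
# Accuracy of coupling-correlation inference (coverage + sign recovery)
# ---------------------------------------------------------------------------

def _simulate_observations(tuning, contrasts, n_trials: int, rng) -> PairObservations:
    responses = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityWarning)
        for c in contrasts:
            params = build_pair_params(tuning, float(c))
            responses.append(sample_trials(params, n_trials, rng))
    contrasts = np.asarray(contrasts, dtype=float)
    return PairObservations(0, contrasts, np.full(len(contrasts), n_trials),
                            responses)


def exp_rho_inference(n_pairs: int = 300, n_trials: int = 500, n_boot: int = 200,
                      seed: int = 0, level: float = 0.9, contrasts=None,
                      cv=2, bootstrap_mode: str = "full",
                      window_width: float = 0.4, window_step: float = 0.2):
    """Coverage and sign-recovery study for the coupling correlations.

    Generates pairs from the inference preset (uniform tuning draws,
    rho_N, rho_D ~ U[-0.9, 0.9]), fits the pairwise model, bootstraps
    percentile CIs at ``level``, and scores: empirical coverage, the
    sign agreement of significant estimates (CI excludes 0 and pairwise
    cross-validated fit beats the independent fit), and fit-vs-true
    correlations.

    Returns ``(table, summary)`` where ``summary`` also carries a sliding-
    window coverage table (window 0.4, step 0.2 over the true rho).
    """
    if contrasts is None:
        contrasts = PRESET_CONTRASTS["fig3"]
    grid = generate_parameter_grid("fig3", n_pairs, seed)
    rows = []
    for i, tuning in enumerate(grid.draws):
        rng = np.random.default_rng((seed, 1, i))
        obs = _simulate_observations(tuning, contrasts, n_trials, rng)
        fit = fit_pair(obs, seed=i, fix_rho_eta=True)
        gof_pair = goodness_of_fit(obs, pairwise_rog_fitter(seed=i), cv=cv, seed=i)
        gof_ind = goodness_of_fit(obs, independent_rog_fitter(seed=i), cv=cv, seed=i)
        boot = bootstrap_rho_ci(obs, n_boot=n_boot, level=level,
                                seed=int(np.random.default_rng((seed, 2, i)).integers(2**31)),
                                mode=bootstrap_mode, point_fit=fit)
        sig = classify_significance(boot, gof_pair.score, gof_ind.score)
        rows.append({
            "pair": i,
            "rho_n_true": tuning.rho_n, "rho_d_true": tuning.rho_d,
            "rho_n_fit": fit.tuning.rho_n, "rho_d_fit": fit.tuning.rho_d,
            "ci_n_lo": boot.ci_n[0], "ci_n_hi": boot.ci_n[1],
            "ci_d_lo": boot.ci_d[0], "ci_d_hi": boot.ci_d[1],
            "covered_n": bool(boot.ci_n[0] <= tuning.rho_n <= boot.ci_n[1]),
            "covered_d": bool(boot.ci_d[0] <= tuning.rho_d <= boot.ci_d[1]),
            "gof_pairwise": gof_pair.score, "gof_independent": gof_ind.score,
            "significant_n": sig["rho_n"], "significant_d": sig["rho_d"],
            "n_boot_skipped": boot.n_skipped,
        })
    table = pd.DataFrame(rows)
    summary = _rho_inference_summary(table, level, window_width, window_step)
    return table, summary


def _sign_agreement(table: pd.DataFrame, which: str) -> float:
    sel = table[table[f"significant_{which}"]]
    if sel.empty:
        return float("nan")
    return float(np.mean(np.sign(sel[f"rho_{which}_fit"])
                         == np.sign(sel[f"rho_{which}_true"])))


def _rho_inference_summary(table, level, window_width, window_step) -> dict:
    centers = np.arange(-0.9 + window_width / 2, 0.9 - window_width / 2 + 1e-9,
                        window_step)
    win_rows = []
    for which in ("n", "d"):
        for ctr in centers:
            sel = table[np.abs(table[f"rho_{which}_true"] - ctr) <= window_width / 2]
            if sel.empty:
                continue
            win_rows.append({"rho": which, "center": float(ctr),
                             "coverage": 100.0 * float(sel[f"covered_{which}"].mean()),
                             "n": len(sel)})
    out = {
        "nominal_level": 100.0 * level,
        "coverage_n": 100.0 * float(table["covered_n"].mean()),
        "coverage_d": 100.0 * float(table["covered_d"].mean()),
        "sign_agreement_n": _sign_agreement(table, "n"),
        "sign_agreement_d": _sign_agreement(table, "d"),
        "n_significant_n": int(table["significant_n"].sum()),
        "n_significant_d": int(table["significant_d"].sum()),
        "corr_fit_true_n_all": float(np.corrcoef(table["rho_n_fit"], table["rho_n_true"])[0, 1]),
        "corr_fit_true_d_all": float(np.corrcoef(table["rho_d_fit"], table["rho_d_true"])[0, 1]),
        "windowed_coverage": pd.DataFrame(win_rows),
        "n_pairs": len(table),
    }
    for which in ("n", "d"):
        sel = table[table[f"significant_{which}"]]
        out[f"corr_fit_true_{which}_significant"] = (
            float(np.corrcoef(sel[f"rho_{which}_fit"], sel[f"rho_{which}_true"])[0, 1])
            if len(sel) > 2 else float("nan"))
    return out


# ---------------------------------------------------------------------------
# Pairwise vs independent single-trial normalization estimators
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def exp_map_comparison(rho_values=(-0.8, -0.4, 0.0, 0.4, 0.8),
                       n_pairs_per_cell: int = 20, n_trials: int = 200,
                       contrasts=None, seed: int = 0) -> pd.DataFrame:
    """Pairwise vs independent MAP recovery of the latent normalization.

    For every (rho_N, rho_D) cell and contrast, simulates pairs with recorded
    latent denominators, runs both estimators with the generating parameters,
    and reports the median across pairs of the difference (pairwise minus
    independent) in z-scored mean squared error and in estimator-truth
    correlation (averaged over the two neurons; z-scoring across trials).
    """
    if contrasts is None:
        contrasts = PRESET_CONTRASTS["fig4"]
    rng = _rng(seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityWarning)
        for rho_n in rho_values:
            for rho_d in rho_values:
                grid = generate_parameter_grid(
                    "fig4", n_pairs_per_cell,
                    int(rng.integers(2**31)), rho=(rho_n, rho_d))
                mse_diff = {c: [] for c in contrasts}
                corr_diff = {c: [] for c in contrasts}
                for tuning in grid.draws:
                    for c in contrasts:
                        params = build_pair_params(tuning, float(c))
                        R, D = sample_trials(params, n_trials, rng, return_latents=True)
                        d_pair, _, _ = _solve_map_batch(R, params)
                        r = R - params.mu_eta
                        d_ind = np.column_stack([
                            _map_independent_vec(r[:, i], params.mu_N[i],
                                                 params.sigma_N[i], params.mu_D[i],
                                                 params.sigma_D[i])
                            for i in range(2)])
                        mses, corrs = [], []
                        for est in (d_pair, d_ind):
                            mse_i, corr_i = [], []
                            for i in range(2):
                                zt = _zscore(D[:, i])
                                ze = _zscore(est[:, i])
                                mse_i.append(np.mean((ze - zt) ** 2))
                                corr_i.append(np.corrcoef(est[:, i], D[:, i])[0, 1])
                            mses.append(np.mean(mse_i))
                            corrs.append(np.mean(corr_i))
                        mse_diff[c].append(mses[0] - mses[1])
                        corr_diff[c].append(corrs[0] - corrs[1])
                for c in contrasts:
                    rows.append({
                        "rho_n": rho_n, "rho_d": rho_d, "contrast": float(c),
                        "mse_diff_median": float(np.median(mse_diff[c])),
                        "corr_diff_median": float(np.median(corr_diff[c])),
                        "n_pairs": n_pairs_per_cell,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise vs independent goodness of fit as correlations grow
# ---------------------------------------------------------------------------

def exp_gof_vs_correlation(n_pairs: int = 100, n_trials: int = 200, seed: int = 0,
                           cv=2, contrasts=None) -> pd.DataFrame:
    """Paired cross-validated goodness of fit against generating correlation size.

    Simulates inference-preset pairs, computes both models' cross-validated
    scores on the same splits, and tags each pair with the mean absolute model
    noise correlation across contrasts (from the closed-form moments).
    """
    if contrasts is None:
        contrasts = PRESET_CONTRASTS["fig3"]
    grid = generate_parameter_grid("fig3", n_pairs, seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityWarning)
        for i, tuning in enumerate(grid.draws):
            rng = np.random.default_rng((seed, 3, i))
            obs = _simulate_observations(tuning, contrasts, n_trials, rng)
            model_corr = np.mean([
                abs(approx_moments(build_pair_params(tuning, float(c))).corr_R)
                for c in contrasts])
            gof_pair = goodness_of_fit(obs, pairwise_rog_fitter(seed=i), cv=cv, seed=i)
            gof_ind = goodness_of_fit(obs, independent_rog_fitter(seed=i), cv=cv, seed=i)
            rows.append({
                "pair": i, "rho_n_true": tuning.rho_n, "rho_d_true": tuning.rho_d,
                "abs_model_corr": float(model_corr),
                "gof_pairwise": gof_pair.score, "gof_independent": gof_ind.score,
                "gof_diff": gof_pair.score - gof_ind.score,
            })
    return pd.DataFrame(rows)

# ---------------------------------------------------------------------------
# Optional figures (matplotlib imported lazily)
# ---------------------------------------------------------------------------

def save_validation_figure(table: pd.DataFrame, path) -> None:
    """Scatter + percent-difference histograms for the moment-validation run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    for row, stat in enumerate(("cov", "corr")):
        ax = axes[row, 0]
        ax.plot(table[f"{stat}_mc"], table[f"{stat}_approx"], ".", ms=2, alpha=0.4)
        lim = ax.get_xlim()
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel(f"Monte-Carlo {stat}")
        ax.set_ylabel(f"approximate {stat}")
        ax = axes[row, 1]
        vals = table[f"{stat}_pct_diff"].clip(-25, 25)
        ax.hist(vals, bins=60, color="tab:gray")
        ax.axvline(float(np.nanmedian(table[f"{stat}_pct_diff"])), color="tab:red")
        ax.set_xlabel(f"{stat} percent difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_trend_figure(table: pd.DataFrame, path) -> None:
    """Binned median noise correlation vs normalization strength, per coupling."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    combos = sorted(set(zip(table.rho_n, table.rho_d)))
    fig, axes = plt.subplots(1, len(combos), figsize=(4 * len(combos), 3.2),
                             squeeze=False)
    for ax, (rn, rd) in zip(axes[0], combos):
        sub = table[(table.rho_n == rn) & (table.rho_d == rd)]
        for c, grp in sub.groupby("contrast"):
            ax.semilogx(grp.eps_product, grp.median_corr, "o-", ms=4,
                        label=f"{c:g}%")
        ax.set_title(f"rho_N={rn:g}, rho_D={rd:g}")
        ax.set_xlabel("epsilon_1 x epsilon_2")
        ax.set_ylabel("median noise correlation")
    axes[0, -1].legend(title="contrast", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
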