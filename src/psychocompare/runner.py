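"""Full in-silico replications: cohort -> three procedures -> fits -> analytics.

One replication emulates one experiment's session structure: every simulated
observer runs the Bayesian adaptive procedure (64 trials), the
constant-stimuli block (180-184 trials), and the interleaved staircase
(<= 150 trials), in a counterbalanced order that defines the block factor
(1st/2nd/3rd procedure of the session). Each procedure's trials are fitted
with the shared psychometric model; the staircase additionally yields the
conventional last-five-reversals threshold, and the adaptive runs carry the
sd-ceiling exclusion flag. The analytics stage screens outliers, computes
pairwise correlations and Bland-Altman agreement for PSE and JND, and tests
for block-wise learning.

Everything is deterministic under the master seed: per-observer response
streams and per-procedure stimulus streams are derived seeds, and re-running
from a saved trial log reproduces the reports byte for byte.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .configs import ExperimentConfig, config_hash, get_experiment
from .constant_stimuli import build_design, run_cs
from .observers import CohortSpec, assigned_orders, sample_cohort
from .psychometric import fit_psychometric, records_to_frame
from .questplus import ParameterGrid, QuestState, run_questplus
from .staircase import conventional_threshold, run_staircase

__all__ = [
    "ResultsBundle",
    "run_replication",
    "analyze",
    "make_report",
    "simulate_block_jnds",
    "staircase_threshold_agreement",
    "questplus_recovery",
]

PROCEDURES = ("questplus", "cs", "staircase")
_PAIRS = tuple(itertools.combinations(PROCEDURES, 2))


def _proc_seed(master_seed: int, obs_index: int, proc: str) -> int:
    tag = {"questplus": 1, "cs": 2, "staircase": 3}[proc]
    return int(
        np.random.SeedSequence([master_seed, 7919, obs_index, tag]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class ResultsBundle:
    config: ExperimentConfig
    master_seed: int
    trials: pd.DataFrame
    estimates: pd.DataFrame
    observers: pd.DataFrame

    def provenance(self) -> dict:
        return {
            "experiment": self.config.experiment,
            "master_seed": self.master_seed,
            "config_sha256": config_hash(self.config),
            "package_version": __version__,
            "n_observers": int(self.observers.shape[0]),
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.estimates.to_csv(out / "estimates.csv", index=False)
        self.observers.to_csv(out / "observers.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance(), indent=2))


def run_replication(
    config: ExperimentConfig | int,
    n_observers: int = 20,
    master_seed: int = 0,
    drift: tuple[float, float, float] = (1.0, 1.0, 1.0),
    out_dir=None,
) -> ResultsBundle:
    """Simulate one complete experiment and fit every procedure's data."""
    if not isinstance(config, ExperimentConfig):
        config = get_experiment(config)
    spec = CohortSpec(
        config=config, n_observers=n_observers, master_seed=master_seed, drift=drift
    )
    cohort = sample_cohort(spec)
    orders = assigned_orders(n_observers)
    design = build_design(config.experiment)
    # the likelihood tables are the expensive part of the adaptive engine;
    # share them across observers through a template state
    grid = ParameterGrid(config.m_values, config.sd_values, config.lapse_values)
    template = QuestState(grid=grid, stimulus_domain=config.stimulus_domain)

    all_trials, estimate_rows, observer_rows = [], [], []
    for i, (observer, order) in enumerate(zip(cohort, orders)):
        observer_rows.append(
            {
                "observer_id": i,
                "true_m": observer.true_params.m,
                "true_sd": observer.true_params.sd,
                "true_lapse": observer.true_params.lapse,
                "order": "-".join(order),
                "rng_seed": observer.rng_seed,
            }
        )
        for block, proc in enumerate(order, start=1):
            seed = _proc_seed(master_seed, i, proc)
            extras: dict = {}
            if proc == "questplus":
                state = QuestState(
                    grid=grid,
                    stimulus_domain=config.stimulus_domain,
                    _tables=template._tables,
                )
                records, summaries = run_questplus(
                    observer, config, block=block, state=state
                )
                extras["ceiling"] = summaries["ceiling"]
                extras["post_mean_m"] = summaries["posterior_mean"]["m"]
                extras["post_mean_sd"] = summaries["posterior_mean"]["sd"]
            elif proc == "cs":
                records = run_cs(observer, design, seed=seed, block=block)
            else:
                records = run_staircase(
                    observer, config.staircase, seed=seed, block=block
                )
                conv = conventional_threshold(
                    records, config.staircase.reversals_for_threshold
                )
                extras["conventional_threshold"] = conv.value
            fit = fit_psychometric(records, bounds=config.fit_bounds)
            frame = records_to_frame(records)
            frame.insert(0, "observer_id", i)
            frame.insert(1, "experiment", config.experiment)
            all_trials.append(frame)
            estimate_rows.append(
                {
                    "observer_id": i,
                    "procedure": proc,
                    "block": block,
                    "pse": fit.pse,
                    "jnd": fit.jnd,
                    "m": fit.params.m,
                    "sd": fit.params.sd,
                    "lapse": fit.params.lapse,
                    "loglik": fit.log_likelihood,
                    "converged": fit.converged,
                    "n_trials": fit.n_trials,
                    "ceiling": extras.get("ceiling", False),
                    "conventional_threshold": extras.get(
                        "conventional_threshold", np.nan
                    ),
                    "post_mean_m": extras.get("post_mean_m", np.nan),
                    "post_mean_sd": extras.get("post_mean_sd", np.nan),
                }
            )
    bundle = ResultsBundle(
        config=config,
        master_seed=master_seed,
        trials=pd.concat(all_trials, ignore_index=True),
        estimates=pd.DataFrame(estimate_rows),
        observers=pd.DataFrame(observer_rows),
    )
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle


def analyze(bundle: ResultsBundle) -> dict:
    """The comparison analytics on one replication's estimates table.

    Excludes ceiling-flagged observers, screens PSE and JND outliers with
    the Sn criterion-3 rule (flags unioned across measures), then computes
    the 3 pairwise correlations and Bland-Altman agreements per measure,
    one-sample bias tests against the reference, and the block-wise
    repeated-measures learning analysis.
    """
    from .stats import (
        bland_altman,
        block_analysis,
        correlation,
        one_sample_bias,
        screen_outliers,
    )

    est = bundle.estimates
    ceiling_obs = set(est.loc[est["ceiling"], "observer_id"])
    est = est[~est["observer_id"].isin(ceiling_obs)]
    wide_pse = est.pivot(index="observer_id", columns="procedure", values="pse")
    wide_jnd = est.pivot(index="observer_id", columns="procedure", values="jnd")

    flagged: set = set()
    for wide in (wide_pse, wide_jnd):
        for proc in PROCEDURES:
            screen = screen_outliers(wide[proc].to_numpy())
            flagged |= set(wide.index[screen.flags])
    keep = [i for i in wide_pse.index if i not in flagged]
    wide_pse, wide_jnd = wide_pse.loc[keep], wide_jnd.loc[keep]

    report: dict = {
        "provenance": bundle.provenance(),
        "excluded": {"ceiling": sorted(ceiling_obs), "outliers": sorted(flagged)},
        "correlations": {},
        "agreement": {},
        "bias": {},
        "learning": {},
    }
    for measure, wide in (("pse", wide_pse), ("jnd", wide_jnd)):
        for a, b in _PAIRS:
            key = f"{measure}:{a}-{b}"
            corr = correlation(wide[a], wide[b])
            report["correlations"][key] = {
                "r": corr.r,
                "p": corr.p,
                "method": corr.method,
            }
            report["agreement"][key] = bland_altman(
                wide[a], wide[b], pair=(a, b)
            ).to_dict()
    for proc in PROCEDURES:
        report["bias"][f"pse:{proc}"] = one_sample_bias(
            wide_pse[proc], bundle.config.reference
        )
    blocks_pse = est.pivot(index="observer_id", columns="block", values="pse").loc[keep]
    blocks_jnd = est.pivot(index="observer_id", columns="block", values="jnd").loc[keep]
    report["learning"]["pse"] = block_analysis(blocks_pse.to_numpy()).to_dict()
    report["learning"]["jnd"] = block_analysis(blocks_jnd.to_numpy()).to_dict()
    return report


def make_report(bundle: ResultsBundle, out_dir, plots: bool = False) -> dict:
    """Write the analysis report (JSON + CSV tables, optional figures)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = analyze(bundle)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    rows = [
        {"comparison": key, **val} for key, val in report["correlations"].items()
    ]
    pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
    agree = [report["agreement"][k] | {"comparison": k} for k in report["agreement"]]
    pd.DataFrame(agree).to_csv(out / "agreement.csv", index=False)
    if plots:
        _write_plots(bundle, report, out)
    return report


def _write_plots(bundle: ResultsBundle, report: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = bundle.estimates
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, measure in zip(axes, ("pse", "jnd")):
        data = [est.loc[est["procedure"] == p, measure].dropna() for p in PROCEDURES]
        ax.boxplot(data, tick_labels=PROCEDURES)
        ax.set_title(measure.upper())
        ax.set_ylabel(bundle.config.units)
    fig.tight_layout()
    fig.savefig(out / "boxplots.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    wide = est.pivot(index="observer_id", columns="procedure", values="pse")
    for ax, (a, b) in zip(axes, _PAIRS):
        rep = report["agreement"][f"pse:{a}-{b}"]
        means = 0.5 * (wide[a] + wide[b])
        diffs = wide[a] - wide[b]
        ax.scatter(means, diffs, s=14)
        for y, style in ((rep["bias"], "-"), (rep["loa_low"], "--"), (rep["loa_high"], "--")):
            ax.axhline(y, linestyle=style, color="tab:green", lw=1)
        ax.set_title(f"{a} vs {b}")
        ax.set_xlabel(f"mean ({bundle.config.units})")
    axes[0].set_ylabel("difference")
    fig.tight_layout()
    fig.savefig(out / "bland_altman_pse.png", dpi=120)
    plt.close(fig)


def simulate_block_jnds(
    config: ExperimentConfig | int,
    n_observers: int = 21,
    master_seed: int = 0,
    drift: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Per-observer per-block JND estimates from one constant-stimuli run per block.

    A light-weight replication used for learning-effect calibration: each
    observer runs the CS design three times (blocks 1-3, drift applied to sd)
    and each block's trials are fitted separately. Returns (n_observers, 3).
    """
    if not isinstance(config, ExperimentConfig):
        config = get_experiment(config)
    spec = CohortSpec(
        config=config, n_observers=n_observers, master_seed=master_seed, drift=drift
    )
    cohort = sample_cohort(spec)
    design = build_design(config.experiment)
    out = np.empty((n_observers, 3))
    for i, observer in enumerate(cohort):
        for block in (1, 2, 3):
            seed = _proc_seed(master_seed, i, "cs") + block
            records = run_cs(observer, design, seed=seed, block=block)
            fit = fit_psychometric(records, bounds=config.fit_bounds)
            out[i, block - 1] = fit.jnd
    return out


def staircase_threshold_agreement(
    config: ExperimentConfig | int = 1,
    n_observers: int = 20,
    master_seed: int = 0,
) -> dict:
    """Correlate conventional and fitted staircase thresholds over a cohort.

    For each simulated observer the interleaved staircase is run once; the
    conventional estimate (mean of the last five reversals per track,
    averaged over tracks) and the threshold of the psychometric fit to the
    same trials are then correlated (Pearson) across observers — the
    classical sanity check that the cheap reversal-based estimate agrees
    with the model-based one.
    """
    if not isinstance(config, ExperimentConfig):
        config = get_experiment(config)
    spec = CohortSpec(config=config, n_observers=n_observers, master_seed=master_seed)
    cohort = sample_cohort(spec)
    conventional, fitted, true_m = [], [], []
    for i, observer in enumerate(cohort):
        records = run_staircase(
            observer, config.staircase, seed=_proc_seed(master_seed, i, "staircase")
        )
        conv = conventional_threshold(records, config.staircase.reversals_for_threshold)
        fit = fit_psychometric(records, bounds=config.fit_bounds)
        conventional.append(conv.value)
        fitted.append(fit.pse)
        true_m.append(observer.true_params.m)
    r = float(np.corrcoef(conventional, fitted)[0, 1])
    return {
        "r": r,
        "n": n_observers,
        "conventional": conventional,
        "fitted": fitted,
        "true_m": true_m,
    }


def questplus_recovery(
    config: ExperimentConfig | int = 1,
    n_observers: int = 100,
    master_seed: int = 0,
    n_trials: int = 64,
) -> dict:
    """Posterior-mean recovery of the observer mean across a seeded cohort.

    Runs the adaptive procedure once per observer and summarizes the error
    of the marginal posterior-mean m against the generating value: bias,
    RMSE, and the per-run errors (for downstream checks such as stimulus
    concentration near threshold).
    """
    if not isinstance(config, ExperimentConfig):
        config = get_experiment(config)
    spec = CohortSpec(config=config, n_observers=n_observers, master_seed=master_seed)
    cohort = sample_cohort(spec)
    grid = ParameterGrid(config.m_values, config.sd_values, config.lapse_values)
    template = QuestState(grid=grid, stimulus_domain=config.stimulus_domain)
    errors, near_fractions = [], []
    for observer in cohort:
        state = QuestState(
            grid=grid,
            stimulus_domain=config.stimulus_domain,
            _tables=template._tables,
        )
        records, summaries = run_questplus(
            observer, config, n_trials=n_trials, state=state
        )
        errors.append(summaries["posterior_mean"]["m"] - observer.true_params.m)
        m, sd = observer.true_params.m, observer.true_params.sd
        late = [rec.stimulus for rec in records[10:]]
        near_fractions.append(
            float(np.mean([abs(x - m) <= 2 * sd for x in late]))
        )
    errors = np.asarray(errors)
    return {
        "bias": float(errors.mean()),
        "rmse": float(np.sqrt(np.mean(errors**2))),
        "median_abs_error": float(np.median(np.abs(errors))),
        "errors": errors.tolist(),
        "near_threshold_fraction": float(np.mean(near_fractions)),
        "n": n_observers,
        "n_trials": n_trials,
    }
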