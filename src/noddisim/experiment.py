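"""Full simulation experiment: grid x protocols x SNR, summaries, comparisons.

Runs the ground-truth tissue grid (ICVF x kappa at FISO = 0) through
signal synthesis, Rician noise injection, and NODDI fitting for every
protocol, SNR level, fiber orientation, and noise trial; aggregates the
long-format results into per-condition mean +- std summaries; and tests
scheme equivalence with a paired comparison of matched estimates.

Per-condition noise seeds are derived deterministically from the master
seed and the full condition tuple, so results are identical regardless
of execution order or worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .schemes import build_protocol, derive_seed, uniform_sphere_directions
from .forward_model import TissueParams, odi_from_kappa, synthesize_signal
from .noise import NoiseSpec, add_rician_noise
from .fitting import FitOptions, fit_noddi

__all__ = [
    "ExperimentConfig",
    "desk_preset",
    "run_experiment",
    "aggregate",
    "compare_schemes",
    "load_roi_reference",
    "roi_reference_row",
    "render_summary_figures",
]

_ESTIMATE_COLUMNS = ("icvf_est", "odi_est", "fiso_est")

RECORD_COLUMNS = (
    "protocol",
    "snr",
    "icvf_true",
    "kappa_true",
    "odi_true",
    "fiso_true",
    "orientation_id",
    "trial",
    "icvf_est",
    "odi_est",
    "fiso_est",
    "converged",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one simulation run (defaults reproduce the full study)."""

    protocols: tuple[str, ...] = ("NODDI-p14", "p12", "p123", "p1234", "p12345")
    snr_levels: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0, math.inf)
    icvf_grid: tuple[float, ...] = (0.2, 0.4, 0.5, 0.8)
    kappa_grid: tuple[float, ...] = (0.0, 0.25, 1.0, 4.0, 16.0)
    fiso_true: float = 0.0
    n_orientations: int = 250
    n_trials: int = 30
    master_seed: int = 0
    #: objective for noisy fits; noise-free (infinite-SNR) levels always
    #: use least squares, where the two objectives coincide.  Rician MLE
    #: is the default because magnitude noise at the outermost shell
    #: (SNR ~ 2 at SNR_b0=20) otherwise biases the high-b protocols.
    objective: str = "rician-likelihood"

    def n_records(self) -> int:
        return (
            len(self.protocols)
            * len(self.snr_levels)
            * len(self.icvf_grid)
            * len(self.kappa_grid)
            * self.n_orientations
            * self.n_trials
        )

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("protocols", "snr_levels", "icvf_grid", "kappa_grid"):
            if key in d:
                d[key] = tuple(
                    math.inf if v in ("inf", "infinity", "Infinity") else v
                    for v in d[key]
                )
        return cls(**d)


def desk_preset(
    snr_levels: tuple[float, ...] = (20.0, 30.0), master_seed: int = 0
) -> ExperimentConfig:
    """Scaled-down design for desk/CI runs: the high-ICVF, mid-dispersion
    corner of the grid (the regime reported for white matter), 50
    orientations, 5 trials, reference vs full-HYDI protocols."""
    return ExperimentConfig(
        protocols=("NODDI-p14", "p12345"),
        snr_levels=snr_levels,
        icvf_grid=(0.5, 0.8),
        kappa_grid=(1.0, 4.0),
        n_orientations=50,
        n_trials=5,
        master_seed=master_seed,
    )


def run_experiment(
    config: ExperimentConfig,
    progress: bool = False,
    orientations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the full condition product and return the long-format table.

    One fiber-orientation set (seeded from the master seed) is shared by
    all conditions.  Noise-free signals are cached per (protocol,
    tissue, orientation); at infinite SNR all trials of a condition are
    identical, so the fit is computed once and replicated.  A failed fit
    is recorded with ``converged=False`` and the run continues.
    """
    if orientations is None:
        orientations = uniform_sphere_directions(
            config.n_orientations, seed=derive_seed(config.master_seed, "orientations")
        )
    else:
        orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
        if len(orientations) != config.n_orientations:
            raise ValueError("orientations length must equal config.n_orientations")
    schemes = {p: build_protocol(p, seed=config.master_seed) for p in config.protocols}

    records: list[tuple] = []
    n_total = config.n_records()
    done = 0
    for pname, scheme in schemes.items():
        for icvf in config.icvf_grid:
            for kappa in config.kappa_grid:
                odi_true = odi_from_kappa(kappa)
                for oid, mu in enumerate(orientations):
                    tissue = TissueParams(
                        f_ic=icvf, kappa=kappa, f_iso=config.fiso_true, mu=tuple(mu)
                    )
                    clean = synthesize_signal(tissue, scheme)
                    for snr in config.snr_levels:
                        inf_fit = None
                        for trial in range(config.n_trials):
                            seed = derive_seed(
                                config.master_seed, pname, snr, icvf, kappa, oid, trial
                            )
                            if math.isinf(snr):
                                if inf_fit is None:
                                    inf_fit = _safe_fit(clean, config, seed, snr)
                                fit = inf_fit
                            else:
                                noisy = add_rician_noise(clean, NoiseSpec(snr, seed=seed))
                                fit = _safe_fit(noisy, config, seed, snr)
                            records.append(
                                (
                                    pname,
                                    snr,
                                    icvf,
                                    kappa,
                                    odi_true,
                                    config.fiso_true,
                                    oid,
                                    trial,
                                    *fit,
                                )
                            )
                            done += 1
                    if progress and done % 500 < config.n_trials * len(
                        config.snr_levels
                    ):
                        print(f"  {done}/{n_total} fits", flush=True)
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def _safe_fit(signal, config: ExperimentConfig, seed: int, snr: float):
    """(icvf_est, odi_est, fiso_est, converged); never raises."""
    objective = config.objective
    if objective == "rician-likelihood" and math.isinf(snr):
        objective = "least-squares"  # Rician NLL degenerates at sigma=0
    try:
        fit = fit_noddi(
            signal,
            FitOptions(
                objective=objective,
                sigma=None if math.isinf(snr) else 1.0 / snr,
                seed=seed,
            ),
        )
        return (fit.params.f_ic, fit.odi, fit.params.f_iso, fit.converged)
    except Exception:
        return (np.nan, np.nan, np.nan, False)


def aggregate(results: pd.DataFrame, group_by: Sequence[str]) -> pd.DataFrame:
    """Mean and std of each estimate per (protocol, snr, *group_by).

    Pools across trials, orientations, and whichever truth parameters
    are not in ``group_by`` (the figure-caption convention).
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    for key in group_by:
        if key not in results.columns:
            raise KeyError(
                f"unknown group key {key!r}; available: {list(results.columns)}"
            )
    keys = ["protocol", "snr", *[k for k in group_by if k not in ("protocol", "snr")]]
    agg = results.groupby(keys, sort=True)[list(_ESTIMATE_COLUMNS)].agg(
        ["mean", "std"]
    )
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    # a single record has no sample std; report 0 (spread of one value)
    agg = agg.fillna(0.0)
    return agg.reset_index()


def compare_schemes(
    results: pd.DataFrame,
    a: str,
    b: str,
    metric: str = "icvf_est",
    snr: float = 20.0,
    method: str = "t",
) -> dict:
    """Paired two-sided test of scheme equivalence.

    Pairs the ``metric`` estimates of protocols ``a`` and ``b`` at the
    given SNR by (truth condition, orientation, trial) and applies a
    paired t-test (default) or a Wilcoxon signed-rank test.

    Returns a dict with the statistic, p-value, number of pairs, and the
    mean paired difference (a minus b).
    """
    from scipy import stats

    if metric not in _ESTIMATE_COLUMNS:
        raise KeyError(f"metric must be one of {_ESTIMATE_COLUMNS}, got {metric!r}")
    keys = ["icvf_true", "kappa_true", "fiso_true", "orientation_id", "trial"]
    sel = results[results["snr"] == snr]
    ta = sel[sel["protocol"] == a][keys + [metric]]
    tb = sel[sel["protocol"] == b][keys + [metric]]
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError(f"protocols {a!r}/{b!r} not both present at snr={snr}")
    merged = ta.merge(tb, on=keys, suffixes=("_a", "_b"), validate="one_to_one")
    if len(merged) != len(ta) or len(merged) != len(tb):
        raise ValueError("condition tuples of the two protocols do not match 1:1")
    xa = merged[f"{metric}_a"].to_numpy()
    xb = merged[f"{metric}_b"].to_numpy()
    if a == b:
        return {
            "statistic": 0.0,
            "p_value": 1.0,
            "n_pairs": len(merged),
            "mean_difference": 0.0,
        }
    if method == "t":
        res = stats.ttest_rel(xa, xb)
    elif method == "wilcoxon":
        res = stats.wilcoxon(xa, xb)
    else:
        raise ValueError(f"method must be 't' or 'wilcoxon', got {method!r}")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_pairs": len(merged),
        "mean_difference": float(np.mean(xa - xb)),
    }


# ---------------------------------------------------------------------------
# packaged white-matter ROI reference (48 JHU ICBM-DTI-81 regions)


def load_roi_reference() -> pd.DataFrame:
    """Reference diffusion metrics in 48 white-matter ROIs.

    Mean and std across 52 healthy adults of DTI metrics (Da, Dr, MD in
    1e-6 mm^2/s; FA), the q-space zero-displacement probability Po, and
    the NODDI metrics ODI, ICVF, FISO.  These motivate 'realistic'
    simulation settings: white matter has high ICVF (~0.5-0.8) and low
    ODI (mostly < 0.35).
    """
    path = resources.files("noddisim.data").joinpath("jhu_wm_roi_reference.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    return df.set_index("roi")


def roi_reference_row(roi: str) -> pd.Series:
    """One ROI's reference metrics; unknown labels list the valid ones."""
    df = load_roi_reference()
    if roi not in df.index:
        raise KeyError(
            f"unknown ROI {roi!r}; valid ROIs: {', '.join(df.index)}"
        )
    return df.loc[roi]


# ---------------------------------------------------------------------------
# figures


def render_summary_figures(summary: pd.DataFrame, out_dir: str) -> list[str]:
    """One figure per SNR level: estimate mean +- std per protocol and
    truth level, with the ground truth as a dashed line.

    ``summary`` must come from :func:`aggregate` grouped by
    ``icvf_true`` and ``kappa_true``.  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    needed = {"protocol", "snr", "icvf_true", "kappa_true"}
    if not needed <= set(summary.columns):
        raise ValueError(f"summary must be grouped by {sorted(needed)}")
    protocols = sorted(summary["protocol"].unique())
    if not protocols:
        raise ValueError("summary contains no protocols")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    panels = [
        ("icvf_est", "icvf_true", "ICVF"),
        ("odi_est", "kappa_true", "ODI"),
        ("fiso_est", "icvf_true", "FISO"),
    ]
    for snr in sorted(summary["snr"].unique()):
        sub = summary[summary["snr"] == snr]
        levels = {key: sorted(sub[key].unique()) for _, key, _ in panels}
        ncols = max(len(v) for v in levels.values())
        fig, axes = plt.subplots(
            3, ncols, figsize=(3.0 * ncols, 8.0), squeeze=False
        )
        for row, (est, truth_key, label) in enumerate(panels):
            for col, level in enumerate(levels[truth_key]):
                ax = axes[row][col]
                cell = sub[sub[truth_key] == level]
                means = [
                    cell[cell["protocol"] == p][f"{est}_mean"].mean()
                    for p in protocols
                ]
                stds = [
                    cell[cell["protocol"] == p][f"{est}_std"].mean()
                    for p in protocols
                ]
                x = np.arange(len(protocols))
                ax.errorbar(x, means, yerr=stds, fmt="o", capsize=3)
                truth_val = {
                    "icvf_est": level,
                    "odi_est": odi_from_kappa(level) if truth_key == "kappa_true" else level,
                    "fiso_est": 0.0,
                }[est]
                ax.axhline(truth_val, linestyle="--", color="gray")
                ax.set_xticks(x)
                ax.set_xticklabels(protocols, rotation=45, fontsize=7)
                ax.set_title(f"{label}, {truth_key}={level:g}", fontsize=8)
            for col in range(len(levels[truth_key]), ncols):
                axes[row][col].set_visible(False)
        snr_tag = "inf" if math.isinf(snr) else f"{snr:g}"
        fig.suptitle(f"SNR_b0 = {snr_tag}")
        fig.tight_layout()
        path = out / f"summary_snr{snr_tag}.png"
        fig.savefig(path, dpi=100, metadata={"Software": None})
        plt.close(fig)
        paths.append(str(path))
    return paths
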