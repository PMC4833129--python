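"""Rician noise injection at a b0-referenced SNR, and per-shell SNR reports.

MRI magnitude data with Gaussian channel noise of standard deviation
sigma in each quadrature channel follows a Rician distribution.  With
the b=0 signal normalized to S0 = 1, specifying the SNR at b=0 fixes
sigma = 1 / SNR_b0.  The per-measurement SNR at higher b is then the
(noise-free) attenuated signal divided by the same sigma, which is how
the per-shell SNR report is defined: deterministic, pooled over shell
directions, tissue-grid conditions, and fiber orientations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schemes import AcquisitionScheme
from .forward_model import SignalSet, TissueParams, synthesize_signal

__all__ = ["NoiseSpec", "add_rician_noise", "shell_snr_report"]

#: the simulated b0 SNR levels (math.inf = noise-free)
SNR_LEVELS = (20.0, 30.0, 40.0, 50.0, math.inf)


@dataclass(frozen=True)
class NoiseSpec:
    """SNR defined at b=0; sigma = 1/snr_b0 given S0 = 1."""

    snr_b0: float
    seed: int = 0

    def __post_init__(self):
        if not self.snr_b0 > 0:
            raise ValueError(f"snr_b0 must be positive, got {self.snr_b0}")

    @property
    def sigma(self) -> float:
        return 0.0 if math.isinf(self.snr_b0) else 1.0 / self.snr_b0


def add_rician_noise(signal: SignalSet, spec: NoiseSpec) -> SignalSet:
    """Replace each value S by sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma).

    Deterministic given the spec's seed; sigma = 0 (infinite SNR) returns
    the input values unchanged.
    """
    if np.any(signal.values < 0):
        raise ValueError("signal values must be nonnegative")
    sigma = spec.sigma
    if sigma == 0.0:
        return SignalSet(signal.scheme, signal.values.copy())
    rng = np.random.default_rng(spec.seed)
    n1, n2 = rng.normal(0.0, sigma, size=(2, len(signal)))
    noisy = np.sqrt((signal.values + n1) ** 2 + n2**2)
    return SignalSet(signal.scheme, noisy)


def shell_snr_report(
    snr_b0: float,
    protocol: AcquisitionScheme,
    grid: list[TissueParams] | None = None,
    orientations: np.ndarray | None = None,
) -> dict[float, tuple[float, float]]:
    """Effective per-shell SNR, pooled over directions x grid x orientations.

    The per-direction SNR is the noise-free signal divided by
    sigma = 1/snr_b0.  For each b-value shell, the mean and standard
    deviation are taken with equal weight over all directions in the
    shell, all tissue conditions in ``grid``, and all fiber
    ``orientations`` (each orientation overriding the grid tissue's mu).

    Returns
    -------
    dict mapping shell b-value -> (mean SNR, std SNR).
    """
    if not snr_b0 > 0:
        raise ValueError(f"snr_b0 must be positive, got {snr_b0}")
    if grid is None:
        grid = default_tissue_grid()
    if len(grid) == 0:
        raise ValueError("tissue grid must be nonempty")
    if orientations is None:
        orientations = np.array([[0.0, 0.0, 1.0]])
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))

    bvals = protocol.bvals
    shells = sorted(set(bvals.tolist()))
    # signals: (n_tissue * n_orient, n_meas)
    sigs = []
    for tissue in grid:
        for mu in orientations:
            t = TissueParams(
                f_ic=tissue.f_ic,
                kappa=tissue.kappa,
                f_iso=tissue.f_iso,
                mu=tuple(mu),
                d_par=tissue.d_par,
                d_iso=tissue.d_iso,
            )
            sigs.append(synthesize_signal(t, protocol).values)
    sig = np.vstack(sigs)
    if math.isinf(snr_b0):
        raise ValueError("per-shell SNR is undefined at infinite snr_b0")
    snr = sig * snr_b0  # S / sigma
    report: dict[float, tuple[float, float]] = {}
    for b in shells:
        vals = snr[:, bvals == b].ravel()
        report[b] = (float(vals.mean()), float(vals.std()))
    return report


def default_tissue_grid(
    icvf_grid=(0.2, 0.4, 0.5, 0.8),
    kappa_grid=(0.0, 0.25, 1.0, 4.0, 16.0),
    fiso: float = 0.0,
) -> list[TissueParams]:
    """The simulated ground-truth tissue grid (ICVF x kappa, FISO fixed)."""
    return [
        TissueParams(f_ic=f, kappa=k, f_iso=fiso)
        for f in icvf_grid
        for k in kappa_grid
    ]
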