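"""NODDI three-compartment diffusion signal model.

The normalized signal for a measurement (b, g) is the convex combination

    E = (1 - f_iso) * [ f_ic * E_ic + (1 - f_ic) * E_ec ] + f_iso * E_iso

of three compartments:

* **Intracellular** (restricted): sticks (zero radial diffusivity) with
  axial diffusivity ``d_par``, orientation-dispersed by a Watson
  distribution W(n; mu, kappa) ~ exp(kappa (mu.n)^2):

      E_ic = Int W(n) exp(-b d_par (g.n)^2) dn

* **Extracellular** (hindered): Gaussian tensor with the same Watson
  orientation average, axial diffusivity d_par and tortuosity-linked
  radial diffusivity d_perp = d_par (1 - f_ic):

      E_ec = exp(-b g^T <D> g),
      <D>  = (d_par - d_perp) <n n^T>_W + d_perp I

  where <n n^T>_W has eigenvalue tau1(kappa) along mu and
  (1 - tau1)/2 perpendicular.

* **Isotropic** (free water): E_iso = exp(-b d_iso).

The Watson-stick integral E_ic is evaluated by a Funk-Hecke / Legendre
expansion: both the Watson density and the stick kernel exp(-a t^2) are
axially symmetric, so

    E_ic = sum_{l even} (2l+1)/(4 Z) * I_W(l) * I_K(l) * P_l(g.mu)

with I_W(l) = Int_{-1}^{1} e^{kappa t^2} P_l(t) dt,
I_K(l) = Int_{-1}^{1} e^{-a t^2} P_l(t) dt, a = b d_par, and
Z = Int_0^1 e^{kappa t^2} dt the Watson normalization.  The 1-D
integrals are computed by fixed high-order Gauss-Legendre quadrature
(exponent shifted by kappa to avoid overflow); the expansion is checked
against a dense spherical-quadrature oracle elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

from .schemes import AcquisitionScheme

__all__ = [
    "D_PAR_DEFAULT",
    "D_ISO_DEFAULT",
    "TissueParams",
    "SignalSet",
    "watson_normalization",
    "watson_tau1",
    "odi_from_kappa",
    "kappa_from_odi",
    "SignalModel",
    "synthesize_signal",
]

#: intrinsic axial diffusivity of neurites, mm^2/s
D_PAR_DEFAULT = 1.7e-3
#: free-water (CSF-like) isotropic diffusivity, mm^2/s
D_ISO_DEFAULT = 3.0e-3

_UNIT_TOL = 1e-10

# Legendre expansion: even orders 0..L_MAX; quadrature nodes for the 1-D
# coefficient integrals.  Orders chosen so the expansion matches dense
# spherical quadrature to <1e-8 over b <= 9375 s/mm^2, kappa <= 64
# (worst-case truncation tail ~5e-9 at kappa=64, b*d_par=16).
_L_MAX = 32
_EVEN_L = np.arange(0, _L_MAX + 1, 2)
_N_QUAD = 192
_QNODES, _QWEIGHTS = np.polynomial.legendre.leggauss(_N_QUAD)
# P_l(t) at the quadrature nodes, shape (n_even_l, n_quad)
_PL_AT_NODES = eval_legendre(_EVEN_L[:, None], _QNODES[None, :])
# kappa above which the Watson density is treated as a delta at +-mu
# (relative error of the delta approximation is O(b*d_par/kappa) ~ 1e-3
# at the crossover, far above the kappa<=64 range the fits explore, and
# the quadrature below the crossover still resolves the density)
_KAPPA_STICK_LIMIT = 1e4


@dataclass(frozen=True)
class TissueParams:
    """NODDI tissue parameters.

    f_ic : intracellular volume fraction (of the non-free-water tissue)
    kappa : Watson concentration (>= 0; larger = less dispersion)
    f_iso : free-water volume fraction
    mu : unit fiber direction
    d_par, d_iso : fixed diffusivities, mm^2/s
    """

    f_ic: float
    kappa: float
    f_iso: float
    mu: tuple[float, float, float] = (0.0, 0.0, 1.0)
    d_par: float = D_PAR_DEFAULT
    d_iso: float = D_ISO_DEFAULT

    def __post_init__(self):
        if not (0.0 <= self.f_ic <= 1.0):
            raise ValueError(f"f_ic must be in [0, 1], got {self.f_ic}")
        if not (0.0 <= self.f_iso <= 1.0):
            raise ValueError(f"f_iso must be in [0, 1], got {self.f_iso}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be nonnegative, got {self.kappa}")
        norm = float(np.linalg.norm(self.mu))
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"fiber direction must be unit length, |mu|={norm}")
        # snap to exact unit length for downstream dot products
        object.__setattr__(
            self, "mu", tuple(np.asarray(self.mu, dtype=float) / norm)
        )

    @property
    def odi(self) -> float:
        return odi_from_kappa(self.kappa)


@dataclass(frozen=True)
class SignalSet:
    """Normalized signal values aligned 1:1 with a scheme's measurements."""

    scheme: AcquisitionScheme
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.scheme),):
            raise ValueError(
                f"signal length {vals.shape} does not match scheme "
                f"({len(self.scheme)} measurements)"
            )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path: str) -> None:
        bvals = self.scheme.bvals
        bvecs = self.scheme.bvecs
        with open(path, "w") as fh:
            fh.write("index,b,gx,gy,gz,value\n")
            for i, (b, g, v) in enumerate(zip(bvals, bvecs, self.values)):
                fh.write(
                    f"{i},{b:.10g},{g[0]:.10g},{g[1]:.10g},{g[2]:.10g},{v:.12g}\n"
                )

    @classmethod
    def from_csv(cls, path: str, scheme: AcquisitionScheme) -> "SignalSet":
        vals = np.loadtxt(path, delimiter=",", skiprows=1, usecols=5, ndmin=1)
        return cls(scheme, vals)


# ---------------------------------------------------------------------------
# Watson distribution helpers


def _watson_shifted_weights(kappa: float) -> np.ndarray:
    """exp(kappa (t^2 - 1)) * GL weights at the quadrature nodes."""
    return _QWEIGHTS * np.exp(kappa * (_QNODES**2 - 1.0))


def watson_normalization(kappa: float) -> float:
    """Spherical mean of the unnormalized Watson density.

    Z(kappa) = (1/4pi) Int_{S^2} exp(kappa (mu.n)^2) dn
             = Int_0^1 exp(kappa t^2) dt,

    so W(n) = exp(kappa (mu.n)^2) / (4 pi Z) integrates to one.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be nonnegative, got {kappa}")
    if kappa == 0:
        return 1.0
    # Z = e^kappa * (1/2) Int_{-1}^{1} e^{kappa (t^2 - 1)} dt; the shifted
    # form keeps the quadrature in float range (Z itself overflows to inf
    # only beyond kappa ~ 709, where it genuinely exceeds float64)
    shifted = 0.5 * float(_watson_shifted_weights(kappa).sum())
    return shifted * float(np.exp(kappa))


def watson_tau1(kappa: float) -> float:
    """Mean-squared alignment tau1 = <(mu.n)^2> under Watson(mu, kappa).

    Equals Int_0^1 t^2 e^{kappa t^2} dt / Int_0^1 e^{kappa t^2} dt;
    1/3 at kappa=0, increasing to 1 as kappa -> infinity.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be nonnegative, got {kappa}")
    if kappa == 0:
        return 1.0 / 3.0
    if kappa > _KAPPA_STICK_LIMIT:
        # Laplace asymptote, relative error O(1/kappa^2)
        return 1.0 - 1.0 / kappa
    w = _watson_shifted_weights(kappa)
    num = float((w * _QNODES**2).sum())
    den = float(w.sum())
    return num / den


def odi_from_kappa(kappa: float) -> float:
    """Orientation dispersion index ODI = (2/pi) arctan(1/kappa).

    Maps kappa=0 to 1 (isotropic dispersion) by the limit convention and
    decreases strictly to 0 as kappa -> infinity.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be nonnegative, got {kappa}")
    if kappa == 0:
        return 1.0
    return float(2.0 / np.pi * np.arctan2(1.0, kappa))


def kappa_from_odi(odi: float) -> float:
    """Inverse of :func:`odi_from_kappa`; odi=1 maps to kappa=0."""
    if not (0.0 < odi <= 1.0):
        raise ValueError(f"ODI must be in (0, 1], got {odi}")
    return float(1.0 / np.tan(np.pi * odi / 2.0))


# ---------------------------------------------------------------------------
# compartment signals (vectorized over measurements)


def _watson_legendre_ratios(kappa: float) -> np.ndarray:
    """I_W(l) / (2 Z) for the even Legendre orders.

    Computed with the exponent shifted by -kappa so both numerator and
    denominator stay in float range for any kappa.
    """
    w = _watson_shifted_weights(kappa)
    iw = _PL_AT_NODES @ w            # shifted I_W(l)
    z2 = float(w.sum())              # shifted 2Z
    return iw / z2


def _stick_legendre_coeffs(a: float) -> np.ndarray:
    """I_K(l) = Int_{-1}^{1} exp(-a t^2) P_l(t) dt for even l."""
    k = _QWEIGHTS * np.exp(-a * _QNODES**2)
    return _PL_AT_NODES @ k


def _ic_signal(kappa: float, a: np.ndarray, cosg: np.ndarray) -> np.ndarray:
    """Watson-averaged stick signal for attenuations a=b*d_par and
    fiber-gradient cosines cosg (same shape)."""
    a = np.asarray(a, dtype=float)
    cosg = np.asarray(cosg, dtype=float)
    uniq_a, inv = np.unique(a, return_inverse=True)
    if kappa == 0:
        # isotropic dispersion: spherical mean of the stick, direction-free
        means = np.array(
            [0.5 * float((_QWEIGHTS * np.exp(-ai * _QNODES**2)).sum()) for ai in uniq_a]
        )
        return means[inv]
    if kappa > _KAPPA_STICK_LIMIT:
        return np.exp(-a * cosg**2)
    ratios = _watson_legendre_ratios(kappa)                    # (n_l,)
    pl_cos = eval_legendre(_EVEN_L[:, None], cosg[None, :])    # (n_l, n)
    coeff_u = np.stack([_stick_legendre_coeffs(float(ai)) for ai in uniq_a], axis=1)
    coeffs = coeff_u[:, inv]                                   # (n_l, n)
    vals = (
        (2 * _EVEN_L + 1)[:, None] / 2.0 * ratios[:, None] * coeffs * pl_cos
    ).sum(axis=0)
    return vals


def _ec_signal(
    f_ic: float, kappa: float, d_par: float, b: np.ndarray, cosg: np.ndarray
) -> np.ndarray:
    """Hindered tensor signal with tortuosity d_perp = d_par (1 - f_ic)."""
    d_perp = d_par * (1.0 - f_ic)
    tau1 = watson_tau1(kappa)
    c2 = cosg**2
    # g^T <D> g with eigenvalue tau1 along mu, (1-tau1)/2 perpendicular
    d_eff = d_perp + (d_par - d_perp) * (
        tau1 * c2 + 0.5 * (1.0 - tau1) * (1.0 - c2)
    )
    return np.exp(-b * d_eff)


class SignalModel:
    """Per-scheme forward-model evaluator with precomputed geometry.

    Caches everything that depends on the scheme alone (unique b-values,
    stick Legendre coefficients at a = b*d_par, the isotropic
    attenuations), so repeated evaluation inside an optimizer costs one
    Watson-coefficient quadrature plus small matrix products per call.
    Agrees with :func:`synthesize_signal` to floating-point rounding
    (same expansion, different summation order).
    """

    def __init__(
        self,
        scheme: AcquisitionScheme,
        d_par: float = D_PAR_DEFAULT,
        d_iso: float = D_ISO_DEFAULT,
    ):
        self.scheme = scheme
        self.d_par = d_par
        self.d_iso = d_iso
        b = scheme.bvals
        self._dw = b > 0
        self._b = b[self._dw]
        self._g = scheme.bvecs[self._dw]
        self._n = len(b)
        uniq_a, self._inv = np.unique(self._b * d_par, return_inverse=True)
        self._uniq_a = uniq_a
        # stick coefficients I_K(l) per unique attenuation, (n_l, n_uniq)
        self._coeff_u = np.stack(
            [_stick_legendre_coeffs(float(a)) for a in uniq_a], axis=1
        )
        # spherical mean of the stick per unique attenuation (kappa=0 case)
        self._iso_stick_u = 0.5 * self._coeff_u[0]
        self._e_iso = np.exp(-self._b * d_iso)
        self._lw = (2 * _EVEN_L + 1) / 2.0

    def evaluate(
        self, f_ic: float, kappa: float, f_iso: float, mu: np.ndarray
    ) -> np.ndarray:
        """Signal values for one parameter set (no validation)."""
        values = np.ones(self._n)
        if self._b.size == 0:
            return values
        cosg = self._g @ np.asarray(mu, dtype=float)
        if f_ic > 0.0:
            if kappa == 0.0:
                e_ic = self._iso_stick_u[self._inv]
            elif kappa > _KAPPA_STICK_LIMIT:
                e_ic = np.exp(-self._uniq_a[self._inv] * cosg**2)
            else:
                ratios = _watson_legendre_ratios(kappa)
                pl_cos = eval_legendre(_EVEN_L[:, None], cosg[None, :])
                coeffs = self._coeff_u[:, self._inv]
                e_ic = ((self._lw * ratios)[:, None] * coeffs * pl_cos).sum(axis=0)
        else:
            e_ic = 0.0
        if f_ic < 1.0:
            e_ec = _ec_signal(f_ic, kappa, self.d_par, self._b, cosg)
        else:
            e_ec = 0.0
        tissue_sig = f_ic * e_ic + (1.0 - f_ic) * e_ec
        values[self._dw] = (1.0 - f_iso) * tissue_sig + f_iso * self._e_iso
        return values

    def evaluate_grid(
        self,
        f_ic_arr: np.ndarray,
        kappa: float,
        f_iso_arr: np.ndarray,
        mu: np.ndarray,
    ) -> np.ndarray:
        """Signals for all (f_ic, f_iso) pairs at one (kappa, mu).

        Shares the Watson coefficient quadrature and the stick integral
        across the batch; used by the grid-search initializer.  Returns
        an array of shape (len(f_ic_arr), len(f_iso_arr), n_measurements).
        """
        f_ic_arr = np.asarray(f_ic_arr, dtype=float)
        f_iso_arr = np.asarray(f_iso_arr, dtype=float)
        cosg = self._g @ np.asarray(mu, dtype=float)
        if kappa == 0.0:
            e_ic = self._iso_stick_u[self._inv] * np.ones_like(cosg)
            tau1 = 1.0 / 3.0
        elif kappa > _KAPPA_STICK_LIMIT:
            e_ic = np.exp(-self._uniq_a[self._inv] * cosg**2)
            tau1 = 1.0
        else:
            ratios = _watson_legendre_ratios(kappa)
            pl_cos = eval_legendre(_EVEN_L[:, None], cosg[None, :])
            coeffs = self._coeff_u[:, self._inv]
            e_ic = ((self._lw * ratios)[:, None] * coeffs * pl_cos).sum(axis=0)
            tau1 = watson_tau1(kappa)
        # hindered tensor per f_ic (tortuosity): shape (m_ic, n_dw)
        d_perp = self.d_par * (1.0 - f_ic_arr)[:, None]
        c2 = cosg[None, :] ** 2
        d_eff = d_perp + (self.d_par - d_perp) * (
            tau1 * c2 + 0.5 * (1.0 - tau1) * (1.0 - c2)
        )
        e_ec = np.exp(-self._b[None, :] * d_eff)
        tissue_sig = f_ic_arr[:, None] * e_ic[None, :] + (1.0 - f_ic_arr)[:, None] * e_ec
        out = (
            (1.0 - f_iso_arr)[None, :, None] * tissue_sig[:, None, :]
            + f_iso_arr[None, :, None] * self._e_iso[None, None, :]
        )
        full = np.ones((len(f_ic_arr), len(f_iso_arr), self._n))
        full[:, :, self._dw] = out
        return full


def synthesize_signal(
    tissue: TissueParams, scheme: AcquisitionScheme
) -> SignalSet:
    """Noise-free NODDI signal for every measurement of a scheme.

    b=0 measurements return exactly 1 (S0 normalization); all other
    values lie in (0, 1].
    """
    b = scheme.bvals
    g = scheme.bvecs
    mu = np.asarray(tissue.mu)
    values = np.ones(len(b))
    dw = b > 0
    if np.any(dw):
        bb = b[dw]
        cosg = g[dw] @ mu
        e_iso = np.exp(-bb * tissue.d_iso)
        a = bb * tissue.d_par
        if tissue.f_ic > 0:
            e_ic = _ic_signal(tissue.kappa, a, cosg)
        else:
            e_ic = np.zeros_like(bb)
        if tissue.f_ic < 1:
            e_ec = _ec_signal(tissue.f_ic, tissue.kappa, tissue.d_par, bb, cosg)
        else:
            e_ec = np.zeros_like(bb)
        tissue_sig = tissue.f_ic * e_ic + (1.0 - tissue.f_ic) * e_ec
        values[dw] = (1.0 - tissue.f_iso) * tissue_sig + tissue.f_iso * e_iso
    return SignalSet(scheme, values)


def synthesize_signal_batch(
    f_ic: np.ndarray,
    kappa: np.ndarray,
    f_iso: np.ndarray,
    mu: np.ndarray,
    scheme: AcquisitionScheme,
    d_par: float = D_PAR_DEFAULT,
    d_iso: float = D_ISO_DEFAULT,
) -> np.ndarray:
    """Vectorized signal synthesis for many parameter sets on one scheme.

    Parameters are broadcast 1-D arrays of equal length m (mu is (m, 3));
    returns an (m, n_measurements) array.  Used by the grid-search
    initializer where per-set Python overhead would dominate.
    """
    f_ic = np.atleast_1d(np.asarray(f_ic, dtype=float))
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    f_iso = np.atleast_1d(np.asarray(f_iso, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    m = len(f_ic)
    out = np.empty((m, len(scheme)))
    for i in range(m):
        t = TissueParams(
            f_ic=float(f_ic[i]),
            kappa=float(kappa[i]),
            f_iso=float(f_iso[i]),
            mu=tuple(mu[i]),
            d_par=d_par,
            d_iso=d_iso,
        )
        out[i] = synthesize_signal(t, scheme).values
    return out
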