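"""Multi-shell diffusion acquisition schemes.

Builds the five-shell HYDI acquisition (b = 0, 375, 1500, 3375, 6000,
9375 s/mm^2 with 1/6/21/24/24/50 encoding directions), the nested shell
combination protocols p12..p12345, and the two-shell NODDI reference
protocol (b = 711 and 2855 s/mm^2 with 30 and 60 directions).  Gradient
direction sets are generated by antipodally symmetric electrostatic
repulsion on the unit sphere from a seeded random start, so every scheme
is deterministic given its seed.

Units: b-values are carried in s/mm^2 and diffusivities elsewhere in the
package in mm^2/s, so products b*d are dimensionless.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Measurement",
    "AcquisitionScheme",
    "HYDI_SHELLS",
    "PROTOCOL_NAMES",
    "derive_seed",
    "uniform_sphere_directions",
    "hydi_shells",
    "build_protocol",
    "write_fsl",
    "read_fsl",
]

# (b-value s/mm^2, number of encoding directions) for the five HYDI
# shells plus the single b=0 measurement.
HYDI_SHELLS: tuple[tuple[float, int], ...] = (
    (0.0, 1),
    (375.0, 6),
    (1500.0, 21),
    (3375.0, 24),
    (6000.0, 24),
    (9375.0, 50),
)

#: two-shell reference protocol: (b, n directions)
NODDI_P14_SHELLS: tuple[tuple[float, int], ...] = (
    (0.0, 1),
    (711.0, 30),
    (2855.0, 60),
)

PROTOCOL_NAMES = ("NODDI-p14", "p12", "p123", "p1234", "p12345")

_UNIT_TOL = 1e-10


def derive_seed(*parts) -> int:
    """Stable, order-sensitive 31-bit seed derived from hashable parts.

    Uses CRC32 of the repr so the mapping is identical across processes
    and Python versions (unlike the builtin ``hash``).
    """
    text = "|".join(repr(p) for p in parts)
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


@dataclass(frozen=True)
class Measurement:
    """One diffusion-weighted measurement: b-value plus unit gradient."""

    b: float
    g: tuple[float, float, float]
    shell_id: int

    def __post_init__(self):
        if self.b < 0:
            raise ValueError(f"b-value must be nonnegative, got {self.b}")
        if self.b > 0:
            norm = float(np.linalg.norm(self.g))
            if abs(norm - 1.0) > _UNIT_TOL:
                raise ValueError(
                    f"gradient direction must be unit length for b>0, |g|={norm}"
                )


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered list of measurements grouped into b-value shells."""

    name: str
    measurements: tuple[Measurement, ...]

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([m.b for m in self.measurements], dtype=float)

    @property
    def bvecs(self) -> np.ndarray:
        """(n, 3) array of gradient directions (zero rows where b=0)."""
        return np.array([m.g for m in self.measurements], dtype=float)

    @property
    def shell_ids(self) -> np.ndarray:
        return np.array([m.shell_id for m in self.measurements], dtype=int)

    def shells(self) -> dict[int, float]:
        """Mapping shell_id -> b-value, in ascending shell order."""
        out: dict[int, float] = {}
        for m in self.measurements:
            if m.shell_id in out:
                if out[m.shell_id] != m.b:
                    raise ValueError("inconsistent b-values within a shell")
            else:
                out[m.shell_id] = m.b
        return dict(sorted(out.items()))

    def shell_counts(self) -> dict[float, int]:
        """Mapping b-value -> number of measurements."""
        counts: dict[float, int] = {}
        for m in self.measurements:
            counts[m.b] = counts.get(m.b, 0) + 1
        return dict(sorted(counts.items()))


def uniform_sphere_directions(
    n: int, seed: int = 0, n_iter: int = 300
) -> np.ndarray:
    """Quasi-uniform antipodally symmetric unit vectors on the sphere.

    Minimizes the Coulomb energy of the point set doubled with its
    antipodes (the standard electrostatic-repulsion construction for
    diffusion encoding tables) by projected gradient descent from a
    seeded Gaussian start.  Deterministic given (n, seed).

    Parameters
    ----------
    n : number of directions (>= 1)
    seed : RNG seed for the random start
    n_iter : repulsion iterations

    Returns
    -------
    (n, 3) array of unit vectors.
    """
    if n < 1:
        raise ValueError(f"need at least one direction, got n={n}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x

    eye = np.eye(n, dtype=bool)
    step = 0.1
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]      # x_i - x_j
        summ = x[:, None, :] + x[None, :, :]      # x_i + x_j (antipodal pair)
        d3 = np.linalg.norm(diff, axis=-1) ** 3
        s3 = np.linalg.norm(summ, axis=-1) ** 3
        d3[eye] = np.inf
        s3[eye] = np.inf
        force = (diff / d3[..., None]).sum(axis=1) + (summ / s3[..., None]).sum(axis=1)
        # project onto the tangent plane of each point
        force -= (force * x).sum(axis=1, keepdims=True) * x
        fmax = np.max(np.linalg.norm(force, axis=1))
        if fmax == 0:
            break
        x = x + step * force / fmax
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step *= 0.985
    return x


def _shell_measurements(
    shell_spec: tuple[tuple[float, int], ...], seed: int, tag: str
) -> tuple[Measurement, ...]:
    meas: list[Measurement] = []
    for shell_id, (b, ne) in enumerate(shell_spec):
        if b == 0:
            meas.extend(
                Measurement(0.0, (0.0, 0.0, 0.0), shell_id) for _ in range(ne)
            )
            continue
        dirs = uniform_sphere_directions(ne, seed=derive_seed(tag, seed, b, ne))
        meas.extend(Measurement(b, tuple(v), shell_id) for v in dirs)
    return tuple(meas)


def hydi_shells(seed: int = 0) -> AcquisitionScheme:
    """The full 5-shell HYDI scheme (126 measurements, one b=0)."""
    return AcquisitionScheme("p12345", _shell_measurements(HYDI_SHELLS, seed, "hydi"))


def build_protocol(name: str, seed: int = 0) -> AcquisitionScheme:
    """Build a named protocol.

    ``p12``..``p12345`` are nested subsets of the HYDI shells (always
    keeping the b=0 measurement); ``NODDI-p14`` is the two-shell
    reference scheme.  Subsets share the parent HYDI directions, so
    protocol nesting holds measurement-for-measurement.
    """
    if name not in PROTOCOL_NAMES:
        raise ValueError(
            f"unknown protocol {name!r}; valid protocols: {', '.join(PROTOCOL_NAMES)}"
        )
    if name == "NODDI-p14":
        return AcquisitionScheme(
            name, _shell_measurements(NODDI_P14_SHELLS, seed, "p14")
        )
    full = hydi_shells(seed)
    n_shells = len(name) - 1  # "p12" -> shells 1..2
    keep = {0} | set(range(1, n_shells + 1))
    meas = tuple(m for m in full.measurements if m.shell_id in keep)
    return AcquisitionScheme(name, meas)


# ---------------------------------------------------------------------------
# FSL-style .bval/.bvec plain-text I/O


def write_fsl(scheme: AcquisitionScheme, prefix: str) -> tuple[str, str]:
    """Write ``prefix.bval`` / ``prefix.bvec`` (measurements in columns)."""
    bvals = scheme.bvals
    bvecs = scheme.bvecs
    bval_path = f"{prefix}.bval"
    bvec_path = f"{prefix}.bvec"
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:.10g}" for b in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.10g}" for v in bvecs[:, axis]) + "\n")
    return bval_path, bvec_path


def read_fsl(bval_path: str, bvec_path: str, name: str = "scheme") -> AcquisitionScheme:
    """Read an FSL-style scheme; shells assigned by ascending unique b."""
    bvals = np.loadtxt(bval_path, ndmin=1, dtype=float)
    bvecs = np.loadtxt(bvec_path, ndmin=2, dtype=float)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError("bval/bvec measurement counts differ")
    unique_b = np.unique(bvals)
    shell_of = {b: i for i, b in enumerate(unique_b)}
    meas = []
    for j, b in enumerate(bvals):
        g = bvecs[:, j]
        if b > 0:
            g = g / np.linalg.norm(g)
        meas.append(Measurement(float(b), tuple(g), shell_of[float(b)]))
    return AcquisitionScheme(name, tuple(meas))
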