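"""Forward scattering model for polydisperse uni- and multilamellar lipid vesicles.

The model describes a vesicle as a spherical core of solvent (a water/ethanol
mixture) wrapped by ``N`` concentric symmetric bilayers.  Each bilayer is a
mirrored six-slab electron-density profile — head | chain | methyl | methyl |
chain | head — with shell half-thicknesses ``R1, R2, R3`` (nm) and electron
densities ``rho1, rho2, rho3`` (e/nm^3).  Bilayer-to-bilayer repeat positions
follow one-dimensional paracrystalline (Hosemann) statistics with mean spacing
``c`` and relative distortion ``g_c``.  Core radii are Schultz (gamma)
distributed with mean ``R0_mean`` and relative dispersion ``xi_R0``.

Two evaluation modes are provided:

``exact_sphere``
    Coherent multishell-sphere amplitude, Schultz-averaged over the core
    radius.  Exact for the spherical geometry, at the price of a dense radius
    quadrature once the product ``Q * R0`` is large.

``separated``
    Large-radius factorisation: flat-bilayer form factor times the
    paracrystal structure factor times the ``8 pi^2 R^2 / Q^2`` thin-shell
    prefactor.  This is the fast path used for fitting; the two modes agree
    to a couple of percent for core radii of a few hundred nm once size
    polydispersity damps the core-radius interference fringes.

All momentum transfers are in nm^-1 internally (inverse angstroms are
converted at the I/O boundary), lengths in nm, electron densities in e/nm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HC_KEV_NM",
    "QGrid",
    "BilayerProfile",
    "SolventSpec",
    "StackSpec",
    "SizeDistribution",
    "VesicleModel",
    "q_from_angle",
    "wavelength_from_energy",
    "mixture_density",
    "schultz_pdf",
    "schultz_nodes",
    "multishell_amplitude",
    "flat_bilayer_amplitude",
    "flat_bilayer_intensity",
    "paracrystal_sf",
    "model_intensity",
    "interlamellar_distance",
    "find_bragg_peak",
]

#: Photon energy–wavelength conversion constant, keV * nm.
HC_KEV_NM = 1.23984

#: Relative dispersion below which a Schultz distribution is treated as a delta.
XI_DELTA = 1e-3


# ---------------------------------------------------------------------------
# geometry conversions
# ---------------------------------------------------------------------------

def q_from_angle(theta: float, wavelength: float) -> float:
    """Momentum transfer Q = 4 pi sin(theta) / lambda.

    Parameters
    ----------
    theta : float
        Half the scattering angle, radians, in [0, pi/2).
    wavelength : float
        X-ray wavelength, nm, > 0.

    Returns
    -------
    float
        Q in nm^-1.
    """
    if wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    if not (0 <= theta < math.pi / 2):
        raise ValueError(f"theta must lie in [0, pi/2), got {theta}")
    return 4.0 * math.pi * math.sin(theta) / wavelength


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength (nm) for a photon energy (keV), lambda = hc / E.

    Note that a rounded 8 keV maps to 0.15498 nm; the conventional
    0.15406 nm is the Cu K-alpha line at 8.048 keV.
    """
    if energy_kev <= 0:
        raise ValueError(f"energy must be > 0 keV, got {energy_kev}")
    return HC_KEV_NM / energy_kev


def interlamellar_distance(q_peak: float) -> float:
    """Real-space repeat distance d = 2 pi / Q for a Bragg peak at ``q_peak`` (nm^-1)."""
    if q_peak <= 0:
        raise ValueError(f"q_peak must be > 0, got {q_peak}")
    return 2.0 * math.pi / q_peak


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QGrid:
    """Strictly increasing, strictly positive momentum-transfer grid in nm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("QGrid requires a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("QGrid values must be finite")
        if np.any(v <= 0):
            raise ValueError("QGrid values must be strictly positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("QGrid values must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def default(cls, n: int = 200, qmin: float = 0.1, qmax: float = 5.0) -> "QGrid":
        """Log-spaced grid over the instrument's nominal 0.1–5 nm^-1 range."""
        return cls(np.geomspace(qmin, qmax, n))

    @classmethod
    def from_inverse_angstrom(cls, values: np.ndarray) -> "QGrid":
        return cls(np.asarray(values, dtype=float) * 10.0)


@dataclass(frozen=True)
class BilayerProfile:
    """Symmetric lipid bilayer as three mirrored constant-density shells.

    ``R1/rho1`` polar head group, ``R2/rho2`` aliphatic chain, ``R3/rho3``
    terminal methyl; thicknesses in nm, densities in e/nm^3.  Total bilayer
    thickness is ``2 * (R1 + R2 + R3)``.
    """

    R1: float
    R2: float
    R3: float
    rho1: float = 370.0
    rho2: float = 320.0
    rho3: float = 300.0

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def half_thickness(self) -> float:
        return self.R1 + self.R2 + self.R3

    @property
    def total_thickness(self) -> float:
        return 2.0 * self.half_thickness


@dataclass(frozen=True)
class SolventSpec:
    """Water/ethanol mixture characterised by the water volume fraction."""

    water_volume_fraction: float
    rho_water: float = 330.0
    rho_ethanol: float = 285.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.water_volume_fraction <= 1.0):
            raise ValueError(
                f"water_volume_fraction must lie in [0, 1], got {self.water_volume_fraction}"
            )

    @property
    def electron_density(self) -> float:
        return mixture_density(self)


def mixture_density(solvent: SolventSpec) -> float:
    """Linear volume-mixed electron density of the water/ethanol solvent, e/nm^3."""
    f = solvent.water_volume_fraction
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"water_volume_fraction must lie in [0, 1], got {f}")
    return f * solvent.rho_water + (1.0 - f) * solvent.rho_ethanol


@dataclass(frozen=True)
class StackSpec:
    """Paracrystalline stack of ``N`` bilayers with mean spacing ``c`` (nm).

    ``g_c`` is the relative standard deviation of the nearest-neighbour
    spacing (Hosemann distortion of the second kind); ``N = 1`` means a
    unilamellar vesicle and a structure factor identically equal to one.
    """

    N: int
    c: float
    g_c: float

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N}")
        object.__setattr__(self, "N", int(self.N))
        if self.c <= 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.g_c < 0:
            raise ValueError(f"g_c must be >= 0, got {self.g_c}")


@dataclass(frozen=True)
class SizeDistribution:
    """Schultz (gamma) law over the vesicle core radius.

    Parameterised by the mean radius ``R0_mean`` (nm) and the relative
    dispersion ``xi_R0`` = sigma/mean = 1/sqrt(z + 1) with Schultz shape z.
    ``xi_R0`` below ``XI_DELTA`` is treated as monodisperse.
    """

    R0_mean: float
    xi_R0: float

    def __post_init__(self) -> None:
        if self.R0_mean <= 0:
            raise ValueError(f"R0_mean must be > 0, got {self.R0_mean}")
        if self.xi_R0 < 0:
            raise ValueError(f"xi_R0 must be >= 0, got {self.xi_R0}")

    @property
    def is_delta(self) -> bool:
        return self.xi_R0 < XI_DELTA

    @property
    def z(self) -> float:
        """Schultz shape parameter z = 1/xi^2 - 1."""
        if self.is_delta:
            return math.inf
        return 1.0 / self.xi_R0**2 - 1.0

    def moment(self, k: int) -> float:
        """Closed-form raw moment <R^k> of the Schultz law."""
        if self.is_delta:
            return self.R0_mean**k
        a = self.z + 1.0
        theta = self.R0_mean / a
        # <R^k> = theta^k * Gamma(a + k) / Gamma(a), via a product to stay finite
        out = 1.0
        for j in range(k):
            out *= theta * (a + j)
        return out


@dataclass(frozen=True)
class VesicleModel:
    """Complete forward-model parameter set for one vesicle population."""

    size: SizeDistribution
    bilayer: BilayerProfile
    stack: StackSpec
    solvent: SolventSpec
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.background < 0:
            raise ValueError(f"background must be >= 0, got {self.background}")


# ---------------------------------------------------------------------------
# Schultz size distribution
# ---------------------------------------------------------------------------

def _gamma_dist(dist: SizeDistribution) -> stats.rv_continuous:
    a = dist.z + 1.0
    return stats.gamma(a=a, scale=dist.R0_mean / a)


def schultz_pdf(R: np.ndarray, dist: SizeDistribution) -> np.ndarray:
    """Schultz probability density over the core radius, nm^-1.

    f(R) = ((z+1)/Rm)^(z+1) R^z exp(-(z+1) R / Rm) / Gamma(z+1), the gamma
    density with shape z + 1 and scale Rm/(z+1).
    """
    if dist.is_delta:
        raise ValueError("xi_R0 below the delta threshold; no continuous density")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("radii must be >= 0")
    return _gamma_dist(dist).pdf(R)


def schultz_nodes(
    dist: SizeDistribution, n_nodes: int = 51
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and weights for averaging over the Schultz law.

    Gauss–Legendre nodes mapped onto the essential support of the density
    (quantiles 1e-12 to 1 - 1e-12), weighted by the density and renormalised
    to unit mass.  A delta branch returns the single node ``R0_mean`` when
    the distribution is (near-)monodisperse.

    Returns
    -------
    (radii, weights)
        Arrays of length ``n_nodes`` (length 1 on the delta branch);
        weights are non-negative and sum to one.
    """
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be >= 1, got {n_nodes}")
    if dist.is_delta or n_nodes == 1:
        return np.array([dist.R0_mean]), np.array([1.0])
    g = _gamma_dist(dist)
    lo, hi = g.ppf(1e-12), g.ppf(1.0 - 1e-12)
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    radii = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    weights = w * g.pdf(radii)
    weights = weights / weights.sum()
    return radii, weights


# ---------------------------------------------------------------------------
# form factors
# ---------------------------------------------------------------------------

def _sphere_kernel(x: np.ndarray) -> np.ndarray:
    """(sin x - x cos x) / x^3, the spherical form-factor kernel; -> 1/3 at x=0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-2
    xs = x[small]
    out[small] = 1.0 / 3.0 - xs**2 / 30.0 + xs**4 / 840.0
    xl = x[~small]
    out[~small] = (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def multishell_amplitude(
    q: np.ndarray,
    boundary_radii: np.ndarray,
    densities: np.ndarray,
    rho_out: float,
) -> np.ndarray:
    """Scattering amplitude (electrons) of concentric constant-density shells.

    ``boundary_radii`` are the outer radii of the regions, strictly
    increasing; ``densities`` holds one electron density per region,
    innermost first; ``rho_out`` is the density outside the last boundary.
    The amplitude is the coherent boundary sum

        F(Q) = sum_j (rho_j - rho_{j+1}) * 3 V_j * (sin(QR_j) - QR_j cos(QR_j)) / (QR_j)^3

    whose Q -> 0 limit is the total excess electron count
    sum_regions (rho_region - rho_out) * V_region.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    radii = np.asarray(boundary_radii, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if radii.size != rho.size:
        raise ValueError(
            f"need one density per region: {radii.size} boundaries vs {rho.size} densities"
        )
    if radii.size == 0:
        return np.zeros_like(q)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("boundary radii must be positive and strictly increasing")
    # density step crossed outward at each boundary
    drho = rho - np.append(rho[1:], rho_out)
    vol = 4.0 * math.pi / 3.0 * radii**3
    x = np.outer(q, radii)
    return (3.0 * vol * drho * _sphere_kernel(x)).sum(axis=1)


def flat_bilayer_amplitude(
    q: np.ndarray, bilayer: BilayerProfile, solvent: SolventSpec
) -> np.ndarray:
    """Per-area amplitude of the flat six-slab bilayer, 2 * integral drho cos(Qz) dz.

    The profile is mirror-symmetric about the bilayer midplane, so only the
    positive-z half (methyl, chain, head outward) contributes twice.  The
    Q -> 0 limit is twice the excess electron surface density,
    2 * sum drho_i t_i.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    rho_s = solvent.electron_density
    # slab boundaries outward from the midplane
    zb = np.array([
        0.0,
        bilayer.R3,
        bilayer.R3 + bilayer.R2,
        bilayer.R3 + bilayer.R2 + bilayer.R1,
    ])
    drho = np.array([bilayer.rho3, bilayer.rho2, bilayer.rho1]) - rho_s
    out = np.empty_like(q)
    nz = q != 0
    qn = q[nz]
    s = np.sin(np.outer(qn, zb))
    out[nz] = 2.0 * ((s[:, 1:] - s[:, :-1]) * drho).sum(axis=1) / qn
    out[~nz] = 2.0 * (drho * np.diff(zb)).sum()
    return out


def flat_bilayer_intensity(
    q: np.ndarray, bilayer: BilayerProfile, solvent: SolventSpec
) -> np.ndarray:
    """Squared flat-bilayer form factor |F(Q)|^2 (per unit area, arbitrary units)."""
    return flat_bilayer_amplitude(q, bilayer, solvent) ** 2


def _bilayer_first_moment(
    q: np.ndarray, bilayer: BilayerProfile, solvent: SolventSpec
) -> np.ndarray:
    """First-moment transform 2 * integral_0^{t/2} z drho(z) sin(Qz) dz.

    Curvature correction of the thin-shell factorisation: for a spherical
    shell of midplane radius R the orientation/size-averaged intensity is
    proportional to R^2 A_c^2 + C^2 with A_c the flat amplitude and C this
    moment.  The C^2 term is O((t/R)^2) except near zeros of A_c, where it
    keeps the model finite and accurate.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    zb = np.array([
        0.0,
        bilayer.R3,
        bilayer.R3 + bilayer.R2,
        bilayer.R3 + bilayer.R2 + bilayer.R1,
    ])
    drho = np.array([bilayer.rho3, bilayer.rho2, bilayer.rho1]) - solvent.electron_density
    out = np.zeros_like(q)
    nz = q != 0
    qn = q[nz][:, None]
    # antiderivative of z sin(qz): sin(qz)/q^2 - z cos(qz)/q
    anti = np.sin(qn * zb) / qn**2 - zb * np.cos(qn * zb) / qn
    out[nz] = 2.0 * ((anti[:, 1:] - anti[:, :-1]) * drho).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# paracrystal structure factor
# ---------------------------------------------------------------------------

def paracrystal_sf(q: np.ndarray, stack: StackSpec) -> np.ndarray:
    """One-dimensional Hosemann paracrystal structure factor, per bilayer.

    S(Q) = 1 + (2/N) sum_{k=1}^{N-1} (N - k) cos(k Q c) |phi|^k with the
    Gaussian nearest-neighbour spacing characteristic function
    |phi(Q)| = exp(-Q^2 c^2 g_c^2 / 2).  Cumulative (second-kind) disorder:
    the k-th neighbour phase decorrelates as |phi|^k.  Normalised so that
    S -> 1 at large Q; S is the exact expectation of |sum_n e^{iQx_n}|^2 / N
    and therefore non-negative.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if stack.N == 1:
        return np.ones_like(q)
    phi = np.exp(-0.5 * q**2 * stack.c**2 * stack.g_c**2)
    s = np.ones_like(q)
    for k in range(1, stack.N):
        s += (2.0 / stack.N) * (stack.N - k) * np.cos(k * q * stack.c) * phi**k
    return np.clip(s, 0.0, None)


# ---------------------------------------------------------------------------
# full model intensity
# ---------------------------------------------------------------------------

def _stack_offsets(model: VesicleModel) -> tuple[np.ndarray, np.ndarray]:
    """Region boundary offsets (relative to the core radius) and densities."""
    b = model.bilayer
    rho_s = model.solvent.electron_density
    slab_t = [b.R1, b.R2, b.R3, b.R3, b.R2, b.R1]
    slab_rho = [b.rho1, b.rho2, b.rho3, b.rho3, b.rho2, b.rho1]
    if model.stack.N > 1 and model.stack.c <= b.total_thickness:
        raise ValueError(
            f"stack spacing c={model.stack.c} nm must exceed the bilayer "
            f"thickness {b.total_thickness} nm"
        )
    offsets = [0.0]
    rho = [rho_s]  # core filled with the same water/ethanol mixture
    for n in range(model.stack.N):
        start = n * model.stack.c
        if start > offsets[-1]:
            offsets.append(start)
            rho.append(rho_s)  # solvent gap between bilayers
        r = start
        for t, d in zip(slab_t, slab_rho):
            r += t
            offsets.append(r)
            rho.append(d)
    return np.asarray(offsets), np.asarray(rho)


def _exact_sphere_nodes(model: VesicleModel, qmax: float) -> int:
    """Quadrature size resolving the sin(Q R0) fringes of the sphere amplitude."""
    dist = model.size
    if dist.is_delta:
        return 1
    g = _gamma_dist(dist)
    span = g.ppf(1.0 - 1e-12) - g.ppf(1e-12)
    periods = span * qmax / (2.0 * math.pi)
    return int(np.clip(8 * periods, 51, 20001))


def model_intensity(
    grid: QGrid,
    model: VesicleModel,
    mode: str = "separated",
    n_nodes: int | None = None,
) -> np.ndarray:
    """SAXS intensity of the vesicle model on ``grid`` (arbitrary units).

    Parameters
    ----------
    grid : QGrid
        Momentum transfers, nm^-1.
    model : VesicleModel
        Full parameter set.
    mode : {"separated", "exact_sphere"}
        ``separated`` evaluates scale * N * 8 pi^2 <R_b^2> / Q^2 *
        |F_flat|^2 * S(Q) + background with R_b the mid-bilayer radius;
        ``exact_sphere`` Schultz-averages the coherent multishell amplitude.
    n_nodes : int, optional
        Override the Schultz quadrature size (exact_sphere mode only).
    """
    q = grid.values
    if mode == "separated":
        ac2 = flat_bilayer_intensity(q, model.bilayer, model.solvent)
        c2 = _bilayer_first_moment(q, model.bilayer, model.solvent) ** 2
        sf = paracrystal_sf(q, model.stack)
        # mean-square midplane radius of the stack centre
        r_eff = (
            model.size.R0_mean
            + model.bilayer.half_thickness
            + 0.5 * (model.stack.N - 1) * model.stack.c
        )
        msq = r_eff**2 + (model.size.xi_R0 * model.size.R0_mean) ** 2
        intensity = (
            model.scale
            * model.stack.N
            * 8.0
            * math.pi**2
            / q**2
            * (msq * ac2 + c2)
            * sf
        )
    elif mode == "exact_sphere":
        n = n_nodes if n_nodes is not None else _exact_sphere_nodes(model, q[-1])
        radii, weights = schultz_nodes(model.size, n)
        offsets, rho = _stack_offsets(model)
        rho_out = model.solvent.electron_density
        drho = rho - np.append(rho[1:], rho_out)
        acc = np.zeros_like(q)
        for start in range(0, radii.size, 256):  # chunk nodes to bound memory
            r0 = radii[start : start + 256]
            w = weights[start : start + 256]
            bounds = r0[:, None] + offsets[None, :]  # (nodes, regions)
            vol = 4.0 * math.pi / 3.0 * bounds**3
            x = q[:, None, None] * bounds[None, :, :]
            amp = (3.0 * vol * drho * _sphere_kernel(x)).sum(axis=2)
            acc += (w * amp**2).sum(axis=1)
        intensity = model.scale * acc
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'separated' or 'exact_sphere'")
    return intensity + model.background


# ---------------------------------------------------------------------------
# Bragg peak location
# ---------------------------------------------------------------------------

def find_bragg_peak(
    curve,
    window: tuple[float, float],
    min_prominence: float = 0.05,
    max_width_fraction: float = 0.35,
) -> float | None:
    """Locate a sharp Bragg reflection inside ``window`` = (qmin, qmax), nm^-1.

    A smooth background is estimated by fitting a quadratic to the log10
    intensity versus log10 Q inside the window, iteratively masking the
    candidate peak region so the reflection does not bias the fit.  A
    candidate is accepted as a Bragg peak only if it

    * rises at least ``min_prominence`` decades above the background,
    * is localised: its above-half-maximum region stays inside the window
      and spans at most ``max_width_fraction`` of it, and
    * is a genuine maximum of the measured intensity itself, not only of
      the background-subtracted excess (form-factor minima inside the
      window otherwise masquerade as broad excess bumps).

    The apex is refined by a parabola through the above-half-maximum points
    in log-log space.  Returns ``None`` when no such reflection exists.
    """
    qmin, qmax = window
    q = curve.grid.values
    if qmin >= qmax:
        raise ValueError("window must satisfy qmin < qmax")
    if qmin < q[0] or qmax > q[-1]:
        raise ValueError(
            f"window ({qmin}, {qmax}) outside the data range ({q[0]:.4g}, {q[-1]:.4g})"
        )
    sel = (q >= qmin) & (q <= qmax)
    if sel.sum() < 5:
        raise ValueError("need at least 5 points inside the search window")
    qs = q[sel]
    y = np.log10(np.clip(curve.intensity[sel], 1e-300, None))
    lq = np.log10(qs)
    n = len(qs)
    deg = 2 if n >= 8 else 1
    mask = np.zeros(n, dtype=bool)
    excess = None
    for _ in range(3):
        use = ~mask
        if use.sum() <= deg + 2:
            break
        coeffs = np.polyfit(lq[use], y[use], deg)
        excess = y - np.polyval(coeffs, lq)
        i = int(np.argmax(excess[1:-1])) + 1
        lo, hi = _half_region(excess, i)
        new_mask = np.zeros_like(mask)
        new_mask[lo : hi + 1] = True
        if new_mask.sum() > 0.6 * n:  # no localised bump; keep the baseline
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    if excess is None:
        return None
    span = lq[-1] - lq[0]
    order = np.arange(1, n - 1)[np.argsort(excess[1:-1])[::-1]]
    for i in order:
        if excess[i] < min_prominence:
            return None
        if not (excess[i] >= excess[i - 1] and excess[i] >= excess[i + 1]):
            continue
        lo, hi = _half_region(excess, i)
        if lo == 0 or hi == n - 1:
            continue
        if (lq[hi] - lq[lo]) / span > max_width_fraction:
            continue
        # the measured intensity itself must peak somewhere inside the
        # excess-positive region around the apex (steep backgrounds displace
        # the intensity maximum from the excess apex, so search the full bump)
        lo0 = lo
        while lo0 > 0 and excess[lo0 - 1] > 0:
            lo0 -= 1
        hi0 = hi
        while hi0 < n - 1 and excess[hi0 + 1] > 0:
            hi0 += 1
        interior = np.arange(max(lo0, 1), min(hi0, n - 2) + 1)
        raw_max = np.any(
            (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1])
        )
        if not raw_max:
            continue
        return _refine_apex(qs, lq, excess, i, lo, hi)
    return None


def _half_region(excess: np.ndarray, i: int) -> tuple[int, int]:
    """Contiguous index range around ``i`` where the excess exceeds half its apex."""
    half = 0.5 * excess[i]
    lo = i
    while lo > 0 and excess[lo - 1] > half:
        lo -= 1
    hi = i
    while hi < len(excess) - 1 and excess[hi + 1] > half:
        hi += 1
    return lo, hi


def _refine_apex(
    qs: np.ndarray, lq: np.ndarray, excess: np.ndarray, i: int, lo: int, hi: int
) -> float:
    """Sub-grid apex: parabola through the above-half-maximum peak region."""
    if hi - lo >= 3:
        # the lamellar interference term and typical reflections are locally
        # symmetric in Q, so the parabola is fit on the linear Q axis
        a, b, _ = np.polyfit(qs[lo : hi + 1], excess[lo : hi + 1], 2)
        if a < 0:
            apex = -b / (2.0 * a)
            if qs[lo] <= apex <= qs[hi]:
                return float(apex)
    # fall back to a three-point parabola on the grid
    denom = excess[i - 1] - 2.0 * excess[i] + excess[i + 1]
    if denom < 0:
        shift = float(np.clip(0.5 * (excess[i - 1] - excess[i + 1]) / denom, -0.5, 0.5))
    else:
        shift = 0.0
    if shift >= 0:
        return float(qs[i] + shift * (qs[min(i + 1, len(qs) - 1)] - qs[i]))
    return float(qs[i] + shift * (qs[i] - qs[i - 1]))
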