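"""Per-bead SLATM spectra for coarse-grained configurations.

The Spectrum of London and Axilrod-Teller-Muto (SLATM) representation
describes the environment of a particle ``i`` of type ``I`` as a
concatenation of

* a one-body identity term, the unique type number ``Z_I``;
* for each neighbour type ``J``, a radial histogram of pairwise
  interactions weighted by a London-dispersion factor
  ``w_ij = 1/2 * Z_I * Z_J / R_ij^6``;
* for each unordered neighbour-type pair ``{J, K}``, an angular histogram
  of triplet interactions weighted by the Axilrod-Teller-Muto triple-dipole
  factor ``v_ijk = 1/3 * Z_I Z_J Z_K * (1 + 3 cos(t_jik) cos(t_ijk)
  cos(t_ikj)) / (R_ij R_ik R_jk)^3``, binned over the angle at the center,
  ``t_jik``.

Each contribution is smoothed by a Gaussian kernel evaluated at the bin
centers and multiplied by the bin width, i.e. a discretized unit-mass
kernel.  Angular kernels are folded back at the support edges so a triplet
at exactly 0 or pi keeps its full mass; radial kernels are plainly
truncated at the range edges.  The representation is invariant under
translation, rotation and bead relabelling, and ignores covalent bonding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import Configuration
from .registry import BeadTypeRegistry, ChannelIndex

__all__ = [
    "SlatmParams",
    "AtomicSpectrum",
    "CoincidentBeadsError",
    "gaussian_bin_profile",
    "two_body_spectrum",
    "three_body_spectrum",
    "atomic_slatm",
]

COINCIDENT_TOL = 1e-6  # Angstrom; closer beads signal corrupt geometry


class CoincidentBeadsError(ValueError):
    """Two beads closer than the coincidence tolerance."""


@dataclass(frozen=True)
class SlatmParams:
    """Kernel widths, bin widths and cutoff of the SLATM histograms.

    Defaults are tuned for coarse-grained bead resolutions: sigma 0.3 A /
    0.2 rad, bin widths 0.2 A / 0.2 rad, radial cutoff 8.0 A.  The angular
    range is [0, pi].  The London/ATM prefactors and exponents are
    overridable for ablation studies.
    """

    sigma_r: float = 0.3
    sigma_theta: float = 0.2
    bin_width_r: float = 0.2
    bin_width_theta: float = 0.2
    r_cutoff: float = 8.0
    two_body_prefactor: float = 0.5
    two_body_exponent: float = 6.0
    three_body_prefactor: float = 1.0 / 3.0
    three_body_exponent: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "sigma_r",
            "sigma_theta",
            "bin_width_r",
            "bin_width_theta",
            "r_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_cutoff <= self.bin_width_r:
            raise ValueError("r_cutoff must exceed bin_width_r")

    @property
    def n_bins_r(self) -> int:
        return math.ceil(self.r_cutoff / self.bin_width_r)

    @property
    def n_bins_theta(self) -> int:
        return math.ceil(math.pi / self.bin_width_theta)

    @property
    def r_bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins_r) + 0.5) * self.bin_width_r

    @property
    def theta_bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins_theta) + 0.5) * self.bin_width_theta

    @property
    def theta_support(self) -> float:
        """Upper edge of the angular histogram support."""
        return self.n_bins_theta * self.bin_width_theta

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "sigma_r",
                "sigma_theta",
                "bin_width_r",
                "bin_width_theta",
                "r_cutoff",
                "two_body_prefactor",
                "two_body_exponent",
                "three_body_prefactor",
                "three_body_exponent",
            )
        }


@dataclass
class AtomicSpectrum:
    """One bead's SLATM: identity scalar plus per-channel histograms."""

    center_type: str
    one_body: float
    two_body: dict[str, np.ndarray]
    three_body: dict[tuple[str, str], np.ndarray]
    params: SlatmParams = field(default_factory=SlatmParams)


# ---------------------------------------------------------------------------
# Gaussian binning
# ---------------------------------------------------------------------------

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _profile_matrix(
    values: np.ndarray,
    sigma: float,
    bin_centers: np.ndarray,
    bin_width: float,
    reflect: tuple[float, float] | None = None,
) -> np.ndarray:
    """(m, n_bins) matrix of discretized unit-mass kernels."""
    values = np.atleast_1d(np.asarray(values, dtype=float))
    d = bin_centers[None, :] - values[:, None]
    out = np.exp(-0.5 * (d / sigma) ** 2)
    if reflect is not None:
        lo, hi = reflect
        for mirrored in (2.0 * lo - values, 2.0 * hi - values):
            dm = bin_centers[None, :] - mirrored[:, None]
            out += np.exp(-0.5 * (dm / sigma) ** 2)
    out *= bin_width / (sigma * _SQRT2PI)
    return out


def gaussian_bin_profile(
    value: float,
    sigma: float,
    bin_centers: np.ndarray,
    bin_width: float,
    reflect: tuple[float, float] | None = None,
) -> np.ndarray:
    """Discretized unit-mass Gaussian kernel centered on ``value``.

    Returns ``g_b = N(c_b; value, sigma) * bin_width`` over the uniform bin
    centers ``c_b``; the entries sum to 1 when the kernel lies fully inside
    the binned range.  With ``reflect=(lo, hi)`` mass spilling past the
    support edges is folded back in (used for the bounded angular domain).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    bin_centers = np.asarray(bin_centers, dtype=float)
    return _profile_matrix(np.array([value]), sigma, bin_centers, bin_width, reflect)[0]


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def _check_coincident(dist: np.ndarray) -> None:
    if dist.size and float(dist.min()) < COINCIDENT_TOL:
        raise CoincidentBeadsError(
            f"beads closer than {COINCIDENT_TOL} A: corrupt geometry"
        )


def two_body_spectrum(
    config: Configuration,
    center_index: int,
    neighbor_type: str,
    params: SlatmParams,
    registry: BeadTypeRegistry,
    neighbor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """London-weighted radial histogram of one center against one type.

    Sums ``w_ij * g(R_ij)`` over all beads ``j != i`` of ``neighbor_type``
    with ``R_ij <= r_cutoff``; the center is never its own neighbour.
    ``neighbor_mask`` optionally restricts the eligible neighbours.
    """
    pos = config.positions
    i = int(center_index)
    z_i = registry.z_of(str(config.types[i]))
    z_j = registry.z_of(neighbor_type)
    sel = (config.types == neighbor_type)
    sel[i] = False
    if neighbor_mask is not None:
        sel &= neighbor_mask
    hist = np.zeros(params.n_bins_r)
    if not sel.any():
        return hist
    r = np.linalg.norm(pos[sel] - pos[i], axis=1)
    _check_coincident(r)
    r = r[r <= params.r_cutoff]
    if r.size == 0:
        return hist
    w = (
        params.two_body_prefactor
        * z_i
        * z_j
        * r ** (-params.two_body_exponent)
    )
    profiles = _profile_matrix(
        r, params.sigma_r, params.r_bin_centers, params.bin_width_r
    )
    return w @ profiles


def _triplet_geometry(pos, i, idx_j, idx_k):
    """Vectorized ATM geometry for pairs (idx_j[m], idx_k[m]) around i."""
    u_ij = pos[idx_j] - pos[i]
    u_ik = pos[idx_k] - pos[i]
    r_ij = np.linalg.norm(u_ij, axis=1)
    r_ik = np.linalg.norm(u_ik, axis=1)
    u_jk = pos[idx_k] - pos[idx_j]
    r_jk = np.linalg.norm(u_jk, axis=1)
    _check_coincident(np.concatenate([r_ij, r_ik, r_jk]))
    # cosines of the interior angles at the center (i), at j, and at k;
    # clipping keeps collinear geometries analytic (cos = +-1)
    cos_i = np.clip((u_ij * u_ik).sum(1) / (r_ij * r_ik), -1.0, 1.0)
    cos_j = np.clip((-u_ij * u_jk).sum(1) / (r_ij * r_jk), -1.0, 1.0)
    cos_k = np.clip((u_ik * u_jk).sum(1) / (r_ik * r_jk), -1.0, 1.0)
    theta = np.arccos(cos_i)
    return r_ij, r_ik, r_jk, cos_i, cos_j, cos_k, theta


def _atm_weights(params, z_i, z_j, z_k, r_ij, r_ik, r_jk, cos_i, cos_j, cos_k):
    angular = 1.0 + 3.0 * cos_i * cos_j * cos_k
    return (
        params.three_body_prefactor
        * z_i
        * z_j
        * z_k
        * angular
        / (r_ij * r_ik * r_jk) ** params.three_body_exponent
    )


def three_body_spectrum(
    config: Configuration,
    center_index: int,
    neighbor_pair: tuple[str, str],
    params: SlatmParams,
    registry: BeadTypeRegistry,
    neighbor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """ATM-weighted angular histogram for one center and one type pair.

    Sums over unordered pairs (j of type J, k of type K), j != k, both
    within ``r_cutoff`` of the center, of ``v_ijk * g(theta_jik)``.  The
    j-k distance is unconstrained; the distance dependence enters through
    the ATM weight itself.  Entries may be negative (ATM sign).
    """
    pos = config.positions
    i = int(center_index)
    type_j, type_k = neighbor_pair
    z_i = registry.z_of(str(config.types[i]))
    z_j = registry.z_of(type_j)
    z_k = registry.z_of(type_k)

    hist = np.zeros(params.n_bins_theta)

    def _in_cutoff(type_name):
        sel = (config.types == type_name)
        sel[i] = False
        if neighbor_mask is not None:
            sel = sel & neighbor_mask
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            return idx
        r = np.linalg.norm(pos[idx] - pos[i], axis=1)
        _check_coincident(r)
        return idx[r <= params.r_cutoff]

    idx_j = _in_cutoff(type_j)
    if type_j == type_k:
        if idx_j.size < 2:
            return hist
        jj, kk = np.triu_indices(idx_j.size, k=1)
        idx_a, idx_b = idx_j[jj], idx_j[kk]
    else:
        idx_k = _in_cutoff(type_k)
        if idx_j.size == 0 or idx_k.size == 0:
            return hist
        idx_a = np.repeat(idx_j, idx_k.size)
        idx_b = np.tile(idx_k, idx_j.size)
    r_ij, r_ik, r_jk, c_i, c_j, c_k = _triplet_geometry(pos, i, idx_a, idx_b)[:6]
    theta = np.arccos(c_i)
    v = _atm_weights(params, z_i, z_j, z_k, r_ij, r_ik, r_jk, c_i, c_j, c_k)
    profiles = _profile_matrix(
        theta,
        params.sigma_theta,
        params.theta_bin_centers,
        params.bin_width_theta,
        reflect=(0.0, params.theta_support),
    )
    return v @ profiles


def _atomic_contributions(
    config: Configuration,
    center_index: int,
    params: SlatmParams,
    registry: BeadTypeRegistry,
    neighbor_mask: np.ndarray | None = None,
):
    """Two-/three-body contributions of one center, present channels only.

    Shared fast path: neighbour distances are computed once, triplet pairs
    are enumerated once over the in-cutoff neighbour set (each unordered
    bead pair counted once) and grouped by type pair.
    """
    pos = config.positions
    i = int(center_index)
    z_i = registry.z_of(str(config.types[i]))

    sel = np.ones(config.n_beads, dtype=bool)
    sel[i] = False
    if neighbor_mask is not None:
        sel &= neighbor_mask
    idx = np.flatnonzero(sel)
    two: dict[str, np.ndarray] = {}
    three: dict[tuple[str, str], np.ndarray] = {}
    if idx.size == 0:
        return two, three
    r_all = np.linalg.norm(pos[idx] - pos[i], axis=1)
    _check_coincident(r_all)
    within = r_all <= params.r_cutoff
    nb = idx[within]
    r_nb = r_all[within]
    if nb.size == 0:
        return two, three

    type_codes = np.array(
        [registry.index_of(str(t)) for t in config.types[nb]], dtype=int
    )
    names = registry.names

    # two-body: group neighbours by type
    prof_r = _profile_matrix(
        r_nb, params.sigma_r, params.r_bin_centers, params.bin_width_r
    )
    for code in np.unique(type_codes):
        mask = type_codes == code
        z_j = registry.z_of(names[code])
        w = (
            params.two_body_prefactor
            * z_i
            * z_j
            * r_nb[mask] ** (-params.two_body_exponent)
        )
        two[names[code]] = w @ prof_r[mask]

    # three-body: all unordered neighbour pairs, grouped by type pair
    if nb.size >= 2:
        jj, kk = np.triu_indices(nb.size, k=1)
        idx_a, idx_b = nb[jj], nb[kk]
        r_ij, r_ik, r_jk, c_i, c_j, c_k, theta = _triplet_geometry(
            pos, i, idx_a, idx_b
        )
        code_a, code_b = type_codes[jj], type_codes[kk]
        lo = np.minimum(code_a, code_b)
        hi = np.maximum(code_a, code_b)
        pair_code = lo * len(names) + hi
        prof_t = _profile_matrix(
            theta,
            params.sigma_theta,
            params.theta_bin_centers,
            params.bin_width_theta,
            reflect=(0.0, params.theta_support),
        )
        for code in np.unique(pair_code):
            mask = pair_code == code
            a, b = divmod(int(code), len(names))
            z_j, z_k = registry.z_of(names[a]), registry.z_of(names[b])
            v = _atm_weights(
                params,
                z_i,
                z_j,
                z_k,
                r_ij[mask],
                r_ik[mask],
                r_jk[mask],
                c_i[mask],
                c_j[mask],
                c_k[mask],
            )
            three[(names[a], names[b])] = v @ prof_t[mask]
    return two, three


def atomic_slatm(
    config: Configuration,
    center_index: int,
    params: SlatmParams,
    registry: BeadTypeRegistry,
    channel_index: ChannelIndex,
    neighbor_mask: np.ndarray | None = None,
) -> AtomicSpectrum:
    """Full SLATM spectrum of one bead over every channel of the index.

    Channels with no contributing neighbours hold zero vectors; a single
    center carries N two-body and N(N+1)/2 three-body channels.
    """
    i = int(center_index)
    if not 0 <= i < config.n_beads:
        raise IndexError(f"center index {i} out of range")
    center_type = str(config.types[i])
    two, three = _atomic_contributions(
        config, i, params, registry, neighbor_mask
    )
    two_full = {
        j: two.get(j, np.zeros(params.n_bins_r)) for j in channel_index.one_body
    }
    three_full = {
        jk: three.get(jk, np.zeros(params.n_bins_theta))
        for jk in channel_index.two_body
    }
    return AtomicSpectrum(
        center_type=center_type,
        one_body=float(registry.z_of(center_type)),
        two_body=two_full,
        three_body=three_full,
        params=params,
    )
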