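"""Synthetic spherical head model and analytic EEG lead field.

The forward model is a current dipole inside a homogeneous conducting sphere
with an insulating exterior.  For that geometry the surface potential has an
exact closed form, obtained by summing the interior Legendre expansion: with
the dipole at radius ``b`` along unit vector ``b_hat``, an electrode on the
scalp sphere (radius ``R``) along ``r_hat``, ``f = b/R``, ``c = b_hat.r_hat``
and ``s = sqrt(1 - 2 f c + f**2)``,

    V = (1 / 4 pi sigma R^2) * [ q_r * S_rad  +  (q_t . (r_hat - c b_hat)) * S_tan ]

    S_rad = (2 f (c - f) / s^3 + 1/s - 1) / f        (-> 3 c as f -> 0)
    S_tan = 2 / s^3 + (1 + s) / (s (1 - f c + s))

where ``q_r`` is the radial component of the dipole moment and ``q_t`` its
tangential part.  ``S_rad`` and ``S_tan`` are the closed-form sums of the
series ``sum (2n+1) f^(n-1) P_n(c)`` and ``sum ((2n+1)/n) f^(n-1) P_n^1(c)``
(the latter carrying the ``sin(gamma)`` factor inside ``r_hat - c b_hat``).

Parcellation is schematic: 148 labels realised as angular patches on the
upper hemisphere of the source shell.  Only the label structure is meant to
be realistic; geometry exists so that the forward/inverse algebra is exact
and testable against the closed form.

Gain units are microvolts per nA*m of dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .labels import CREDIBILITY_LOOP_AREAS, PARCEL_LABELS

#: Default physical parameters: scalp radius [m] and conductivity [S/m].
DEFAULT_RADIUS = 0.09
DEFAULT_SIGMA = 0.33
#: Source shell radius as a fraction of the scalp radius.
DEFAULT_DIPOLE_FRAC = 0.8

_GEOMETRY_SEED = 780143  # fixed: head geometry is part of the model, not the draw


def fibonacci_hemisphere(n: int, z_min: float = 0.02) -> np.ndarray:
    """``n`` unit vectors quasi-uniformly covering the upper hemisphere."""
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sphere_dipole_potential(
    electrodes: np.ndarray,
    dip_pos: np.ndarray,
    dip_moment: np.ndarray,
    radius: float = DEFAULT_RADIUS,
    sigma: float = DEFAULT_SIGMA,
) -> np.ndarray:
    """Closed-form scalp potential of one dipole, per electrode.

    Parameters
    ----------
    electrodes
        ``(n_e, 3)`` positions on the scalp sphere [m].
    dip_pos, dip_moment
        Dipole position [m] (strictly inside the sphere) and moment [nA*m].

    Returns
    -------
    ndarray of shape ``(n_e,)`` -- potential in microvolts, not referenced.
    """
    electrodes = np.atleast_2d(np.asarray(electrodes, dtype=float))
    p = np.asarray(dip_pos, dtype=float)
    q = np.asarray(dip_moment, dtype=float)
    b = np.linalg.norm(p)
    if b >= radius:
        raise GeometryError(f"dipole at radius {b:.4f} m outside sphere {radius} m")
    r_hat = electrodes / np.linalg.norm(electrodes, axis=1, keepdims=True)
    # nA*m -> A*m (1e-9) and V -> uV (1e6)
    scale = 1e-3 / (4.0 * np.pi * sigma * radius**2)
    if b < 1e-12 * radius:
        return 3.0 * scale * (r_hat @ q)
    b_hat = p / b
    f = b / radius
    c = r_hat @ b_hat
    s = np.sqrt(1.0 - 2.0 * f * c + f * f)
    q_r = q @ b_hat
    q_t = q - q_r * b_hat
    s_rad = (2.0 * f * (c - f) / s**3 + 1.0 / s - 1.0) / f
    s_tan = 2.0 / s**3 + (1.0 + s) / (s * (1.0 - f * c + s))
    tang = (r_hat - c[:, None] * b_hat[None, :]) @ q_t
    return scale * (q_r * s_rad + tang * s_tan)


@dataclass
class LeadField:
    """Channels x dipoles gain matrix with a parcel assignment per dipole.

    Columns are average-referenced.  ``dipole_parcels[j]`` is the index into
    ``parcel_labels`` of the parcel containing dipole ``j``; dipoles carry
    fixed radial (surface-normal on the spherical shell) orientations.
    """

    gain: np.ndarray                 # (n_channels, n_dipoles), uV per nA*m
    dipole_parcels: np.ndarray       # (n_dipoles,), int
    parcel_labels: list[str]
    electrode_pos: np.ndarray        # (n_channels, 3) [m]
    dipole_pos: np.ndarray           # (n_dipoles, 3) [m]
    dipole_ori: np.ndarray           # (n_dipoles, 3), unit vectors
    radius: float = DEFAULT_RADIUS
    sigma: float = DEFAULT_SIGMA

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.gain.shape[1]

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_labels)

    def parcel_dipoles(self, label_or_index) -> np.ndarray:
        """Dipole indices belonging to one parcel."""
        if isinstance(label_or_index, str):
            idx = self.parcel_labels.index(label_or_index)
        else:
            idx = int(label_or_index)
        return np.flatnonzero(self.dipole_parcels == idx)

    def parcel_pattern(self, labels) -> np.ndarray:
        """Summed gain column over the dipoles of the given parcels.

        The sensor topography produced by a unit source current in every
        dipole of the listed parcels -- the building block for injecting
        area-localized effects.
        """
        if isinstance(labels, str):
            labels = [labels]
        cols = np.concatenate([self.parcel_dipoles(lb) for lb in labels])
        return self.gain[:, cols].sum(axis=1)


def project_sources(lead: LeadField, source_tc: np.ndarray) -> np.ndarray:
    """Project dipole time courses (n_dipoles x n_samples) to the sensors."""
    if source_tc.shape[0] != lead.n_dipoles:
        raise GeometryError(
            f"source has {source_tc.shape[0]} dipoles, lead field {lead.n_dipoles}"
        )
    return lead.gain @ source_tc


def build_head_model(
    n_channels: int = 64,
    n_dipoles: int = 2048,
    parcel_labels: list[str] | None = None,
    radius: float = DEFAULT_RADIUS,
    sigma: float = DEFAULT_SIGMA,
    dipole_frac: float = DEFAULT_DIPOLE_FRAC,
    priority_labels: list[str] | None = None,
) -> LeadField:
    """Build the analytic spherical lead field.

    Electrodes sit on the scalp sphere, quasi-uniform on the upper
    hemisphere.  Each parcel owns an angular patch around a quasi-uniform
    centre direction on the source shell (radius ``dipole_frac * radius``);
    its dipoles are deterministically jittered around the centre with radial
    orientation.  Every parcel receives at least one dipole.

    ``priority_labels`` (default: the credibility-loop parcels) are placed
    under the vertex, beneath the cognitive-electrode patch -- the synthetic
    analogue of the study geometry in which the parcels carrying condition
    effects are visible in the cognitive ERP.  The remaining labels fill the
    remaining patch centres in their fixed order.
    """
    if parcel_labels is None:
        parcel_labels = list(PARCEL_LABELS)
    if priority_labels is None:
        priority_labels = [lb for lb in CREDIBILITY_LOOP_AREAS if lb in parcel_labels]
    n_parcels = len(parcel_labels)
    if n_dipoles < n_parcels:
        raise GeometryError(
            f"need at least one dipole per parcel ({n_parcels}), got {n_dipoles}"
        )
    if not 0.0 < dipole_frac < 1.0:
        raise GeometryError("dipole shell must be strictly inside the sphere")

    electrodes = radius * fibonacci_hemisphere(n_channels)
    raw_centers = fibonacci_hemisphere(n_parcels, z_min=0.05)
    # vertex-proximal centres go to the priority parcels, the rest follow
    # label order on the remaining centres
    by_height = np.argsort(-raw_centers[:, 2], kind="stable")
    label_order = list(priority_labels) + [
        lb for lb in parcel_labels if lb not in priority_labels
    ]
    centers = np.empty_like(raw_centers)
    for rank, lb in enumerate(label_order):
        centers[parcel_labels.index(lb)] = raw_centers[by_height[rank]]

    # per-parcel dipole counts: as even as possible, remainder to the front
    base, extra = divmod(n_dipoles, n_parcels)
    counts = np.full(n_parcels, base, dtype=int)
    counts[:extra] += 1

    # patch angular half-width ~ sqrt(hemisphere area / n_parcels)
    patch_rad = 0.6 * np.sqrt(2.0 / n_parcels)
    rng = np.random.default_rng(_GEOMETRY_SEED)

    dip_dirs = []
    dip_parcels = []
    for p in range(n_parcels):
        u = centers[p]
        # tangential basis at u
        helper = np.array([0.0, 0.0, 1.0])
        if abs(u[2]) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(u, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        offsets = rng.normal(scale=patch_rad, size=(counts[p], 2))
        d = u[None, :] + offsets[:, :1] * e1[None, :] + offsets[:, 1:] * e2[None, :]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        dip_dirs.append(d)
        dip_parcels.extend([p] * counts[p])

    dirs = np.vstack(dip_dirs)
    dipole_pos = dipole_frac * radius * dirs
    dipole_ori = dirs  # radial

    gain = np.empty((n_channels, len(dirs)))
    for j in range(len(dirs)):
        gain[:, j] = sphere_dipole_potential(
            electrodes, dipole_pos[j], dipole_ori[j], radius=radius, sigma=sigma
        )
    gain -= gain.mean(axis=0, keepdims=True)  # average reference

    return LeadField(
        gain=gain,
        dipole_parcels=np.asarray(dip_parcels, dtype=int),
        parcel_labels=list(parcel_labels),
        electrode_pos=electrodes,
        dipole_pos=dipole_pos,
        dipole_ori=dipole_ori,
        radius=radius,
        sigma=sigma,
    )


def cognitive_channel_indices(lead: LeadField, n: int = 26) -> list[int]:
    """Default cognitive-electrode subset: the ``n`` channels nearest the vertex."""
    order = np.argsort(-lead.electrode_pos[:, 2], kind="stable")
    return sorted(int(i) for i in order[:n])
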