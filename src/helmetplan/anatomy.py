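"""Voxel tissue phantoms and tissue property lookups.

The package operates on cell-centered voxel label grids (x right, y anterior,
z cranial; 4 mm isotropic spacing by default) with a per-tissue property
table holding dielectric values at the discrete operating frequencies
{250, 375, 500} MHz and thermal values for the bioheat stage.

Two generators are provided: a concentric layered sphere enclosed in a
spherical water bolus (used for the antenna-coupling experiments) and a
layered ellipsoidal synthetic head with a caudal muscle fill, eyes, and an
embedded tumor blob of prescribed volume (a stand-in for a segmented
patient; synthetic by construction).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import C0, EPS0, ETA0

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "TissueModel",
    "PhantomSpec",
    "TumorSpec",
    "load_property_table",
    "build_layered_sphere_phantom",
    "build_synthetic_patient",
    "lookup_properties",
    "intrinsic_impedance",
    "wavelength_in",
]

# Canonical label ids. 0 is always exterior background (air or water,
# depending on context); every other id present in a grid must have a row in
# the property table.
LABELS = {
    "background": 0,
    "water": 1,
    "skin": 2,
    "muscle": 3,
    "bone_cortical": 4,
    "csf": 5,
    "brain_gray": 6,
    "brain_white": 7,
    "eye_vitreous": 8,
    "cartilage": 9,
    "pharynx_air": 10,
    "tumor": 11,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


def load_property_table(path=None) -> dict:
    """Load the per-tissue property table.

    Returns ``{"frequencies_hz": [...], "tissues": {name: {...}}}`` from the
    packaged YAML, or from ``path`` if given.
    """
    if path is None:
        ref = importlib.resources.files("helmetplan.data") / "tissue_properties.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = yaml.safe_load(text)
    table["frequencies_hz"] = [float(f) for f in table["frequencies_hz"]]
    return table


def intrinsic_impedance(eps_r, sigma, f, lossy: bool = True):
    """Intrinsic impedance of a (lossy) medium, eta = eta0 / sqrt(eps_c).

    With ``lossy=True`` the complex permittivity eps_r - j sigma/(omega eps0)
    is used; otherwise only the real permittivity. Vacuum returns eta0.
    """
    eps_r = np.asarray(eps_r, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if lossy:
        eps_c = eps_r - 1j * sigma / (2 * np.pi * f * EPS0)
    else:
        eps_c = eps_r.astype(complex)
    return ETA0 / np.sqrt(eps_c)


def wavelength_in(eps_r, f) -> float:
    """Lossless wavelength in a medium of relative permittivity eps_r, in m."""
    return C0 / (f * np.sqrt(eps_r))


@dataclass
class TissueModel:
    """Voxel label grid plus tissue property and frequency tables.

    ``labels`` is indexed ``[ix, iy, iz]``; the center of voxel (0,0,0) sits
    at ``origin`` (mm) and centers advance by ``spacing`` (mm) per index.
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    property_table: dict = None
    frequency_set: tuple = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        if self.property_table is None:
            self.property_table = load_property_table()
        if self.frequency_set is None:
            self.frequency_set = tuple(self.property_table["frequencies_hz"])

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self):
        """Per-axis voxel-center coordinates in mm."""
        return [self.origin[k] + self.spacing[k] * np.arange(self.labels.shape[k])
                for k in range(3)]

    def voxel_centers(self):
        """(nx, ny, nz, 3) array of voxel-center coordinates in mm."""
        cx, cy, cz = self.axis_coords()
        X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def point_to_index(self, points_mm):
        """Fractional voxel indices of physical points (mm)."""
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing

    def mask(self, *names) -> np.ndarray:
        ids = [LABELS[n] for n in names]
        return np.isin(self.labels, ids)

    @property
    def patient_mask(self) -> np.ndarray:
        """Tissue voxels: everything except background, water, and air gaps."""
        return ~np.isin(self.labels, [LABELS["background"], LABELS["water"],
                                      LABELS["pharynx_air"]])

    # -- property lookups -------------------------------------------------
    def _freq_index(self, f: float) -> int:
        freqs = np.asarray(self.property_table["frequencies_hz"])
        i = int(np.argmin(np.abs(freqs - f)))
        if abs(freqs[i] - f) > 1e-3 * f + 1.0:
            raise ValueError(f"frequency {f} Hz not in table {freqs.tolist()}")
        return i

    def tissue_scalar(self, name: str, quantity: str, f: float = None) -> float:
        row = self.property_table["tissues"][name]
        if quantity in ("eps_r", "sigma"):
            return float(row[quantity][self._freq_index(f)])
        return float(row[quantity])

    def property_map(self, quantity: str, f: float = None) -> np.ndarray:
        """Per-voxel map of a tissue property.

        ``quantity`` is one of eps_r, sigma (frequency-dependent, require
        ``f``), rho, cp, k_th, perfusion. Background voxels take the values
        of air (eps_r=1, sigma=0, and negligible thermal coupling).
        """
        air = {"eps_r": 1.0, "sigma": 0.0, "rho": 1.2, "cp": 1004.0,
               "k_th": 0.026, "perfusion": 0.0}
        present = np.unique(self.labels)
        lut = np.zeros(int(present.max()) + 1, dtype=float)
        for lab in present:
            lab = int(lab)
            if lab == 0:
                lut[lab] = air[quantity]
                continue
            name = LABEL_NAMES.get(lab)
            if name is None or name not in self.property_table["tissues"]:
                raise KeyError(f"no property row for label {lab}"
                               f" ({name or 'unknown'})")
            lut[lab] = self.tissue_scalar(name, quantity, f)
        return lut[self.labels]

    def eta_map(self, f: float, lossy: bool = True) -> np.ndarray:
        """Per-voxel complex intrinsic impedance at frequency f."""
        eps = self.property_map("eps_r", f)
        sig = self.property_map("sigma", f)
        return intrinsic_impedance(eps, sig, f, lossy=lossy)


@dataclass
class TumorSpec:
    center_mm: tuple = (0.0, -40.0, -30.0)
    volume_ml: float = 126.0       # default target volume (medulloblastoma-sized)
    axis_ratio_jitter: float = 0.3  # random semi-axis spread of the blob


@dataclass
class PhantomSpec:
    """Concentric layered-sphere phantom: skin/bone/CSF shells over a brain
    core, enclosed in a spherical water bolus."""

    outer_radius: float = 96.9          # mm, scalp radius
    shell_thicknesses: tuple = (6.3, 6.8, 10.7)  # mm: skin, bone, CSF
    bolus_thickness: float = 50.0       # mm of water outside the scalp
    tumor: TumorSpec = None

    def __post_init__(self):
        if self.outer_radius <= 0 or any(t < 0 for t in self.shell_thicknesses):
            raise ValueError("radii and shell thicknesses must be nonnegative")
        if sum(self.shell_thicknesses) >= self.outer_radius:
            raise ValueError("shells thicker than the phantom radius")

    @property
    def core_radius(self) -> float:
        return self.outer_radius - sum(self.shell_thicknesses)


def _centered_grid(half_extent_mm, spacing):
    """Cell-centered cube grid covering [-h, h]^3."""
    n = int(np.ceil(2 * half_extent_mm / spacing))
    origin = -(n - 1) / 2 * spacing
    return n, np.full(3, origin)


def build_layered_sphere_phantom(spec: PhantomSpec, spacing: float = 4.0,
                                 property_table: dict = None) -> TissueModel:
    """Voxelize the layered sphere phantom by cell-center radius test."""
    flags = []
    for name, t in zip(("skin", "bone", "csf"), spec.shell_thicknesses):
        if 0 < t < spacing:
            flags.append(f"under-resolved shell: {name} ({t} mm < {spacing} mm voxel)")
        elif 0 < t < 3 * spacing:
            flags.append(f"thin shell: {name} spans < 3 voxels at {spacing} mm")

    r_bolus = spec.outer_radius + spec.bolus_thickness
    n, origin = _centered_grid(r_bolus + spacing, spacing)
    ax = origin[0] + spacing * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)

    t_skin, t_bone, t_csf = spec.shell_thicknesses
    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[r <= r_bolus] = LABELS["water"]
    labels[r <= spec.outer_radius] = LABELS["skin"]
    labels[r <= spec.outer_radius - t_skin] = LABELS["bone_cortical"]
    labels[r <= spec.outer_radius - t_skin - t_bone] = LABELS["csf"]
    labels[r <= spec.core_radius] = LABELS["brain_gray"]

    model = TissueModel(labels, np.full(3, float(spacing)), origin,
                        property_table=property_table, flags=flags)
    if spec.tumor is not None:
        brain = model.mask("brain_gray")
        _carve_tumor(model, spec.tumor, brain, rng=np.random.default_rng(0))
    return model


def _carve_tumor(model: TissueModel, tumor: TumorSpec, allowed: np.ndarray,
                 rng: np.random.Generator, tol: float = 0.05) -> None:
    """Label a tumor blob of the requested volume inside ``allowed`` voxels.

    The blob is a randomly oriented ellipsoid scaled iteratively until the
    voxelized volume is within ``tol`` of the target (clipped to the allowed
    compartment). Raises if the compartment cannot host the volume.
    """
    target_mm3 = tumor.volume_ml * 1000.0
    avail_mm3 = allowed.sum() * model.voxel_volume_mm3
    if avail_mm3 < target_mm3:
        raise ValueError(
            f"tumor volume {tumor.volume_ml} mL exceeds the host compartment"
            f" ({avail_mm3 / 1000.0:.1f} mL available)")

    jit = tumor.axis_ratio_jitter
    ratios = 1.0 + rng.uniform(-jit, jit, size=3)
    # random rotation from a QR decomposition of a Gaussian matrix
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1

    XYZ = model.voxel_centers() - np.asarray(tumor.center_mm, dtype=float)
    local = XYZ @ q  # coordinates in the blob frame

    # semi-axes for a unit scale; volume of ellipsoid = 4/3 pi prod(axes)
    base_axes = ratios * (target_mm3 / (4.0 / 3.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    scale = 1.0
    for _ in range(25):
        axes = base_axes * scale
        inside = (np.sum((local / axes) ** 2, axis=-1) <= 1.0) & allowed
        vol = inside.sum() * model.voxel_volume_mm3
        if vol == 0:
            scale *= 1.5
            continue
        if abs(vol - target_mm3) / target_mm3 <= tol * 0.6:
            break
        scale *= (target_mm3 / vol) ** (1.0 / 3.0)
    else:
        inside = (np.sum((local / (base_axes * scale)) ** 2, axis=-1) <= 1.0) & allowed
        vol = inside.sum() * model.voxel_volume_mm3
    if abs(vol - target_mm3) / target_mm3 > tol:
        raise ValueError(
            f"could not voxelize tumor to {tumor.volume_ml} mL within "
            f"{tol:.0%} (achieved {vol / 1000.0:.1f} mL)")
    model.labels[inside] = LABELS["tumor"]


def _inside_ellipsoid(XYZ, center, radii):
    radii = np.maximum(np.asarray(radii, dtype=float), 1e-9)
    return np.sum(((XYZ - center) / radii) ** 2, axis=-1) <= 1.0


def build_synthetic_patient(seed: int = 0,
                            head_radii=(75.0, 92.0, 94.0),
                            tumor_spec: TumorSpec | None = TumorSpec(),
                            spacing: float = 4.0,
                            bolus_radii=None,
                            trim_offset: float = 77.0,
                            property_table: dict = None) -> TissueModel:
    """Layered ellipsoidal head with caudal muscle fill and optional tumor.

    The head is a stack of coaxial ellipsoids (skin, cortical bone, CSF,
    gray matter, white matter) centered at the origin; the caudal region is
    filled with muscle to emulate the rest of the body, two vitreous-humor
    eyes sit on the anterior face, and a small pharyngeal air duct runs
    caudally. ``bolus_radii`` (default ``head_radii + 50 mm``) carves the
    surrounding water bolus, trimmed ``trim_offset`` mm caudal to center.
    Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    a, b, c = (float(r) for r in head_radii)
    if bolus_radii is None:
        bolus_radii = (a + 50.0, b + 50.0, c + 50.0)
    ab, bb, cb = (float(r) for r in bolus_radii)

    half = max(ab, bb, cb) + 2 * spacing
    n, origin = _centered_grid(half, spacing)
    model = TissueModel(np.zeros((n, n, n), dtype=np.int16),
                        np.full(3, float(spacing)), origin,
                        property_table=property_table)
    XYZ = model.voxel_centers()
    labels = model.labels

    # water bolus (trimmed caudally to leave a breathing opening)
    in_bolus = _inside_ellipsoid(XYZ, np.zeros(3), (ab, bb, cb))
    in_bolus &= XYZ[..., 2] >= -trim_offset
    labels[in_bolus] = LABELS["water"]

    # head shells, offset inward per shell thickness along every semi-axis
    t_skin, t_bone, t_csf, t_gray = 6.3, 6.8, 10.7, 15.0
    shells = [
        ("skin", (a, b, c)),
        ("bone_cortical", (a - t_skin, b - t_skin, c - t_skin)),
        ("csf", (a - t_skin - t_bone,
                 b - t_skin - t_bone,
                 c - t_skin - t_bone)),
        ("brain_gray", (a - t_skin - t_bone - t_csf,
                        b - t_skin - t_bone - t_csf,
                        c - t_skin - t_bone - t_csf)),
        ("brain_white", (a - t_skin - t_bone - t_csf - t_gray,
                         b - t_skin - t_bone - t_csf - t_gray,
                         c - t_skin - t_bone - t_csf - t_gray)),
    ]
    for name, radii in shells:
        labels[_inside_ellipsoid(XYZ, np.zeros(3), radii)] = LABELS[name]

    # caudal fill: muscle below the brain stem, down to the domain floor,
    # within a neck cylinder and the head envelope
    z = XYZ[..., 2]
    rho_xy = np.sqrt(XYZ[..., 0] ** 2 + XYZ[..., 1] ** 2)
    z_neck = -c + 35.0
    fill = (z < z_neck) & ((rho_xy <= 0.55 * min(a, b)) |
                           _inside_ellipsoid(XYZ, np.zeros(3), (a, b, c)))
    labels[fill] = LABELS["muscle"]

    # pharyngeal air duct
    duct = (z < z_neck + 15.0) & (np.sqrt(XYZ[..., 0] ** 2 +
                                          (XYZ[..., 1] - 25.0) ** 2) <= 8.0)
    labels[duct & (labels == LABELS["muscle"])] = LABELS["pharynx_air"]

    # eyes: two vitreous spheres on the anterior face
    for sx in (-1.0, 1.0):
        eye_c = np.array([sx * 30.0, b - 16.0, -18.0])
        labels[_inside_ellipsoid(XYZ, eye_c, (11.0, 11.0, 11.0))] = LABELS["eye_vitreous"]

    if tumor_spec is not None:
        allowed = model.mask("brain_gray", "brain_white")
        _carve_tumor(model, tumor_spec, allowed, rng)
    return model


def lookup_properties(model: TissueModel, f: float, lossy_eta: bool = True):
    """Per-voxel (eps_r, sigma, rho, eta) maps at frequency ``f``."""
    eps = model.property_map("eps_r", f)
    sigma = model.property_map("sigma", f)
    rho = model.property_map("rho")
    eta = intrinsic_impedance(eps, sigma, f, lossy=lossy_eta)
    return eps, sigma, rho, eta
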