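"""Synthetic implant-in-bone micro-CT phantoms with analytic ground truth.

The generator builds a grayscale volume containing a threaded titanium-like
cylinder embedded in cortical bone, with a *prescribed* osseointegration
pattern: an angular-sector × groove contact map states, for every groove ring
and every angular position around the implant axis, whether bone touches the
thread profile there.  Where the map says "no contact" a gap of background
intensity (a few voxels wide) separates bone from metal, emulating fibrous
or unmineralised interface tissue.

Because the thread is modelled as annular rings rather than a true helix,
every longitudinal plane sees the identical groove geometry, and the
bone-to-implant contact ratio (BIC) of any plane can be computed *exactly*
from the contact map: each groove's exposed profile arc at a given plane
angle is either fully in contact or fully free.  That analytic value is the
ground truth against which the measurement pipeline is validated.

On top of the clean geometry, :func:`add_artifacts` emulates the residual
imperfections of reconstructed scans around metal:

* a bright one-or-few-voxel *halo* at the interface (residual beam
  hardening), modelled as a saturating floor — shell voxels are raised to at
  least the halo intensity, so dark gap voxels become bone-like while bone
  stays bone;
* *ceramic granules* (β-TCP remnants) at bone-like intensity scattered
  through the peri-implant region — deliberately indistinguishable from bone
  by thresholding, reproducing the confound that inflates CT-measured BIC
  relative to histology;
* additive Gaussian noise, clipped to the 8-bit range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Volume

DEFAULT_ANGLES = (0.0, 45.0, 90.0, 135.0)


@dataclass
class PhantomConfig:
    """Geometry, intensity and artifact parameters of a synthetic scan.

    Defaults describe the modelled study conditions: a Ø 4 mm × 8.5 mm dental
    implant scanned at 20 µm isotropic resolution, with 8-bit class
    intensities placing bone at the centre of the default 60–90 threshold
    window.  Thread pitch and depth are free parameters of the generator (no
    measured values exist for them); the defaults give six complete grooves
    per side, comfortably more than the four that are measured.
    """

    implant_diameter_um: float = 4000.0
    implant_length_um: float = 8500.0
    thread_depth_um: float = 600.0
    thread_pitch_um: float = 1200.0
    crest_axial_fraction: float = 0.4
    bone_outer_radius_um: float = 3000.0
    volume_shape: tuple[int, int, int] = (464, 320, 320)
    voxel_size_um: float = 20.0
    intensity_background: float = 20.0
    intensity_bone: float = 75.0
    intensity_implant: float = 230.0
    noise_sd: float = 0.0
    halo_width_voxels: int = 0
    halo_intensity: float = 75.0
    granule_count: int = 0
    granule_radius_um: float = 40.0
    granule_intensity: float | None = None  # None -> bone intensity
    contact_gap_voxels: int = 3
    seed: int = 0

    # -- derived geometry (voxel units) ------------------------------------
    @property
    def radius_vox(self) -> float:
        return self.implant_diameter_um / 2.0 / self.voxel_size_um

    @property
    def core_radius_vox(self) -> float:
        return self.radius_vox - self.thread_depth_um / self.voxel_size_um

    @property
    def length_vox(self) -> int:
        return int(round(self.implant_length_um / self.voxel_size_um))

    @property
    def pitch_vox(self) -> int:
        return int(round(self.thread_pitch_um / self.voxel_size_um))

    @property
    def crest_width_vox(self) -> int:
        return max(1, int(round(self.crest_axial_fraction * self.pitch_vox)))

    @property
    def bone_outer_radius_vox(self) -> float:
        return self.bone_outer_radius_um / self.voxel_size_um

    @property
    def n_crests(self) -> int:
        return (self.length_vox - self.crest_width_vox) // self.pitch_vox + 1

    @property
    def grooves_per_side_available(self) -> int:
        return self.n_crests - 1

    @property
    def axis_center(self) -> tuple[int, int]:
        """(cy, cx) of the implant axis, on voxel centres."""
        return self.volume_shape[1] // 2, self.volume_shape[2] // 2

    @property
    def z_top(self) -> int:
        return (self.volume_shape[0] - self.length_vox) // 2

    @classmethod
    def validation_scale(cls, **overrides) -> "PhantomConfig":
        """Geometrically similar phantom at validation scale.

        A Ø 0.8 mm × 2.4 mm implant on a 144 x 128 x 128 grid at the native
        20 µm voxel size: every geometric ratio that matters to the
        measurement (thread depth/pitch relative to diameter, groove count
        above the minimum measured, bone annulus width in voxels) is
        preserved while volumes stay small enough for exhaustive validation
        sweeps.
        """
        params = dict(
            implant_diameter_um=800.0,
            implant_length_um=2400.0,
            thread_depth_um=160.0,
            thread_pitch_um=400.0,
            bone_outer_radius_um=1000.0,
            volume_shape=(144, 128, 128),
            voxel_size_um=20.0,
        )
        params.update(overrides)
        return cls(**params)

    def crest_centers_z(self) -> np.ndarray:
        k = np.arange(self.n_crests)
        return self.z_top + k * self.pitch_vox + self.crest_width_vox / 2.0

    def __post_init__(self) -> None:
        nz, ny, nx = self.volume_shape
        margin_xy = min(ny, nx) / 2.0 - self.bone_outer_radius_vox
        margin_z = (nz - self.length_vox) / 2.0
        if margin_xy < 2 or margin_z < 2:
            raise ValueError(
                "implant/bone geometry does not fit in the volume with a 2-voxel margin "
                f"(xy margin {margin_xy:.1f}, z margin {margin_z:.1f} voxels)"
            )
        if not (self.intensity_background < self.intensity_bone < self.intensity_implant):
            raise ValueError("class intensities must be ordered background < bone < implant")
        # class means must be separable by the default windows
        if not (self.intensity_background < 60 <= self.intensity_bone <= 90 < self.intensity_implant):
            raise ValueError(
                "class intensities must be separable by the default segmentation windows "
                "(background < 60 <= bone <= 90 < implant)"
            )
        if self.core_radius_vox < 2:
            raise ValueError("thread depth leaves no implant core")
        if self.grooves_per_side_available < 4:
            raise ValueError(
                f"geometry yields only {self.grooves_per_side_available} grooves per side; >= 4 required"
            )
        if self.halo_width_voxels < 0 or self.granule_count < 0:
            raise ValueError("halo_width_voxels and granule_count must be >= 0")
        if self.contact_gap_voxels < 2:
            raise ValueError("contact_gap_voxels must be >= 2 (no-contact gap must be resolvable)")


@dataclass
class ContactMap:
    """Piecewise-constant osseointegration pattern over sectors × grooves.

    ``contact[g, s]`` says whether groove ring ``g`` (0-based from the
    implant top) is bone-contacting within angular sector ``s``.  Sector
    ``s`` is centred on ``s * (360 / granularity)`` degrees, so the default
    measurement angles fall at sector centres for the default granularity 8.
    """

    contact: np.ndarray  # bool, shape (n_grooves, granularity)
    target_fraction: float
    seed: int

    def __post_init__(self) -> None:
        self.contact = np.asarray(self.contact, dtype=bool)
        if self.contact.ndim != 2 or self.contact.shape[1] < 4:
            raise ValueError("contact map needs shape (n_grooves, granularity >= 4)")

    @property
    def n_grooves(self) -> int:
        return self.contact.shape[0]

    @property
    def granularity(self) -> int:
        return self.contact.shape[1]

    def sector_of(self, angle_deg) -> np.ndarray | int:
        width = 360.0 / self.granularity
        return np.round(np.asarray(angle_deg) / width).astype(int) % self.granularity

    def indicator(self, angle_deg: float, groove_index: int) -> bool:
        """True iff groove ``groove_index`` (1-based from top) contacts bone at ``angle_deg``."""
        if not 1 <= groove_index <= self.n_grooves:
            raise IndexError(f"groove {groove_index} outside 1..{self.n_grooves}")
        return bool(self.contact[groove_index - 1, self.sector_of(angle_deg % 360.0)])

    def fraction(self) -> float:
        return float(self.contact.mean())


def sample_contact_map(
    target_fraction: float,
    granularity: int = 8,
    seed: int = 0,
    n_grooves: int = 6,
) -> ContactMap:
    """Draw a random contact map with (near-)exact global contact fraction.

    Each groove ring gets exactly ``round(target_fraction * granularity)``
    contacting sectors, chosen through a seeded per-groove permutation.  The
    permutations are nested: raising the target (same seed) only ever adds
    sectors, so ground-truth BIC is monotone in the target fraction.
    """
    if not (0.0 <= target_fraction <= 1.0):
        raise ValueError(f"target_fraction must lie in [0, 1], got {target_fraction}")
    if granularity < 4:
        raise ValueError("granularity must be >= 4")
    rng = np.random.default_rng(seed)
    k = int(round(target_fraction * granularity))
    contact = np.zeros((n_grooves, granularity), dtype=bool)
    for g in range(n_grooves):
        order = rng.permutation(granularity)
        contact[g, order[:k]] = True
    return ContactMap(contact=contact, target_fraction=target_fraction, seed=seed)


@dataclass
class GroundTruth:
    """Analytic BIC of a phantom: per plane-and-groove, per plane, and overall.

    ``per_plane_groove`` maps ``(angle_deg, side, groove_index)`` → BIC %
    (0 or 100 for a sector-constant map); ``per_plane`` maps angle → BIC %
    over the measured grooves; ``bic_mean_percent`` is the arithmetic mean of
    the per-plane values (the multi-slice summary measure).
    """

    per_plane_groove: dict
    per_plane: dict
    bic_mean_percent: float
    contact_map: ContactMap
    config: PhantomConfig
    grooves_measured: int = 4

    def __post_init__(self) -> None:
        vals = list(self.per_plane.values()) + [self.bic_mean_percent] + list(
            self.per_plane_groove.values()
        )
        if any(not (0.0 <= v <= 100.0) for v in vals):
            raise ValueError("ground-truth BIC values must lie in [0, 100]")
        if abs(self.bic_mean_percent - float(np.mean(list(self.per_plane.values())))) > 1e-9:
            raise ValueError("multi-angle mean must equal the mean of per-plane values")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"angle_deg": a, "side": side, "groove_id": g, "bic_percent": v}
            for (a, side, g), v in sorted(self.per_plane_groove.items())
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "bic_mean_percent": self.bic_mean_percent,
            "per_plane_percent": {str(a): v for a, v in self.per_plane.items()},
            "target_fraction": self.contact_map.target_fraction,
            "grooves_measured": self.grooves_measured,
        }

    def export(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def _cylinder_fields(cfg: PhantomConfig):
    """Per-plane radius/angle fields and the per-z surface radius profile."""
    nz, ny, nx = cfg.volume_shape
    cy, cx = cfg.axis_center
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(yy - cy, xx - cx)
    phi = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    z = np.arange(nz)
    in_range = (z >= cfg.z_top) & (z < cfg.z_top + cfg.length_vox)
    in_crest = in_range & (((z - cfg.z_top) % cfg.pitch_vox) < cfg.crest_width_vox)
    surf = np.where(in_crest, cfg.radius_vox, cfg.core_radius_vox)
    return rr, phi, in_range, surf


def implant_mask(cfg: PhantomConfig) -> np.ndarray:
    """Boolean mask of the threaded-cylinder implant (annular-ring thread model)."""
    rr, _, in_range, surf = _cylinder_fields(cfg)
    return in_range[:, None, None] & (rr[None, :, :] <= surf[:, None, None])


def _ground_truth(cfg: PhantomConfig, cm: ContactMap, angles: Sequence[float], grooves_measured: int) -> GroundTruth:
    per_pg: dict = {}
    per_plane: dict = {}
    for a in angles:
        vals = []
        for g in range(1, cm.n_grooves + 1):
            right = 100.0 * cm.indicator(a, g)
            left = 100.0 * cm.indicator(a + 180.0, g)
            per_pg[(a, "right", g)] = right
            per_pg[(a, "left", g)] = left
            if g <= grooves_measured:
                vals.extend([right, left])
        per_plane[a] = float(np.mean(vals))
    return GroundTruth(
        per_plane_groove=per_pg,
        per_plane=per_plane,
        bic_mean_percent=float(np.mean(list(per_plane.values()))),
        contact_map=cm,
        config=cfg,
        grooves_measured=grooves_measured,
    )


def build_phantom(
    cfg: PhantomConfig,
    cm: ContactMap,
    angles: Sequence[float] = DEFAULT_ANGLES,
    grooves_measured: int = 4,
) -> tuple[Volume, GroundTruth]:
    """Construct the noise-free grayscale phantom and its analytic ground truth.

    Bone fills the annulus between the implant surface and
    ``bone_outer_radius`` along the implant span.  In every (groove, sector)
    cell the contact map marks "no contact", bone within
    ``contact_gap_voxels`` (chessboard distance) of the implant is carved
    back to background, leaving a clean separation gap; where it marks
    "contact", bone touches the thread profile directly.  Deterministic given
    the config.
    """
    if cm.n_grooves < cfg.grooves_per_side_available:
        raise ValueError(
            f"contact map covers {cm.n_grooves} grooves; phantom has {cfg.grooves_per_side_available}"
        )
    rr, phi, in_range, surf = _cylinder_fields(cfg)
    implant = in_range[:, None, None] & (rr[None, :, :] <= surf[:, None, None])
    bone = in_range[:, None, None] & (rr[None, :, :] <= cfg.bone_outer_radius_vox) & ~implant

    # carve separation gaps where the map prescribes no contact
    dist = ndimage.distance_transform_cdt(~implant, metric="chessboard")
    near = dist <= cfg.contact_gap_voxels
    sector2d = cm.sector_of(phi)
    zc = cfg.crest_centers_z()
    for g in range(cfg.grooves_per_side_available):
        z_lo, z_hi = int(np.ceil(zc[g])), int(np.ceil(zc[g + 1]))
        no_contact2d = ~cm.contact[g, sector2d]  # (ny, nx)
        sl = slice(z_lo, z_hi)
        bone[sl] &= ~(no_contact2d[None, :, :] & near[sl])

    voxels = np.full(cfg.volume_shape, cfg.intensity_background, dtype=np.float32)
    voxels[bone] = cfg.intensity_bone
    voxels[implant] = cfg.intensity_implant
    gt = _ground_truth(cfg, cm, angles, grooves_measured)
    return Volume(voxels=voxels, voxel_size_um=cfg.voxel_size_um), gt


def add_artifacts(v: Volume, cfg: PhantomConfig, rng: np.random.Generator | None = None) -> Volume:
    """Apply residual-reconstruction artifacts: interface halo, granules, noise.

    * Halo: voxels within ``halo_width_voxels`` (chessboard) of the implant,
      excluding the implant itself, are raised to at least
      ``halo_intensity`` (saturating floor, then clipped) — a bright
      beam-hardening band that thresholding mistakes for bone.
    * Granules: ``granule_count`` spheres of ``granule_radius_um`` at
      bone-like intensity, uniformly placed over the non-implant
      peri-implant region (seeded).
    * Noise: additive Gaussian of ``noise_sd``, clipped to [0, 255].

    With halo 0 / granules 0 / noise 0 the output is voxel-identical to the
    input.  Reproducible for a fixed ``cfg.seed`` (or a supplied ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = v.voxels.astype(np.float32, copy=True)
    imp_thr = (cfg.intensity_bone + cfg.intensity_implant) / 2.0
    implant = v.voxels >= imp_thr

    if cfg.halo_width_voxels > 0:
        # Euclidean band: an isotropic halo of the stated thickness in every
        # direction (a chessboard band would be sqrt(2)x thicker along
        # diagonals and bleed past an equally wide in-plane exclusion band
        # in oblique slices)
        dist = ndimage.distance_transform_edt(~implant)
        shell = (dist > 0) & (dist <= cfg.halo_width_voxels)
        out[shell] = np.maximum(out[shell], cfg.halo_intensity)

    if cfg.granule_count > 0:
        nz, ny, nx = cfg.volume_shape
        cy, cx = cfg.axis_center
        yy, xx = np.mgrid[0:ny, 0:nx]
        rr2d = np.hypot(yy - cy, xx - cx)
        z_ok = np.zeros(nz, dtype=bool)
        z_ok[cfg.z_top : cfg.z_top + cfg.length_vox] = True
        region = z_ok[:, None, None] & (rr2d[None] <= cfg.bone_outer_radius_vox) & ~implant
        candidates = np.flatnonzero(region)
        centers = np.unravel_index(
            rng.choice(candidates, size=cfg.granule_count, replace=True), cfg.volume_shape
        )
        r_vox = max(1.0, cfg.granule_radius_um / cfg.voxel_size_um)
        rad = int(np.ceil(r_vox))
        off = np.mgrid[-rad : rad + 1, -rad : rad + 1, -rad : rad + 1]
        ball = (off**2).sum(axis=0) <= r_vox**2
        dz, dy, dx = (o[ball] for o in off)
        g_int = cfg.intensity_bone if cfg.granule_intensity is None else cfg.granule_intensity
        for z0, y0, x0 in zip(*centers):
            zi, yi, xi = z0 + dz, y0 + dy, x0 + dx
            keep = (zi >= 0) & (zi < nz) & (yi >= 0) & (yi < ny) & (xi >= 0) & (xi < nx)
            zi, yi, xi = zi[keep], yi[keep], xi[keep]
            keep2 = ~implant[zi, yi, xi]
            zi, yi, xi = zi[keep2], yi[keep2], xi[keep2]
            out[zi, yi, xi] = np.maximum(out[zi, yi, xi], g_int)

    if cfg.noise_sd > 0:
        out += cfg.noise_sd * rng.standard_normal(out.shape, dtype=np.float32)

    np.clip(out, 0.0, 255.0, out=out)
    return Volume(voxels=out, voxel_size_um=v.voxel_size_um)
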