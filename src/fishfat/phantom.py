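"""Digital fish-in-agarose phantoms with known fat content.

The phantom emulates what the scanner sees when an adult zebrafish is
embedded in a salted low-melting-agarose cylinder and imaged with a
chemically selective (CHESS) fat/water pair: a water-only agarose
compartment, a lean fish body with a small intrinsic fat signal, and one
or more adipose depots (subcutaneous shell, visceral ellipsoid, ...) of
high fat fraction.  Because every voxel's true fat fraction is known, the
phantom carries an exact :class:`GroundTruth` against which the
quantification chain can be scored, and a noisy EchoMRI-like whole-body
reference readout can be simulated for method-comparison designs.

Noise model
-----------
Magnitude MR pixels follow a Rician law: the noise-free channel signal
``RG * S`` (receiver gain times object signal) is perturbed by two
independent zero-mean Gaussian draws of standard deviation ``sigma`` --
one in-phase, one in quadrature -- and the magnitude is taken:

    M = sqrt((RG*S + n1)^2 + n2^2)

At zero signal this reduces to a Rayleigh background with mean
``sigma*sqrt(pi/2)`` and second moment ``2*sigma^2``, which is what the
noise-correction stage of the quantification chain exploits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import AcquisitionGeometry, ChannelStack

__all__ = [
    "Ellipsoid",
    "ShellSector",
    "Depot",
    "PhantomSpec",
    "GroundTruth",
    "default_spec",
    "build_truth_volumes",
    "simulate_chess_pair",
    "simulate_reference_fat_mass",
    "sigma_for_peak_snr",
    "design_cohort",
    "make_cohort",
    "load_spec",
    "save_spec",
]

DEPOT_LABELS = ("subcutaneous", "visceral", "hepatic", "intramuscular")


# ---------------------------------------------------------------------------
# geometric primitives

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, center and semi-axes in mm (x, y, z)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes_mm}")

    def mask(self, coords) -> np.ndarray:
        z, y, x = coords
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    def scaled(self, s: float) -> "Ellipsoid":
        """Linearly scale the semi-axes by ``s`` (volume scales as s^3)."""
        return Ellipsoid(self.center_mm, tuple(a * s for a in self.semi_axes_mm))

    def bounds_mm(self):
        c, a = self.center_mm, self.semi_axes_mm
        return tuple(ci - ai for ci, ai in zip(c, a)), tuple(
            ci + ai for ci, ai in zip(c, a)
        )


@dataclass(frozen=True)
class ShellSector:
    """Shell between two concentric ellipsoids, optionally restricted to an
    in-plane angular sector.

    ``inner_scale`` in (0, 1) gives the inner surface as a scaled copy of
    the outer ellipsoid; ``phi_deg`` (optional) keeps only voxels whose
    polar angle in the axial (x, y) plane, measured from +x towards +y,
    lies inside ``[phi_min, phi_max]`` degrees.  This models a
    subcutaneous fat layer hugging the body surface.
    """

    outer: Ellipsoid
    inner_scale: float
    phi_deg: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.inner_scale < 1.0:
            raise ValueError(f"inner_scale must be in (0, 1), got {self.inner_scale}")

    def mask(self, coords) -> np.ndarray:
        m = self.outer.mask(coords) & ~self.outer.scaled(self.inner_scale).mask(coords)
        if self.phi_deg is not None:
            z, y, x = coords
            cx, cy, _ = self.outer.center_mm
            phi = np.degrees(np.arctan2(y - cy, x - cx))
            lo, hi = self.phi_deg
            m = m & (phi >= lo) & (phi <= hi)
        return m

    def scaled(self, s: float) -> "ShellSector":
        """Scale the shell *thickness* by ``s``, keeping the outer surface
        fixed (the depot stays attached to the body)."""
        new_inner = max(1.0 - (1.0 - self.inner_scale) * s, 1e-6)
        if new_inner >= 1.0:
            new_inner = 1.0 - 1e-6
        return ShellSector(self.outer, new_inner, self.phi_deg)

    def bounds_mm(self):
        return self.outer.bounds_mm()


@dataclass(frozen=True)
class Depot:
    """One adipose depot: a labelled geometric primitive with a true fat
    signal fraction."""

    label: str
    shape: Ellipsoid | ShellSector
    fat_fraction: float

    def __post_init__(self) -> None:
        if self.label not in DEPOT_LABELS:
            raise ValueError(f"depot label must be one of {DEPOT_LABELS}, got {self.label!r}")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError(f"fat fraction must be in [0, 1], got {self.fat_fraction}")

    def scaled(self, s: float) -> "Depot":
        return replace(self, shape=self.shape.scaled(s))


# ---------------------------------------------------------------------------
# phantom specification

@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a synthetic fish-in-agarose acquisition.

    Signal levels are in arbitrary pre-gain scanner units with the lean
    fish tissue's total (fat + water) proton signal normalised to
    ``tissue_signal``.  Agarose (a nearly pure-water gel) emits water
    signal only, at ``agarose_signal``.  ``sigma`` is the per-channel
    Gaussian noise standard deviation on the *post-gain* intensity scale.
    """

    geometry: AcquisitionGeometry
    body: Ellipsoid
    tube_radius_mm: float
    depots: tuple[Depot, ...]
    lean_fat_fraction: float = 0.05
    tissue_signal: float = 1.0
    agarose_signal: float = 1.3
    # autogain-consistent defaults: gain x peak channel signal is matched
    # across channels (fat peak 0.90 x 180 = 162, water peak 1.3 x 125 = 162.5)
    receiver_gain: dict = field(default_factory=lambda: {"fat": 180.0, "water": 125.0})
    sigma: float = 0.0
    fat_density_mg_mm3: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lean_fat_fraction <= 1.0:
            raise ValueError("lean fat fraction must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube radius must be positive")
        for ch in ("fat", "water"):
            if ch not in self.receiver_gain or not self.receiver_gain[ch] > 0:
                raise ValueError(f"receiver gain for {ch!r} must be positive")
        if self.tissue_signal <= 0 or self.agarose_signal < 0:
            raise ValueError("signal levels must be positive (agarose may be 0)")
        if self.fat_density_mg_mm3 <= 0:
            raise ValueError("fat density must be positive")
        object.__setattr__(self, "depots", tuple(self.depots))
        self._check_depots_in_grid()

    def _check_depots_in_grid(self) -> None:
        geom = self.geometry
        half = (geom.fov_mm[0] / 2, geom.fov_mm[1] / 2, geom.slab_depth_mm / 2)
        for depot in self.depots:
            lo, hi = depot.shape.bounds_mm()
            # bounds are (x, y, z); grid half-extents ordered the same way
            if any(l < -h or u > h for l, u, h in zip(lo, hi, half)):
                raise ValueError(
                    f"depot {depot.label!r} extends outside the imaging grid "
                    f"(bounds {lo} .. {hi}, half-extents {half})"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-voxel and aggregate fat content of a phantom."""

    fat_fraction: np.ndarray          # per-voxel true fat signal fraction
    voxel_volume_mm3: float
    fat_volume_mm3: float
    fat_mass_mg: float
    fat_density_mg_mm3: float
    depot_masses_mg: dict             # per-depot + "lean" contributions

    def __post_init__(self) -> None:
        total = sum(self.depot_masses_mg.values())
        if not math.isclose(total, self.fat_mass_mg, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"depot masses sum to {total}, expected total {self.fat_mass_mg}"
            )


def default_spec(
    sigma: float = 0.0,
    seed: int = 0,
    geometry: AcquisitionGeometry | None = None,
) -> PhantomSpec:
    """The standard phantom: an obese adult zebrafish in an 8 mm agarose tube.

    Default acquisition follows the printed small-animal protocol
    (16 x 16 mm in-plane field of view, 128 x 128 matrix, 50 axial slices
    of 0.5 mm; the slice stack therefore spans 25 mm).  The fish body is a
    2.8 x 3.2 x 11 mm semi-axis ellipsoid carrying a subcutaneous fat
    shell and a visceral fat ellipsoid, both at fat fraction 0.90, over a
    lean background of fat fraction 0.05.
    """
    if geometry is None:
        geometry = AcquisitionGeometry(
            fov_mm=(16.0, 16.0), matrix=(128, 128), n_slices=50,
            slice_thickness_mm=0.5,
        )
    body = Ellipsoid(center_mm=(0.0, 0.0, 0.0), semi_axes_mm=(2.8, 3.2, 11.0))
    depots = (
        Depot("subcutaneous", ShellSector(outer=body, inner_scale=0.85), 0.90),
        Depot(
            "visceral",
            Ellipsoid(center_mm=(0.0, 0.8, -2.0), semi_axes_mm=(1.6, 1.8, 5.0)),
            0.90,
        ),
    )
    return PhantomSpec(
        geometry=geometry,
        body=body,
        tube_radius_mm=3.5,
        depots=depots,
        sigma=sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truth construction

def _compartment_masks(spec: PhantomSpec, coords=None):
    """Boolean masks (tube, body) on the voxel grid."""
    if coords is None:
        coords = spec.geometry.voxel_centers_mm()
    z, y, x = coords
    tube = (x**2 + y**2) <= spec.tube_radius_mm**2
    body = spec.body.mask(coords) & tube
    return tube, body


def build_truth_volumes(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Noise-free fat and water signal volumes plus exact ground truth.

    Voxels inside a depot carry fat signal proportional to the depot fat
    fraction and water signal proportional to its complement; remaining
    body voxels use the lean fat fraction; agarose voxels are water-only;
    voxels outside the tube are signal-free.  Depots listed later override
    earlier ones where they overlap, and each depot is clipped to the
    fish body.
    """
    coords = spec.geometry.voxel_centers_mm()
    tube, body = _compartment_masks(spec, coords)

    frac = np.zeros(spec.geometry.shape, dtype=float)
    frac[body] = spec.lean_fat_fraction
    owner = np.full(spec.geometry.shape, -1, dtype=np.int8)  # -1 = lean / none
    for i, depot in enumerate(spec.depots):
        # depots are clipped to the body; a depot scaled below voxel size
        # simply contributes nothing
        dmask = depot.shape.mask(coords) & body
        frac[dmask] = depot.fat_fraction
        owner[dmask] = i

    fat = np.zeros(spec.geometry.shape, dtype=float)
    water = np.zeros(spec.geometry.shape, dtype=float)
    fat[body] = spec.tissue_signal * frac[body]
    water[body] = spec.tissue_signal * (1.0 - frac[body])
    agarose = tube & ~body
    water[agarose] = spec.agarose_signal

    vox = spec.geometry.voxel_volume_mm3()
    density = spec.fat_density_mg_mm3
    truth_frac = np.where(body, frac, 0.0)
    total_volume = float(truth_frac.sum() * vox)
    depot_masses: dict[str, float] = {}
    for i, depot in enumerate(spec.depots):
        m = float(frac[owner == i].sum() * vox * density)
        depot_masses[depot.label] = depot_masses.get(depot.label, 0.0) + m
    depot_masses["lean"] = float(frac[body & (owner == -1)].sum() * vox * density)

    truth = GroundTruth(
        fat_fraction=truth_frac,
        voxel_volume_mm3=vox,
        fat_volume_mm3=total_volume,
        fat_mass_mg=total_volume * density,
        fat_density_mg_mm3=density,
        depot_masses_mg=depot_masses,
    )
    return fat, water, truth


# ---------------------------------------------------------------------------
# simulation

def simulate_chess_pair(
    fat_volume: np.ndarray,
    water_volume: np.ndarray,
    spec: PhantomSpec,
    seed: int | None = None,
) -> tuple[ChannelStack, ChannelStack]:
    """Rician-noisy magnitude stacks for the fat and water excitations.

    Each channel's voxel value is ``sqrt((RG*S + n1)^2 + n2^2)`` with
    ``n1, n2`` independent N(0, sigma^2) draws; ``sigma = 0`` returns the
    gain-scaled signal exactly.  The same spec and seed always produce
    bit-identical stacks (fat channel drawn first).
    """
    shape = spec.geometry.shape
    if fat_volume.shape != shape or water_volume.shape != shape:
        raise ValueError("signal volumes do not match the spec geometry")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    stacks = []
    for channel, signal in (("fat", fat_volume), ("water", water_volume)):
        gain = spec.receiver_gain[channel]
        amplified = gain * signal
        if spec.sigma > 0:
            n1 = rng.standard_normal(shape)
            n2 = rng.standard_normal(shape)
            data = np.hypot(amplified + spec.sigma * n1, spec.sigma * n2)
        else:
            data = amplified.copy()
        stacks.append(
            ChannelStack(
                channel=channel,
                data=data,
                receiver_gain=gain,
                geometry=spec.geometry,
                seed=seed,
                sigma_truth=spec.sigma,
            )
        )
    return stacks[0], stacks[1]


def simulate_reference_fat_mass(
    true_mass_mg: float, cv: float, seed: int | None = None
) -> float:
    """Noisy whole-body fat-mass readout emulating a quantitative-NMR
    body-composition analyser: ``mass * (1 + e)`` with ``e ~ N(0, cv^2)``."""
    if true_mass_mg < 0:
        raise ValueError(f"fat mass must be non-negative, got {true_mass_mg}")
    if cv < 0:
        raise ValueError(f"coefficient of variation must be non-negative, got {cv}")
    if cv == 0:
        return float(true_mass_mg)
    rng = np.random.default_rng(seed)
    return float(true_mass_mg * (1.0 + cv * rng.standard_normal()))


def sigma_for_peak_snr(
    spec: PhantomSpec, peak_snr: float, fat_volume=None, water_volume=None
) -> float:
    """Noise sigma giving the requested peak signal-to-noise ratio, where
    the peak is the largest post-gain noise-free intensity in either channel."""
    if peak_snr <= 0:
        raise ValueError("peak SNR must be positive")
    if fat_volume is None or water_volume is None:
        fat_volume, water_volume, _ = build_truth_volumes(spec)
    peak = max(
        spec.receiver_gain["fat"] * float(fat_volume.max()),
        spec.receiver_gain["water"] * float(water_volume.max()),
    )
    return peak / peak_snr


# ---------------------------------------------------------------------------
# cohorts

#: Default cohort fat-mass span (mg): a 5.5-fold range covering lean-ish to
#: severely obese adult zebrafish.
DEFAULT_COHORT_MASS_RANGE = (40.0, 220.0)


def _scaled_spec(spec: PhantomSpec, s: float) -> PhantomSpec:
    return replace(spec, depots=tuple(d.scaled(s) for d in spec.depots))


def _mass_for_scale(spec: PhantomSpec, s: float, coords, body) -> float:
    """True fat mass of ``spec`` with depots scaled by ``s``; mask-level
    recomputation only (no signal volumes), for use inside the bisection."""
    vox = spec.geometry.voxel_volume_mm3()
    taken = np.zeros(spec.geometry.shape, dtype=bool)
    fat_voxels = 0.0
    for depot in reversed(tuple(d.scaled(s) for d in spec.depots)):
        m = depot.shape.mask(coords) & body & ~taken
        fat_voxels += depot.fat_fraction * m.sum()
        taken |= m
    fat_voxels += spec.lean_fat_fraction * (body.sum() - taken.sum())
    return float(fat_voxels * vox * spec.fat_density_mg_mm3)


def design_cohort(
    n: int,
    mass_range_mg: tuple[float, float],
    base_spec: PhantomSpec | None = None,
) -> list[tuple[PhantomSpec, np.ndarray, np.ndarray, GroundTruth]]:
    """Deterministic cohort design: ``n`` phantoms whose true fat masses
    increase linearly across ``mass_range_mg``.

    Depot linear dimensions are scaled by a common per-animal factor found
    by bisection on the voxelised true mass; the achieved masses match the
    targets up to voxelisation (a fraction of a percent at the default
    grid).  Raises if the range is degenerate or unreachable.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 animals")
    lo, hi = mass_range_mg
    if not hi > lo or lo < 0:
        raise ValueError(f"degenerate fat-mass range {mass_range_mg}")
    if base_spec is None:
        base_spec = default_spec()

    coords = base_spec.geometry.voxel_centers_mm()
    _, body = _compartment_masks(base_spec, coords)

    # bracket the scale range
    s_lo, s_hi = 1e-3, 1.0
    m_hi = _mass_for_scale(base_spec, s_hi, coords, body)
    while m_hi < hi:
        s_hi *= 1.25
        try:
            _scaled_spec(base_spec, s_hi)  # validates depots still in grid
        except ValueError as err:
            raise ValueError(
                f"fat-mass range {mass_range_mg} mg is unreachable by depot "
                f"scaling (max achievable ~{m_hi:.1f} mg)"
            ) from err
        m_hi = _mass_for_scale(base_spec, s_hi, coords, body)
        if s_hi > 1e3:
            raise ValueError(f"fat-mass range {mass_range_mg} mg is unreachable")
    m_lo = _mass_for_scale(base_spec, s_lo, coords, body)
    if m_lo > lo:
        raise ValueError(
            f"minimum target {lo} mg is below the lean-only mass {m_lo:.2f} mg"
        )

    targets = np.linspace(lo, hi, n)
    out = []
    for target in targets:
        a, b = s_lo, s_hi
        for _ in range(30):
            mid = 0.5 * (a + b)
            if _mass_for_scale(base_spec, mid, coords, body) < target:
                a = mid
            else:
                b = mid
        scaled = _scaled_spec(base_spec, b)
        fat, water, truth = build_truth_volumes(scaled)
        out.append((scaled, fat, water, truth))
    masses = [t.fat_mass_mg for *_, t in out]
    if not all(b > a for a, b in zip(masses, masses[1:])):
        raise ValueError(f"cohort masses are not strictly increasing: {masses}")
    return out


def make_cohort(
    n: int,
    mass_range_mg: tuple[float, float],
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    reference_cv: float = 0.02,
):
    """Simulate a full synthetic validation cohort.

    Returns a list of ``(fat_stack, water_stack, truth, reference_mg)``
    tuples: the noisy CHESS pair, the exact ground truth and a noisy
    reference fat-mass readout for each animal.  Reproducible under
    ``seed``; the geometric design itself is seed-independent.
    """
    design = design_cohort(n, mass_range_mg, base_spec)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(design))
    cohort = []
    for (spec, fat, water, truth), child in zip(design, children):
        sim_seed, ref_seed = child.generate_state(2).tolist()
        fat_stack, water_stack = simulate_chess_pair(fat, water, spec, seed=sim_seed)
        ref = simulate_reference_fat_mass(truth.fat_mass_mg, reference_cv, seed=ref_seed)
        cohort.append((fat_stack, water_stack, truth, ref))
    return cohort


# ---------------------------------------------------------------------------
# spec (de)serialisation

def _shape_to_dict(shape) -> dict:
    if isinstance(shape, Ellipsoid):
        return {
            "type": "ellipsoid",
            "center_mm": list(shape.center_mm),
            "semi_axes_mm": list(shape.semi_axes_mm),
        }
    return {
        "type": "shell_sector",
        "outer": _shape_to_dict(shape.outer),
        "inner_scale": shape.inner_scale,
        "phi_deg": list(shape.phi_deg) if shape.phi_deg else None,
    }


def _shape_from_dict(d: dict):
    if d["type"] == "ellipsoid":
        return Ellipsoid(tuple(d["center_mm"]), tuple(d["semi_axes_mm"]))
    if d["type"] == "shell_sector":
        return ShellSector(
            _shape_from_dict(d["outer"]),
            d["inner_scale"],
            tuple(d["phi_deg"]) if d.get("phi_deg") else None,
        )
    raise ValueError(f"unknown depot primitive {d['type']!r}")


def save_spec(spec: PhantomSpec, path: str | Path) -> Path:
    """Write a phantom spec as JSON."""
    d = {
        "geometry": {
            "fov_mm": list(spec.geometry.fov_mm),
            "matrix": list(spec.geometry.matrix),
            "n_slices": spec.geometry.n_slices,
            "slice_thickness_mm": spec.geometry.slice_thickness_mm,
        },
        "body": _shape_to_dict(spec.body),
        "tube_radius_mm": spec.tube_radius_mm,
        "depots": [
            {
                "label": d_.label,
                "shape": _shape_to_dict(d_.shape),
                "fat_fraction": d_.fat_fraction,
            }
            for d_ in spec.depots
        ],
        "lean_fat_fraction": spec.lean_fat_fraction,
        "tissue_signal": spec.tissue_signal,
        "agarose_signal": spec.agarose_signal,
        "receiver_gain": dict(spec.receiver_gain),
        "sigma": spec.sigma,
        "fat_density_mg_mm3": spec.fat_density_mg_mm3,
        "seed": spec.seed,
    }
    path = Path(path)
    path.write_text(json.dumps(d, indent=1))
    return path


def load_spec(path: str | Path) -> PhantomSpec:
    """Read a phantom spec written by :func:`save_spec`."""
    d = json.loads(Path(path).read_text())
    return PhantomSpec(
        geometry=AcquisitionGeometry(
            fov_mm=tuple(d["geometry"]["fov_mm"]),
            matrix=tuple(d["geometry"]["matrix"]),
            n_slices=d["geometry"]["n_slices"],
            slice_thickness_mm=d["geometry"]["slice_thickness_mm"],
        ),
        body=_shape_from_dict(d["body"]),
        tube_radius_mm=d["tube_radius_mm"],
        depots=tuple(
            Depot(e["label"], _shape_from_dict(e["shape"]), e["fat_fraction"])
            for e in d["depots"]
        ),
        lean_fat_fraction=d["lean_fat_fraction"],
        tissue_signal=d.get("tissue_signal", 1.0),
        agarose_signal=d.get("agarose_signal", 1.3),
        receiver_gain=d["receiver_gain"],
        sigma=d["sigma"],
        fat_density_mg_mm3=d.get("fat_density_mg_mm3", 0.9),
        seed=d["seed"],
    )
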