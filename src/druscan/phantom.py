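"""Synthetic fundus phantoms with exact ground truth.

Clinical fundus photographs of drusen patients are not redistributable, so
every stage of the pipeline is exercised on generated phantoms that mimic
the structures the algorithm relies on:

* a bright, round optic disc (intensity above the 200 detection cutoff),
* dark vessels radiating outward from the disc as jittered random-walk
  polylines with a fixed stamp width,
* small bright circular drusen (diameters below the large median window)
  scattered around the geometric fovea estimate in the half of the image
  opposite the disc, rendered with a soft 1-pixel intensity taper to mimic
  their ambiguous boundaries,
* a smooth linear illumination gradient, and
* salt-type (bright) impulse noise.

The generator returns the image together with exact disc / vessel / drusen
masks and the planted macula center, so detection accuracy can be scored
without any manual annotation. Everything is a deterministic function of
the spec's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom", "phantom_suite", "DIFFICULTY_PRESETS"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic fundus image.

    Defaults give a half-scale (768x512) image: a 40-px-radius disc at
    intensity 230 on a 120 background, six vessels of stamp width 3 at
    intensity 40 (+/- 5 jitter), ten drusen of 4-14 px diameter at +40
    contrast, a 20-level illumination ramp and 0.1% salt noise.
    """

    width: int = 768
    height: int = 512
    disc_center: tuple[int, int] | None = None  # (row, col); None -> seeded placement
    disc_radius: int = 40
    disc_intensity: int = 230
    background_intensity: int = 120
    gradient_amplitude: int = 20
    n_vessels: int = 6
    vessel_intensity: int = 40
    vessel_width: int = 3
    n_drusen: int = 10
    drusen_diameter_range: tuple[float, float] = (4.0, 14.0)
    drusen_contrast: int = 40
    salt_noise_density: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if not self.disc_intensity > 200:
            raise ValueError("disc_intensity must exceed the 200 detection cutoff")
        if not 0.0 <= self.salt_noise_density <= 1.0:
            raise ValueError("salt_noise_density must be in [0, 1]")
        lo, hi = self.drusen_diameter_range
        if not 0 < lo <= hi:
            raise ValueError("invalid drusen_diameter_range")


@dataclass(frozen=True)
class PhantomBundle:
    """A phantom image and its planted ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    disc_mask: np.ndarray  # bool
    vessel_mask: np.ndarray  # bool
    drusen_mask: np.ndarray  # bool
    macula_center: tuple[int, int]  # (row, col), geometric fovea estimate
    disc_center: tuple[float, float]  # planted disc center (row, col)
    spec: PhantomSpec = field(repr=False)

    @property
    def green(self) -> np.ndarray:
        return self.image[:, :, 1]


def _soft_disk(canvas: np.ndarray, center: tuple[float, float], radius: float,
               taper: float = 1.0) -> np.ndarray:
    """Weight map of an anti-aliased disk: 1 inside, linear taper to 0.

    The taper runs from ``radius - taper`` to ``radius + taper``; pixels at
    distance <= radius carry weight >= 0.5 and define the hard mask.
    """
    h, w = canvas.shape
    r0, c0 = center
    rr, cc = np.ogrid[:h, :w]
    d = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    return np.clip((radius + taper - d) / (2.0 * taper), 0.0, 1.0)


def render_drusen_profile(canvas: np.ndarray, center: tuple[float, float],
                          diameter: float, contrast: float) -> np.ndarray:
    """Add one soft-edged druse to ``canvas`` (float); return its hard mask."""
    w = _soft_disk(canvas, center, diameter / 2.0, taper=1.0)
    canvas += contrast * w
    return w >= 0.5


def _walk_vessel(rng: np.random.Generator, start: np.ndarray, angle: float,
                 h: int, w: int, max_steps: int = 1500) -> np.ndarray:
    """Jittered random-walk centerline from ``start`` heading ``angle``."""
    pts = []
    pos = start.astype(float)
    step = 2.0
    for _ in range(max_steps):
        pos = pos + step * np.array([np.sin(angle), np.cos(angle)])
        if not (0 <= pos[0] < h and 0 <= pos[1] < w):
            break
        pts.append(pos.copy())
        angle += rng.normal(0.0, 0.12)
    return np.array(pts) if pts else np.empty((0, 2))


def _stamp_polyline(shape: tuple[int, int], pts: np.ndarray, width: float) -> np.ndarray:
    """Boolean mask of all pixels within ``width/2`` of any centerline point."""
    mask = np.zeros(shape, dtype=bool)
    r_br = width / 2.0
    br = int(np.ceil(r_br))
    oy, ox = np.ogrid[-br : br + 1, -br : br + 1]
    brush = oy**2 + ox**2 <= r_br**2
    h, w = shape
    for p in pts:
        r, c = int(round(p[0])), int(round(p[1]))
        r0, r1 = max(r - br, 0), min(r + br + 1, h)
        c0, c1 = max(c - br, 0), min(c + br + 1, w)
        mask[r0:r1, c0:c1] |= brush[r0 - (r - br) : r1 - (r - br), c0 - (c - br) : c1 - (c - br)]
    return mask


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Render a phantom fundus image from ``spec`` (deterministic in seed).

    Raises
    ------
    PlacementError
        If the requested drusen cannot be placed without overlap.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # --- background + smooth illumination gradient ---------------------
    theta = rng.uniform(0, 2 * np.pi)
    rr, cc = np.mgrid[:h, :w]
    ramp = (cc / max(w - 1, 1) - 0.5) * np.cos(theta) + (rr / max(h - 1, 1) - 0.5) * np.sin(theta)
    canvas = spec.background_intensity + spec.gradient_amplitude * ramp

    # --- optic disc -----------------------------------------------------
    if spec.disc_center is None:
        side_left = bool(rng.integers(0, 2))
        drow = h / 2 + rng.uniform(-h / 8, h / 8)
        dcol = w * rng.uniform(0.12, 0.18)
        if not side_left:
            dcol = w - 1 - dcol
        disc_center = (drow, dcol)
    else:
        disc_center = (float(spec.disc_center[0]), float(spec.disc_center[1]))
    disc_w = _soft_disk(canvas, disc_center, spec.disc_radius, taper=1.5)
    canvas = canvas * (1 - disc_w) + spec.disc_intensity * disc_w
    disc_mask = disc_w >= 0.5

    # --- vessels radiating from the disc --------------------------------
    vessel_mask = np.zeros((h, w), dtype=bool)
    base_angles = rng.permutation(spec.n_vessels) * (2 * np.pi / max(spec.n_vessels, 1))
    for k in range(spec.n_vessels):
        angle = base_angles[k] + rng.uniform(-0.3, 0.3)
        start = np.array(
            [
                disc_center[0] + 0.9 * spec.disc_radius * np.sin(angle),
                disc_center[1] + 0.9 * spec.disc_radius * np.cos(angle),
            ]
        )
        pts = _walk_vessel(rng, start, angle, h, w)
        if len(pts):
            vessel_mask |= _stamp_polyline((h, w), pts, spec.vessel_width)
    vessel_mask &= ~disc_mask  # vessels are ground truth only outside the disc
    jitter = rng.integers(-5, 6, size=int(vessel_mask.sum()))
    canvas[vessel_mask] = spec.vessel_intensity + jitter

    # --- drusen around the geometric fovea estimate ----------------------
    edge = w - 1 if disc_center[1] < w / 2 else 0
    macula = (int(round(disc_center[0])), int(round((disc_center[1] + edge) / 2)))
    lo_d, hi_d = spec.drusen_diameter_range
    # keep every druse strictly inside the macular half opposite the disc
    placement_radius = min(
        0.35 * abs(macula[1] - disc_center[1]),
        abs(macula[1] - w / 2) - hi_d / 2 - 2,
    )
    drusen_mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    attempts = 0
    while len(placed) < spec.n_drusen:
        attempts += 1
        if attempts > 200 * max(spec.n_drusen, 1):
            raise PlacementError(
                f"could not place {spec.n_drusen} drusen after {attempts} attempts"
            )
        diam = rng.uniform(lo_d, hi_d)
        rad = np.sqrt(rng.uniform(0, 1)) * placement_radius
        ang = rng.uniform(0, 2 * np.pi)
        r = macula[0] + rad * np.sin(ang)
        c = macula[1] + rad * np.cos(ang)
        r_half = diam / 2.0
        margin = r_half + 3
        if not (margin <= r < h - margin and margin <= c < w - margin):
            continue
        if any(np.hypot(r - pr, c - pc) < r_half + prad + 4 for pr, pc, prad in placed):
            continue
        # keep clear of vessels and the disc so ground-truth masks stay disjoint
        ir, ic = int(round(r)), int(round(c))
        pad = int(np.ceil(r_half)) + 3
        r0, r1 = max(ir - pad, 0), min(ir + pad + 1, h)
        c0, c1 = max(ic - pad, 0), min(ic + pad + 1, w)
        if vessel_mask[r0:r1, c0:c1].any() or disc_mask[r0:r1, c0:c1].any():
            continue
        drusen_mask |= render_drusen_profile(canvas, (r, c), diam, spec.drusen_contrast)
        placed.append((r, c, r_half))

    # --- salt impulse noise ----------------------------------------------
    n_salt = rng.binomial(h * w, spec.salt_noise_density)
    if n_salt:
        idx = rng.choice(h * w, size=n_salt, replace=False)
        canvas.ravel()[idx] = 255.0

    green = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    red = np.clip(0.75 * green.astype(np.float64) + 40, 0, 255).astype(np.uint8)
    blue = np.clip(0.45 * green.astype(np.float64), 0, 255).astype(np.uint8)
    image = np.stack([red, green, blue], axis=-1)

    return PhantomBundle(
        image=image,
        disc_mask=disc_mask,
        vessel_mask=vessel_mask,
        drusen_mask=drusen_mask,
        macula_center=macula,
        disc_center=disc_center,
        spec=spec,
    )


#: Difficulty presets: (drusen_contrast, gradient_amplitude, salt_noise_density).
DIFFICULTY_PRESETS: dict[str, dict] = {
    "easy": dict(drusen_contrast=60, gradient_amplitude=0, salt_noise_density=0.001),
    "medium": dict(drusen_contrast=40, gradient_amplitude=20, salt_noise_density=0.001),
    "hard": dict(drusen_contrast=20, gradient_amplitude=40, salt_noise_density=0.003),
}


def phantom_suite(seeds, difficulty: str = "medium", **overrides) -> list[PhantomBundle]:
    """Generate one phantom per seed at a named difficulty level.

    ``easy`` uses +60 drusen contrast with no illumination gradient,
    ``medium`` +40 with a moderate gradient, ``hard`` +20 with a strong
    gradient and denser salt noise. Extra keyword arguments override
    individual :class:`PhantomSpec` fields.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("phantom_suite requires at least one seed")
    if difficulty not in DIFFICULTY_PRESETS:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    params = {**DIFFICULTY_PRESETS[difficulty], **overrides}
    return [generate_phantom(PhantomSpec(seed=int(s), **params)) for s in seeds]
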