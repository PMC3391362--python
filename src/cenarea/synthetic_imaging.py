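"""Synthetic 3D immunofluorescence cells with known centromere ground truth.

Renders multi-channel 3D stacks that emulate interphase root-tip cells
stained for CENH3: compact bright foci (kinetochores/centromeres) over a
diffuse non-centromeric background, a DAPI-style nuclear ellipsoid, and an
optional FISH channel that marks a subset of foci (the "alien" centromeres
of an addition line).  Every stack carries its exact ground truth — the
focus specifications and the projected truth mask — so the measurement
pipeline can be validated pixel-for-pixel without real microscopy data.

The optical model is deliberately minimal: foci are hard spheres, optics are
a single Gaussian blur applied to the focus layer, and the background is a
smooth random field rescaled so its maximum is *exactly* the requested
value.  That last construction makes the threshold rule ("one grey level
above the brightest non-centromeric staining") exactly testable: on a
noiseless render the correct threshold is ``background_max + 1`` by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "FocusSpec",
    "GroundTruth",
    "ImageStack",
    "render_cell",
    "render_addition_line_cell",
    "write_stack",
    "read_stack",
]

CENH3 = "CENH3"
DAPI = "DAPI"
FISH = "FISH"

DEFAULT_BIT_DEPTH = 12  # typical scientific CCD

# Placement is rejection-sampled; give up after this many tries per focus.
_MAX_PLACEMENT_TRIES = 500


@dataclass(frozen=True)
class FocusSpec:
    """One rendered centromere focus: a hard sphere of constant intensity.

    ``label`` distinguishes host from alien centromeres in addition-line
    cells; plain cells leave it None.
    """

    center: tuple[int, int, int]  # (z, y, x), 0-based voxels
    radius: float
    peak_intensity: int
    channel: str = CENH3
    label: str | None = None


@dataclass
class GroundTruth:
    """Exact truth for a rendered stack: the foci and the projected mask.

    ``projected_mask`` marks the pixels whose noiseless (pre-noise,
    post-blur) maximum-intensity projection exceeds the background maximum —
    i.e. exactly the area an ideal application of the threshold rule would
    measure.
    """

    foci: list[FocusSpec] = field(default_factory=list)
    projected_mask: np.ndarray | None = None
    background_max: int = 0

    @property
    def projected_area(self) -> int:
        if self.projected_mask is None:
            return 0
        return int(self.projected_mask.sum())

    def background_mask(self) -> np.ndarray:
        """The non-centromeric region of the projection (truth complement)."""
        if self.projected_mask is None:
            raise ValueError("ground truth has no projected mask")
        return ~self.projected_mask


@dataclass
class ImageStack:
    """Named 3D integer channels of equal shape plus optional ground truth."""

    channels: dict[str, np.ndarray]
    bit_depth: int = DEFAULT_BIT_DEPTH
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        hi = 2**self.bit_depth - 1
        for name, ch in self.channels.items():
            if ch.min() < 0 or ch.max() > hi:
                raise ValueError(
                    f"channel {name!r} intensities outside [0, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _smooth_background(
    shape: tuple[int, int, int],
    background_max: int,
    rng: np.random.Generator,
    smooth_sigma: float = 6.0,
) -> np.ndarray:
    """Low-frequency random field rescaled so its maximum is exactly
    ``background_max`` grey levels."""
    if background_max <= 0:
        return np.zeros(shape, dtype=np.int64)
    f = gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    f -= f.min()
    f /= f.max()
    return np.round(f * background_max).astype(np.int64)


def _nucleus_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Filled ellipsoid with semi-axes 0.4 x each dimension, centred."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = [(s - 1) / 2 for s in shape]
    az, ay, ax = [0.4 * s for s in shape]
    return (
        ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    ) <= 1.0


def _place_foci(
    shape: tuple[int, int, int],
    n_foci: int,
    radius_range: tuple[float, float],
    intensity_range: tuple[int, int],
    rng: np.random.Generator,
    channel: str = CENH3,
    label: str | None = None,
    existing: list[FocusSpec] | None = None,
    min_gap: float = 2.0,
) -> list[FocusSpec]:
    """Sample non-overlapping foci inside the nuclear ellipsoid.

    Disjointness is enforced *laterally* (in the y-x plane) so that the
    projected footprints of distinct foci do not merge; this also implies
    the spheres are disjoint in 3D.  ``min_gap`` is the clearance between
    sphere surfaces — callers widen it when blur will spread the footprints.
    """
    placed: list[FocusSpec] = list(existing) if existing else []
    new: list[FocusSpec] = []
    cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
    ay, ax = 0.4 * shape[1], 0.4 * shape[2]
    for _ in range(n_foci):
        r = float(rng.uniform(*radius_range))
        peak = int(rng.integers(intensity_range[0], intensity_range[1] + 1))
        # z anywhere the sphere fits, or the mid-plane when the stack is
        # too shallow (the sphere is then z-truncated; its projection is
        # still a full disk)
        if shape[0] - 1 - r >= r:
            z_range = (r, shape[0] - 1 - r)
        else:
            z_range = ((shape[0] - 1) / 2, (shape[0] - 1) / 2)
        for attempt in range(_MAX_PLACEMENT_TRIES):
            # laterally inside the shrunk nuclear ellipse so the
            # projection lands within the nucleus
            z = rng.uniform(*z_range)
            y = rng.uniform(r, shape[1] - 1 - r)
            x = rng.uniform(r, shape[2] - 1 - r)
            inside = (
                ((y - cy) / max(ay - r, 1e-9)) ** 2
                + ((x - cx) / max(ax - r, 1e-9)) ** 2
            ) <= 1.0
            if not inside:
                continue
            zi, yi, xi = int(round(z)), int(round(y)), int(round(x))
            lateral_ok = all(
                np.hypot(yi - f.center[1], xi - f.center[2])
                >= r + f.radius + min_gap
                for f in placed
            )
            if lateral_ok:
                spec = FocusSpec(
                    center=(zi, yi, xi),
                    radius=r,
                    peak_intensity=peak,
                    channel=channel,
                    label=label,
                )
                placed.append(spec)
                new.append(spec)
                break
        else:
            raise RuntimeError(
                f"could not place focus {len(new) + 1}/{n_foci} after "
                f"{_MAX_PLACEMENT_TRIES} tries; image too crowded"
            )
    return new


def _paint_spheres(
    shape: tuple[int, int, int], foci: list[FocusSpec]
) -> np.ndarray:
    layer = np.zeros(shape, dtype=float)
    for f in foci:
        zc, yc, xc = f.center
        r = f.radius
        ri = int(np.ceil(r))
        z0, z1 = max(zc - ri, 0), min(zc + ri, shape[0] - 1)
        y0, y1 = max(yc - ri, 0), min(yc + ri, shape[1] - 1)
        x0, x1 = max(xc - ri, 0), min(xc + ri, shape[2] - 1)
        zz, yy, xx = np.ogrid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
        ball = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2 <= r**2
        sub = layer[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
        np.maximum(sub, ball * float(f.peak_intensity), out=sub)
    return layer


def _finalize_channel(
    noiseless: np.ndarray,
    noise_model: str,
    bit_depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    hi = 2**bit_depth - 1
    if noise_model == "none":
        out = noiseless
    elif noise_model == "poisson":
        out = rng.poisson(noiseless.astype(float))
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    return np.clip(out, 0, hi).astype(np.uint16)


def render_cell(
    shape: tuple[int, int, int] = (16, 128, 128),
    n_foci: int = 20,
    focus_radius_range: tuple[float, float] = (2.0, 4.0),
    focus_intensity_range: tuple[int, int] = (1500, 3000),
    background_max: int = 300,
    blur_sigma: float = 1.0,
    noise_model: str = "poisson",
    seed: int = 0,
    bit_depth: int = DEFAULT_BIT_DEPTH,
    include_dapi: bool = True,
) -> ImageStack:
    """Render one synthetic interphase cell with ground truth.

    The CENH3 channel is the voxelwise maximum of (a) a smooth background
    whose maximum is exactly ``background_max`` and (b) ``n_foci`` hard
    spheres, Gaussian-blurred by ``blur_sigma`` to stand in for optics.
    Ground truth is taken from the pre-noise stack: the projected truth mask
    is the set of pixels whose noiseless maximum projection exceeds
    ``background_max``.  Deterministic for a fixed seed.

    With ``blur_sigma=0`` and ``noise_model="none"`` the downstream
    threshold-and-count measurement reproduces the ground-truth area
    exactly; the defaults (1-voxel blur, Poisson noise) emulate a realistic
    acquisition where small errors are expected.
    """
    if n_foci < 0:
        raise ValueError(f"n_foci must be >= 0, got {n_foci}")
    hi = 2**bit_depth - 1
    if not 0 <= background_max <= hi:
        raise ValueError(f"background_max outside [0, {hi}]")
    if n_foci > 0 and background_max >= focus_intensity_range[0]:
        raise ValueError(
            "background_max must be below the minimum focus intensity for a "
            f"separable ground truth (got {background_max} >= "
            f"{focus_intensity_range[0]})"
        )
    if focus_intensity_range[1] > hi:
        raise ValueError(
            f"focus intensity {focus_intensity_range[1]} exceeds bit depth"
        )

    rng = np.random.default_rng(seed)
    bg = _smooth_background(shape, background_max, rng)
    gap = 2.0 + 4.0 * blur_sigma  # keep blurred footprints from merging
    foci = _place_foci(
        shape, n_foci, focus_radius_range, focus_intensity_range, rng,
        min_gap=gap,
    )
    layer = _paint_spheres(shape, foci)
    if blur_sigma > 0:
        layer = gaussian_filter(layer, blur_sigma)
    noiseless = np.maximum(bg, np.round(layer).astype(np.int64))

    proj = noiseless.max(axis=0)
    truth = GroundTruth(
        foci=foci,
        projected_mask=proj > background_max,
        background_max=background_max,
    )

    channels = {CENH3: _finalize_channel(noiseless, noise_model, bit_depth, rng)}
    if include_dapi:
        dapi = _nucleus_mask(shape).astype(float) * (0.3 * hi)
        dapi = gaussian_filter(dapi, 1.0)
        channels[DAPI] = _finalize_channel(
            np.round(dapi).astype(np.int64), noise_model, bit_depth, rng
        )
    return ImageStack(channels=channels, bit_depth=bit_depth, ground_truth=truth)


def render_addition_line_cell(
    shape: tuple[int, int, int] = (16, 192, 192),
    n_host_foci: int = 41,
    n_alien_foci: int = 1,
    host_params: dict | None = None,
    alien_params: dict | None = None,
    fish_marks_alien: bool = True,
    background_max: int = 300,
    blur_sigma: float = 1.0,
    noise_model: str = "poisson",
    seed: int = 0,
    bit_depth: int = DEFAULT_BIT_DEPTH,
) -> ImageStack:
    """Render an addition-line cell: host centromeres plus alien centromeres
    carried on an introduced chromosome, with a FISH channel marking only
    the alien foci.

    The defaults emulate one cell of an oat line carrying a single added
    maize chromosome (41 host + 1 alien focus); host and alien focus sizes
    are equal by default, the regime where the two classes should be
    statistically indistinguishable.  ``host_params`` / ``alien_params``
    accept ``radius_range`` and ``intensity_range`` overrides.
    """
    if fish_marks_alien and n_alien_foci < 1:
        raise ValueError("need at least one alien focus when FISH marks alien")
    host_params = {
        "radius_range": (2.0, 4.0),
        "intensity_range": (1500, 3000),
        **(host_params or {}),
    }
    alien_params = {
        "radius_range": host_params["radius_range"],
        "intensity_range": host_params["intensity_range"],
        **(alien_params or {}),
    }
    hi = 2**bit_depth - 1
    min_peak = min(
        host_params["intensity_range"][0], alien_params["intensity_range"][0]
    )
    if background_max >= min_peak:
        raise ValueError(
            "background_max must be below the minimum focus intensity"
        )

    rng = np.random.default_rng(seed)
    bg = _smooth_background(shape, background_max, rng)
    gap = 2.0 + 4.0 * blur_sigma  # keep blurred footprints from merging
    alien = _place_foci(
        shape, n_alien_foci, alien_params["radius_range"],
        alien_params["intensity_range"], rng, label="alien", min_gap=gap,
    )
    host = _place_foci(
        shape, n_host_foci, host_params["radius_range"],
        host_params["intensity_range"], rng, label="host", existing=alien,
        min_gap=gap,
    )
    foci = alien + host

    cen_layer = _paint_spheres(shape, foci)
    fish_layer = _paint_spheres(shape, alien)
    if blur_sigma > 0:
        cen_layer = gaussian_filter(cen_layer, blur_sigma)
        fish_layer = gaussian_filter(fish_layer, blur_sigma)
    cen_noiseless = np.maximum(bg, np.round(cen_layer).astype(np.int64))
    fish_noiseless = np.round(fish_layer).astype(np.int64)

    proj = cen_noiseless.max(axis=0)
    truth = GroundTruth(
        foci=foci,
        projected_mask=proj > background_max,
        background_max=background_max,
    )
    channels = {
        CENH3: _finalize_channel(cen_noiseless, noise_model, bit_depth, rng),
    }
    if fish_marks_alien:
        channels[FISH] = _finalize_channel(
            fish_noiseless, noise_model, bit_depth, rng
        )
    return ImageStack(channels=channels, bit_depth=bit_depth, ground_truth=truth)


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar I/O
# ---------------------------------------------------------------------------

def _truth_to_json(truth: GroundTruth | None) -> dict | None:
    if truth is None:
        return None
    mask = truth.projected_mask
    return {
        "background_max": truth.background_max,
        "foci": [
            {
                "center": list(f.center),
                "radius": f.radius,
                "peak_intensity": f.peak_intensity,
                "channel": f.channel,
                "label": f.label,
            }
            for f in truth.foci
        ],
        "mask_shape": None if mask is None else list(mask.shape),
        "mask_true_pixels": None
        if mask is None
        else np.argwhere(mask).tolist(),
    }


def _truth_from_json(obj: dict | None) -> GroundTruth | None:
    if obj is None:
        return None
    mask = None
    if obj.get("mask_shape") is not None:
        mask = np.zeros(tuple(obj["mask_shape"]), dtype=bool)
        pix = np.asarray(obj["mask_true_pixels"], dtype=int)
        if pix.size:
            mask[pix[:, 0], pix[:, 1]] = True
    foci = [
        FocusSpec(
            center=tuple(f["center"]),
            radius=f["radius"],
            peak_intensity=f["peak_intensity"],
            channel=f["channel"],
            label=f.get("label"),
        )
        for f in obj["foci"]
    ]
    return GroundTruth(
        foci=foci, projected_mask=mask, background_max=obj["background_max"]
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF (axes C,Z,Y,X) with a JSON sidecar
    recording channel order, bit depth, and ground truth."""
    path = Path(path)
    arr = np.stack([stack.channels[c] for c in stack.channel_names])
    tifffile.imwrite(path, arr)
    sidecar = {
        "channels": stack.channel_names,
        "bit_depth": stack.bit_depth,
        "ground_truth": _truth_to_json(stack.ground_truth),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_stack(path) -> ImageStack:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    arr = tifffile.imread(path)
    if arr.ndim == 3:  # single channel written without the C axis
        arr = arr[None]
    channels = {name: arr[i] for i, name in enumerate(sidecar["channels"])}
    return ImageStack(
        channels=channels,
        bit_depth=sidecar["bit_depth"],
        ground_truth=_truth_from_json(sidecar.get("ground_truth")),
    )
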