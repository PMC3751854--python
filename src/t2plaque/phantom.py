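"""Digital carotid vessel phantom with multi-echo spin-echo simulation.

The phantom is a 2D cross-section of a carotid artery: a signal-suppressed
lumen (ideal double-inversion-recovery black blood), an annular vessel
wall of normal intima/media, circular plaque-component inclusions inside
the wall (fibrous cap, lipid-rich necrotic core, recent intraplaque
haemorrhage, calcification), an optional sternocleidomastoid-muscle disc,
and background.  Each signal-bearing pixel carries a ground-truth T2 and
amplitude beta drawn from per-tissue Gaussians; the multi-echo series is
the mono-exponential decay ``SI = beta * exp(-TE/T2)`` sampled on the TE
grid, corrupted by Rician noise (magnitude of signal plus complex
Gaussian noise).

The first echo of a multiple-spin-echo train is a pure primary echo while
later echoes are enhanced by stimulated-echo pathways; the simulator
emulates this by scaling the first echo by ``first_echo_scale`` (< 1).
Downstream fitting always discards the first echo, so results must be
insensitive to this scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

# integer codes used in label maps (also the NIfTI on-disk encoding)
LABEL_CODES = {
    "background": 0,
    "lumen": 1,
    "wall": 2,
    "fibrous": 3,
    "lrnc": 4,
    "recent_iph": 5,
    "calcification": 6,
    "muscle": 7,
}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}

#: tissues whose pixels carry a decaying signal (defined truth T2)
SIGNAL_TISSUES = ("wall", "fibrous", "lrnc", "recent_iph", "muscle")

#: default TE grid of the multiple-spin-echo acquisition, ms
DEFAULT_TE_MS = tuple(12.9 * k for k in range(1, 9))

#: per-tissue (T2 mean, T2 SD, beta mean, beta SD); T2 in ms, beta in
#: arbitrary signal units.  T2 distributions follow in-vivo carotid
#: measurements at 3 T: normal intima/media 54 +/- 13 ms, fibrous tissue
#: 56 +/- 9 ms, lipid-rich necrotic core 37 +/- 5 ms, recent intraplaque
#: haemorrhage 107 +/- 25 ms; skeletal muscle sits in the literature
#: 30-50 ms range.  Calcification gives essentially no signal.
DEFAULT_TISSUE_PARAMS = {
    "wall": (54.0, 13.0, 500.0, 25.0),
    "fibrous": (56.0, 9.0, 500.0, 25.0),
    "lrnc": (37.0, 5.0, 500.0, 25.0),
    "recent_iph": (107.0, 25.0, 500.0, 25.0),
    "muscle": (40.0, 5.0, 500.0, 25.0),
    "calcification": (0.0, 0.0, 0.0, 0.0),
}


def pixel_size_mm(fov_mm: float, n_pixels: int) -> float:
    """Reconstructed pixel size: field of view divided by (zero-padded)
    matrix size, e.g. 160 mm over 640 pixels -> 0.25 mm."""
    if fov_mm <= 0 or n_pixels <= 0:
        raise ValueError("fov_mm and n_pixels must be positive")
    return fov_mm / n_pixels


@dataclass
class PhantomSpec:
    """Geometry, tissue and acquisition parameters of the digital phantom.

    Coordinates are 0-based (row, col) with pixel centers on the integer
    grid.  ``component_blobs`` are circular inclusions (label, center,
    radius in pixels) that must lie inside the wall annulus; later blobs
    overwrite earlier ones.  ``noise_sd`` is the per-channel SD of
    the complex Gaussian noise underlying the Rician magnitude noise.

    SNR here always means measured magnitude over ``noise_sd``.  The
    default noise level puts the measured first-echo SNR of normal wall
    (beta 500, T2 54 ms, first-echo scale 0.85) at ~30, falling toward
    the SNR < 2 floor at the longest TEs for short-T2 tissue.
    """

    grid_shape: tuple[int, int] = (96, 96)
    pixel_size_mm: float = 0.25
    lumen_center: tuple[float, float] = (48.0, 48.0)
    lumen_radius_px: float = 12.0
    wall_thickness_px: float = 8.0
    component_blobs: list[tuple[str, tuple[float, float], float]] = field(
        default_factory=lambda: [
            ("fibrous", (48.0, 64.0), 4.0),
            ("lrnc", (32.0, 48.0), 4.0),
            ("recent_iph", (59.3, 36.7), 2.2),
            ("calcification", (36.7, 59.3), 2.0),
        ]
    )
    muscle_center: tuple[float, float] | None = (80.0, 80.0)
    muscle_radius_px: float = 9.0
    tissue_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PARAMS)
    )
    te_grid_ms: tuple[float, ...] = DEFAULT_TE_MS
    noise_sd: float = 11.2
    first_echo_scale: float = 0.85
    coil_profile: dict | None = None  # {"kind": "linear", "gradient": (gr, gc)}
    lumen_flow_echo1: float = 0.0  # residual-flow artefact amplitude on echo 1
    t2_floor_ms: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        te = np.asarray(self.te_grid_ms, dtype=float)
        if te.ndim != 1 or len(te) < 2 or np.any(np.diff(te) <= 0) or np.any(te <= 0):
            raise ValueError("te_grid_ms must be strictly increasing and positive")
        if self.lumen_radius_px <= 0 or self.wall_thickness_px <= 0:
            raise ValueError("radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 < self.first_echo_scale <= 1):
            raise ValueError("first_echo_scale must lie in (0, 1]")
        for label, (t2m, t2s, bm, bs) in self.tissue_params.items():
            if t2s < 0 or bs < 0:
                raise ValueError(f"negative SD for tissue {label!r}")
        r_in, r_out = self.lumen_radius_px, self.lumen_radius_px + self.wall_thickness_px
        c = np.asarray(self.lumen_center, dtype=float)
        for label, center, radius in self.component_blobs:
            if label not in LABEL_CODES:
                raise ValueError(f"unknown tissue label {label!r}")
            if radius <= 0:
                raise ValueError("blob radius must be positive")
            d = float(np.hypot(*(np.asarray(center, dtype=float) - c)))
            if d - radius < r_in or d + radius > r_out:
                raise ValueError(
                    f"blob {label!r} at {center} r={radius} falls outside the wall annulus"
                )

    def to_json(self) -> str:
        d = asdict(self)
        d["te_grid_ms"] = list(self.te_grid_ms)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["lumen_center"] = tuple(d["lumen_center"])
        d["te_grid_ms"] = tuple(d["te_grid_ms"])
        if d.get("muscle_center") is not None:
            d["muscle_center"] = tuple(d["muscle_center"])
        d["component_blobs"] = [
            (lbl, tuple(ctr), float(r)) for lbl, ctr, r in d.get("component_blobs", [])
        ]
        d["tissue_params"] = {k: tuple(v) for k, v in d.get("tissue_params", {}).items()}
        return cls(**d)


@dataclass
class Phantom:
    """Rasterized phantom: per-pixel tissue label and ground truth.

    ``truth_t2_ms`` and ``truth_beta`` are NaN / 0 where the label carries
    no decaying signal (lumen, background, calcification).
    """

    label_map: np.ndarray  # int codes, see LABEL_CODES
    truth_t2_ms: np.ndarray  # float, NaN where undefined
    truth_beta: np.ndarray  # float, 0 where signal-free

    def mask(self, *labels: str) -> np.ndarray:
        codes = [LABEL_CODES[l] for l in labels]
        return np.isin(self.label_map, codes)

    @property
    def wall_mask(self) -> np.ndarray:
        """Everything inside the vessel-wall boundaries (all wall tissues)."""
        return self.mask("wall", "fibrous", "lrnc", "recent_iph", "calcification")


def _disc(shape: tuple[int, int], center, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the geometry and draw per-pixel ground truth.

    Pixel-center inclusion decides membership; blobs are painted in list
    order (last listed wins on overlap).  T2 draws are truncated below at
    ``spec.t2_floor_ms`` to keep the decay physical.  Reproducible for a
    fixed ``spec.seed``.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    label = np.full(shape, LABEL_CODES["background"], dtype=np.int16)

    r_in = spec.lumen_radius_px
    r_out = r_in + spec.wall_thickness_px
    label[_disc(shape, spec.lumen_center, r_out)] = LABEL_CODES["wall"]
    label[_disc(shape, spec.lumen_center, r_in)] = LABEL_CODES["lumen"]
    if spec.muscle_center is not None:
        label[_disc(shape, spec.muscle_center, spec.muscle_radius_px)] = LABEL_CODES["muscle"]
    for tissue, center, radius in spec.component_blobs:
        label[_disc(shape, center, radius)] = LABEL_CODES[tissue]

    rng = np.random.default_rng(spec.seed)
    t2 = np.full(shape, np.nan)
    beta = np.zeros(shape)
    for tissue in SIGNAL_TISSUES:
        m = label == LABEL_CODES[tissue]
        if not m.any():
            continue
        t2m, t2s, bm, bs = spec.tissue_params[tissue]
        n = int(m.sum())
        t2[m] = np.maximum(rng.normal(t2m, t2s, n), spec.t2_floor_ms)
        beta[m] = np.maximum(rng.normal(bm, bs, n), 0.0)
    return Phantom(label_map=label, truth_t2_ms=t2, truth_beta=beta)


def noise_free_series(phantom: Phantom, spec: PhantomSpec) -> np.ndarray:
    """Ideal signal stack, shape (n_echo, rows, cols)."""
    te = np.asarray(spec.te_grid_ms, dtype=float)
    t2 = np.where(np.isfinite(phantom.truth_t2_ms), phantom.truth_t2_ms, 1.0)
    decay = np.exp(-te[:, None, None] / t2[None])
    stack = phantom.truth_beta[None] * decay
    stack[:, ~np.isfinite(phantom.truth_t2_ms)] = 0.0
    stack[0] *= spec.first_echo_scale
    if spec.lumen_flow_echo1:
        stack[0][phantom.mask("lumen")] += spec.lumen_flow_echo1
    if spec.coil_profile is not None:
        stack *= coil_field(spec)[None]
    return stack


def coil_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth multiplicative coil-sensitivity field (mean ~1)."""
    prof = spec.coil_profile or {}
    rr, cc = np.mgrid[0 : spec.grid_shape[0], 0 : spec.grid_shape[1]]
    if prof.get("kind", "linear") == "linear":
        gr, gc = prof.get("gradient", (0.0, 0.0))
        f = 1.0 + gr * (rr - rr.mean()) / rr.shape[0] + gc * (cc - cc.mean()) / cc.shape[1]
        return np.clip(f, 0.1, None)
    raise ValueError(f"unknown coil profile kind {prof.get('kind')!r}")


def add_rician_noise(stack: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + complex Gaussian noise), per-channel SD ``noise_sd``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return stack.copy()
    re = stack + rng.normal(0.0, noise_sd, stack.shape)
    im = rng.normal(0.0, noise_sd, stack.shape)
    return np.hypot(re, im)


def simulate_series(phantom: Phantom, spec: PhantomSpec, seed: int | None = None):
    """Simulate the noisy multi-echo magnitude series.

    Returns ``(stack, te_ms)`` with ``stack`` of shape (n_echo, rows,
    cols).  The noise seed defaults to ``spec.seed + 1`` so geometry and
    noise can be varied independently.
    """
    spec.validate()
    clean = noise_free_series(phantom, spec)
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    noisy = add_rician_noise(clean, spec.noise_sd, rng)
    return noisy, np.asarray(spec.te_grid_ms, dtype=float)


def write_fixture_bundle(phantom: Phantom, stack: np.ndarray, te_ms: np.ndarray,
                         spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete phantom bundle readable by :mod:`t2plaque.io`.

    Files: ``series.nii`` (echo stack), ``series.json`` (TE vector and
    noise SD sidecar), ``labels.nii``, ``truth_t2.nii``, ``truth_beta.nii``,
    ``wall_mask.nii``, ``background_mask.nii``, ``spec.json``.
    """
    from . import io as t2io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["series"] = t2io.write_series(
        out / "series.nii", stack, te_ms,
        pixel_size_mm=spec.pixel_size_mm, noise_sd=spec.noise_sd,
    )
    paths["labels"] = t2io.write_image(out / "labels.nii", phantom.label_map,
                                       spec.pixel_size_mm, dtype=np.int16)
    paths["truth_t2"] = t2io.write_image(out / "truth_t2.nii", phantom.truth_t2_ms,
                                         spec.pixel_size_mm)
    paths["truth_beta"] = t2io.write_image(out / "truth_beta.nii", phantom.truth_beta,
                                           spec.pixel_size_mm)
    paths["wall_mask"] = t2io.write_image(out / "wall_mask.nii",
                                          phantom.wall_mask.astype(np.uint8),
                                          spec.pixel_size_mm, dtype=np.uint8)
    paths["background_mask"] = t2io.write_image(
        out / "background_mask.nii", phantom.mask("background").astype(np.uint8),
        spec.pixel_size_mm, dtype=np.uint8)
    (out / "spec.json").write_text(spec.to_json())
    paths["spec"] = out / "spec.json"
    return paths
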