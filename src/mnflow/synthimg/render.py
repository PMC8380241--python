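"""Deterministic rendering of two-channel 16-bit synthetic cell images.

Fluorescence channel: bright soft discs for nuclei and micronuclei on a low
background. Brightfield channel: one textured cell disc with a darker rim on
a bright background. All randomness flows through the explicit seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from mnflow.ingest.records import IMAGE_SIZE
from mnflow.synthimg.profiles import LabProfile
from mnflow.synthimg.specs import CellSpec

_YY, _XX = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE].astype(np.float64)


def _soft_disc(cy: float, cx: float, radius: float, aspect: float = 1.0) -> np.ndarray:
    """Anti-aliased disc indicator in [0, 1]."""
    dist = np.hypot((_XX - cx) / aspect, _YY - cy)
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _place_discs(
    rng: np.random.Generator,
    radii: list[float],
    centre: tuple[float, float],
    cell_radius: float,
    margin: float,
    min_edge_gap: float,
    existing: list[tuple[float, float, float]] | None = None,
    max_tries: int = 400,
) -> list[tuple[float, float, float]]:
    """Rejection-sample disc centres so each disc lies wholly inside the cell
    boundary (with ``margin``) and keeps ``min_edge_gap`` clearance from every
    other disc. The gap relaxes by 10% after each failed full attempt, so
    placement always terminates deterministically. Returns only the newly
    placed discs as (cy, cx, r)."""
    fixed: list[tuple[float, float, float]] = list(existing or [])
    gap = min_edge_gap
    while True:
        attempt = list(fixed)
        ok = True
        for r in radii:
            region_r = max(cell_radius - r - margin, 0.0)
            for _ in range(max_tries):
                rho = region_r * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                cy = centre[0] + rho * np.sin(theta)
                cx = centre[1] + rho * np.cos(theta)
                if all(
                    np.hypot(cy - py, cx - px) >= r + pr + gap
                    for py, px, pr in attempt
                ):
                    attempt.append((cy, cx, r))
                    break
            else:
                ok = False
                break
        if ok:
            return attempt[len(fixed):]
        gap *= 0.9  # relax and retry; terminates since gap -> 0


def _smooth_noise(rng: np.random.Generator, sigma: float, amplitude: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal((IMAGE_SIZE, IMAGE_SIZE)), sigma)
    sd = field.std()
    if sd > 0:
        field = field / sd
    return amplitude * field


def _quantize(channel: np.ndarray) -> np.ndarray:
    return np.floor(np.clip(channel, 0.0, 1.0) * 65535 + 0.5).astype(np.uint16)


def _tilt_plane(rng: np.random.Generator, tilt: float) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi)
    u = (_XX - IMAGE_SIZE / 2) * np.cos(theta) + (_YY - IMAGE_SIZE / 2) * np.sin(theta)
    return 1.0 + tilt * u / IMAGE_SIZE


def render_cell(spec: CellSpec, lab: LabProfile, seed: int) -> np.ndarray:
    """Render one cell as a (64, 64, 2) uint16 array (fluorescence, brightfield).

    Deterministic for fixed (spec, lab, seed). Raises ValueError if the spec
    violates its invariants (already enforced at CellSpec construction).
    """
    rng = np.random.default_rng(seed)
    if spec.unscorable_kind is not None:
        return _render_unscorable(spec, lab, rng)

    centre = (
        IMAGE_SIZE / 2 + rng.uniform(-2, 2),
        IMAGE_SIZE / 2 + rng.uniform(-2, 2),
    )
    cell_r = spec.cell_diameter_px / 2.0
    focus_sigma = lab.blur_sigma_px * rng.uniform(0.8, 1.25)

    nucleus_radii = [d / 2.0 for d in spec.nucleus_diameters_px]
    gap = 2.5 + 2.0 * focus_sigma
    nuclei = _place_discs(rng, nucleus_radii, centre, cell_r, 2.0, gap)

    mn_radii = [ratio * spec.mean_nucleus_diameter / 2.0 for ratio in spec.mn_diameter_ratios]
    mns = _place_discs(rng, mn_radii, centre, cell_r, 2.0, gap, existing=nuclei)

    return _render_channels(spec, lab, rng, centre, cell_r, focus_sigma, nuclei, mns)


def _render_channels(spec, lab, rng, centre, cell_r, focus_sigma, nuclei, mns,
                     bf_level=0.90, texture_amp=0.05, rim_level=0.50):
    # fluorescence
    signal = np.zeros((IMAGE_SIZE, IMAGE_SIZE))
    for cy, cx, r in nuclei:
        signal = np.maximum(signal, rng.uniform(0.82, 0.95) * _soft_disc(cy, cx, r))
    for cy, cx, r in mns:
        signal = np.maximum(signal, rng.uniform(0.92, 1.0) * _soft_disc(cy, cx, r))
    signal = np.clip(signal * lab.fluor_gain, 0.0, 1.0)
    signal = ndimage.gaussian_filter(signal, focus_sigma)
    fluor = lab.background_level * _tilt_plane(rng, lab.illumination_tilt) + signal
    fluor = fluor + rng.normal(0.0, lab.channel_noise_sd, fluor.shape)

    # brightfield
    disc = _soft_disc(centre[0], centre[1], cell_r, spec.aspect)
    bf = 0.78 * _tilt_plane(rng, lab.illumination_tilt)
    interior = bf_level + _smooth_noise(rng, 1.5, texture_amp)
    bf = bf * (1.0 - disc * (1.0 - interior))
    dist = np.hypot((_XX - centre[1]) / spec.aspect, _YY - centre[0])
    rim = np.clip(1.5 - np.abs(dist - cell_r), 0.0, 1.0)
    bf = bf * (1.0 - rim * (1.0 - rim_level))
    bf = ndimage.gaussian_filter(bf, 0.7 * focus_sigma)
    bf = bf + rng.normal(0.0, lab.channel_noise_sd, bf.shape)

    return np.stack([_quantize(fluor), _quantize(bf)], axis=-1)


def _render_unscorable(spec: CellSpec, lab: LabProfile, rng: np.random.Generator) -> np.ndarray:
    kind = spec.unscorable_kind
    centre = (IMAGE_SIZE / 2 + rng.uniform(-2, 2), IMAGE_SIZE / 2 + rng.uniform(-2, 2))
    focus_sigma = lab.blur_sigma_px * rng.uniform(0.8, 1.25)

    if kind == "debris":
        # small irregular speckles, no cell disc
        n = rng.integers(2, 6)
        fluor = lab.background_level * _tilt_plane(rng, lab.illumination_tilt)
        bf = 0.78 * _tilt_plane(rng, lab.illumination_tilt)
        for _ in range(n):
            cy, cx = rng.uniform(8, IMAGE_SIZE - 8, size=2)
            r = rng.uniform(1.0, 3.0)
            fluor = fluor + rng.uniform(0.1, 0.5) * _soft_disc(cy, cx, r)
            bf = bf * (1.0 - 0.5 * _soft_disc(cy, cx, r * rng.uniform(0.8, 1.5)))
        fluor = ndimage.gaussian_filter(fluor, focus_sigma)
        bf = ndimage.gaussian_filter(bf, 0.7 * focus_sigma)
        fluor += rng.normal(0.0, lab.channel_noise_sd, fluor.shape)
        bf += rng.normal(0.0, lab.channel_noise_sd, bf.shape)
        return np.stack([_quantize(fluor), _quantize(bf)], axis=-1)

    if kind == "doublet":
        # two touching cell discs, each with one nucleus
        cell_r = spec.cell_diameter_px / 2.0 * 0.8
        offset = cell_r * 0.95
        theta = rng.uniform(0, 2 * np.pi)
        c1 = (centre[0] + offset * np.sin(theta), centre[1] + offset * np.cos(theta))
        c2 = (centre[0] - offset * np.sin(theta), centre[1] - offset * np.cos(theta))
        nuc_r = cell_r * 0.45
        nuclei = [(c1[0], c1[1], nuc_r), (c2[0], c2[1], nuc_r)]
        signal = np.zeros((IMAGE_SIZE, IMAGE_SIZE))
        for cy, cx, r in nuclei:
            signal = np.maximum(signal, rng.uniform(0.82, 0.95) * _soft_disc(cy, cx, r))
        signal = ndimage.gaussian_filter(np.clip(signal * lab.fluor_gain, 0, 1), focus_sigma)
        fluor = lab.background_level * _tilt_plane(rng, lab.illumination_tilt) + signal
        fluor += rng.normal(0.0, lab.channel_noise_sd, fluor.shape)
        bf = 0.78 * _tilt_plane(rng, lab.illumination_tilt)
        for cy, cx in (c1, c2):
            disc = _soft_disc(cy, cx, cell_r)
            interior = 0.90 + _smooth_noise(rng, 1.5, 0.05)
            bf = bf * (1.0 - disc * (1.0 - interior))
            dist = np.hypot(_XX - cx, _YY - cy)
            rim = np.clip(1.5 - np.abs(dist - cell_r), 0.0, 1.0)
            bf = bf * (1.0 - rim * 0.5)
        bf = ndimage.gaussian_filter(bf, 0.7 * focus_sigma)
        bf += rng.normal(0.0, lab.channel_noise_sd, bf.shape)
        return np.stack([_quantize(fluor), _quantize(bf)], axis=-1)

    if kind == "out_of_focus":
        # a normal-looking cell rendered at 4x the optical blur
        n_nuclei = int(rng.integers(1, 3))
        cell_r = spec.cell_diameter_px / 2.0
        nuc_r = cell_r * (0.48 if n_nuclei == 1 else 0.38)
        nuclei = _place_discs(rng, [nuc_r] * n_nuclei, centre, cell_r, 2.0, 3.0)
        return _render_channels(spec, lab, rng, centre, cell_r,
                                4.0 * max(focus_sigma, 0.8), nuclei, [])

    if kind == "mitotic":
        # fragmented chromatin texture inside a large cell disc
        cell_r = spec.cell_diameter_px / 2.0 * 1.05
        n_frag = int(rng.integers(8, 15))
        radii = [rng.uniform(1.5, 3.0) for _ in range(n_frag)]
        frags = _place_discs(rng, radii, centre, cell_r * 0.55, 0.0, 0.5)
        return _render_channels(spec, lab, rng, centre, cell_r, focus_sigma, [], frags,
                                texture_amp=0.08)

    if kind == "dead":
        # shrunken granular disc with fragmented fluorescence
        cell_r = spec.cell_diameter_px / 2.0 * 0.5
        n_frag = int(rng.integers(3, 7))
        radii = [rng.uniform(1.5, 3.5) for _ in range(n_frag)]
        frags = _place_discs(rng, radii, centre, max(cell_r * 0.75, 5.0), 0.0, 0.3)
        return _render_channels(spec, lab, rng, centre, cell_r, focus_sigma, [], frags,
                                bf_level=0.75, texture_amp=0.18, rim_level=0.45)

    raise ValueError(f"unknown unscorable kind {kind!r}")
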