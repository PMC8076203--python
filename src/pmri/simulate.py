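"""Synthetic multi-coil Cartesian k-space with known ground truth.

The simulator stands in for a multi-channel head-coil acquisition: a real
phantom image is multiplied by smooth complex per-coil sensitivity maps,
Fourier-transformed (centred, orthonormal convention: DC at index
``n // 2``, Parseval holds exactly), and corrupted with i.i.d. circular
complex Gaussian noise.

Two sensitivity families are provided:

* ``smooth-gaussian`` — Gaussian-magnitude bumps placed around the image with
  smooth random phase: a realistic stand-in for receive coils.
* ``harmonic`` — unit-modulus pure spatial harmonics
  ``exp(i 2π m_l y / ny)`` with ``m_l = l``.  With at least ``R`` such coils
  every missing phase-encode line is an exact linear combination of acquired
  coil lines (the classic SMASH construction), which makes this family an
  analytic correctness oracle for GRAPPA-type reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import SamplingMask

__all__ = [
    "KSpace",
    "CoilSensitivities",
    "fft2c",
    "ifft2c",
    "make_phantom",
    "make_sensitivities",
    "simulate_kspace",
    "apply_mask",
    "coil_images",
]


# ---------------------------------------------------------------------------
# centred orthonormal FFT helpers

def fft2c(img: np.ndarray) -> np.ndarray:
    """Centred 2-D orthonormal FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


# ---------------------------------------------------------------------------
# containers

@dataclass
class KSpace:
    """Complex multi-coil Cartesian k-space, DC at the centre index.

    ``data`` has shape ``(n_coils, n_ky, n_kx)``; ``sampled`` flags acquired
    phase-encode lines (unsampled lines are exactly zero-filled).
    """

    data: np.ndarray
    sampled: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_coils, n_ky, n_kx)")
        self.sampled = np.asarray(self.sampled, dtype=bool)
        if self.sampled.shape != (self.data.shape[1],):
            raise ValueError("sampled must have one flag per ky line")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_ky(self) -> int:
        return self.data.shape[1]

    @property
    def n_kx(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "KSpace":
        return KSpace(self.data.copy(), self.sampled.copy(), dict(self.meta))


@dataclass
class CoilSensitivities:
    """Complex per-coil sensitivity maps ``(n_coils, ny, nx)``."""

    maps: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if not np.isfinite(self.maps).all():
            raise ValueError("sensitivity maps must be finite")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


# ---------------------------------------------------------------------------
# phantoms

# Modified Shepp-Logan ellipses: (intensity, a, b, x0, y0, phi_deg) on the
# [-1, 1]^2 square; intensities tuned for visible soft-tissue contrast.
_SHEPP_LOGAN = [
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
]


def make_phantom(
    ny: int, nx: int, kind: str = "shepp-logan", seed: int = 0
) -> np.ndarray:
    """Nonnegative test image with maximum value 1.

    ``shepp-logan`` evaluates the modified Shepp-Logan ellipse set
    analytically at each pixel centre; ``blobs`` is a smooth sum of a few
    Gaussian bumps (deterministic for a given ``seed``); ``speckle`` is a
    smooth random image built from white complex k-space noise under a
    Gaussian spectral envelope.  Speckle's spectrum is generic (no
    separable structure), which keeps GRAPPA calibration systems full rank —
    the phantom of choice for k-space-exactness fixtures.
    """
    if ny < 16 or nx < 16:
        raise ValueError("ny and nx must be at least 16")
    if kind == "shepp-logan":
        y, x = np.meshgrid(
            np.linspace(-1, 1, ny, endpoint=False) + 1 / ny,
            np.linspace(-1, 1, nx, endpoint=False) + 1 / nx,
            indexing="ij",
        )
        img = np.zeros((ny, nx))
        for val, a, b, x0, y0, phi in _SHEPP_LOGAN:
            c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
            xr = (x - x0) * c + (-(y) - y0) * s
            yr = -(x - x0) * s + (-(y) - y0) * c
            img += val * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
        img = np.clip(img, 0.0, None)
    elif kind == "blobs":
        rng = np.random.default_rng(seed)
        y, x = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        img = np.zeros((ny, nx))
        # centres and widths keep the Gaussian tails (and hence the spectral
        # leakage from border truncation) below ~1e-9 of the peak
        for _ in range(4):
            cy = rng.uniform(0.42, 0.58) * ny
            cx = rng.uniform(0.42, 0.58) * nx
            w = rng.uniform(0.045, 0.065) * min(ny, nx)
            amp = rng.uniform(0.4, 1.0)
            img += amp * np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2 * w**2)))
    elif kind == "speckle":
        rng = np.random.default_rng(seed)
        ky = np.arange(ny)[:, None] - ny // 2
        kx = np.arange(nx)[None, :] - nx // 2
        sig = min(ny, nx) / 13.0  # edge of k-space suppressed below ~1e-10
        env = np.exp(-(ky**2 + kx**2) / (2 * sig**2))
        spec = (rng.normal(size=(ny, nx)) + 1j * rng.normal(size=(ny, nx)))
        img = np.real(ifft2c(spec * env))
        img = img - img.min()
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")
    m = img.max()
    return img / m if m > 0 else img


# ---------------------------------------------------------------------------
# coil sensitivities

def make_sensitivities(
    n_coils: int,
    ny: int,
    nx: int,
    kind: str = "smooth-gaussian",
    seed: int = 0,
) -> CoilSensitivities:
    """Simulated receive-coil sensitivity maps.

    ``smooth-gaussian`` places Gaussian-magnitude bumps at equal angles
    around a circle just inside the FOV with a smooth random linear phase;
    the sum-of-squares of the maps stays well away from zero everywhere in
    the matrix.  ``harmonic`` returns unit-modulus pure harmonics
    ``exp(i 2π l y / ny)`` along the phase-encode axis.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if kind == "harmonic":
        # phase measured from the centre pixel so that, under the centred
        # FFT convention, coil l's spectrum is coil 0's rolled by exactly
        # l lines with no extra phase factor
        yy = (np.arange(ny) - ny // 2)[None, :, None]
        orders = np.arange(n_coils)[:, None, None]
        maps = np.exp(2j * np.pi * orders * yy / ny) * np.ones((1, 1, nx))
        return CoilSensitivities(maps, kind, {"orders": list(range(n_coils))})
    if kind != "smooth-gaussian":
        raise ValueError(f"unknown sensitivity kind: {kind!r}")
    rng = np.random.default_rng(seed)
    y, x = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    radius = 0.55 * min(ny, nx)
    width = 0.7 * min(ny, nx)
    maps = np.empty((n_coils, ny, nx), dtype=np.complex128)
    for l in range(n_coils):
        theta = 2 * np.pi * l / n_coils + rng.uniform(-0.1, 0.1)
        cy = ny / 2 + radius * np.sin(theta)
        cx = nx / 2 + radius * np.cos(theta)
        mag = np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2 * width**2)))
        gy, gx = rng.uniform(-1.5, 1.5, size=2)
        phase = 2 * np.pi * (gy * y / ny + gx * x / nx) + rng.uniform(0, 2 * np.pi)
        maps[l] = mag * np.exp(1j * phase)
    return CoilSensitivities(maps, kind, {"seed": seed})


# ---------------------------------------------------------------------------
# acquisition

def simulate_kspace(
    image: np.ndarray,
    sens: CoilSensitivities,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KSpace:
    """Fully sampled multi-coil k-space of ``image`` seen through ``sens``.

    Each coil's data is the centred orthonormal FFT of ``sens[l] * image``
    plus complex Gaussian noise with standard deviation ``noise_sigma`` per
    real and imaginary component.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape != sens.maps.shape[1:]:
        raise ValueError("image shape must match sensitivity maps")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    data = fft2c(sens.maps * image[None])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(scale=noise_sigma, size=(2, *data.shape))
        data = data + noise[0] + 1j * noise[1]
    sampled = np.ones(image.shape[0], dtype=bool)
    meta = {"noise_sigma": float(noise_sigma), "seed": int(seed),
            "sens_kind": sens.kind}
    return KSpace(data, sampled, meta)


def apply_mask(kspace: KSpace, mask: SamplingMask) -> KSpace:
    """Zero out unacquired phase-encode lines across all coils."""
    if mask.n_ky != kspace.n_ky:
        raise ValueError("mask n_ky does not match k-space")
    out = kspace.copy()
    out.data[:, ~mask.sampled, :] = 0.0
    out.sampled = mask.sampled.copy()
    return out


def coil_images(kspace: KSpace) -> np.ndarray:
    """Per-coil complex images via the inverse centred orthonormal FFT."""
    return ifft2c(kspace.data)
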