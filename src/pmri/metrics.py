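"""Coil combination and reconstruction-quality metrics.

The reference image is the root-sum-of-squares (SoS) combination of the
per-coil magnitude images,

    I_sos = sqrt( Σ_l |I_l|² ),

and reconstructions are scored against it with two regionwise metrics:

* artifact power, ``AP = Σ_ROI (|I_ref| − |I_recon|)² / Σ_ROI |I_ref|²`` —
  the normalized squared magnitude error (lower is better);
* ``SNR = 10·log10( Σ_ROI |I_recon|² / Σ_ROI |I_recon − I_ref|² )`` in dB
  (higher is better; +inf when the images agree exactly).

AP is intentionally scale-sensitive: reconstructions must be compared at
their native scale (the orthonormal FFT convention keeps image and k-space
energies equal), not renormalized.  The ROI defaults to the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Roi",
    "MetricsReport",
    "sos_combine",
    "artifact_power",
    "snr_db",
    "difference_map",
    "evaluate",
]


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest ``[y0:y1, x0:x1]`` (half-open)."""

    y0: int
    y1: int
    x0: int
    x1: int

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "Roi":
        return cls(0, shape[0], 0, shape[1])

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass
class MetricsReport:
    """AP / SNR / acceleration accounting for one reconstruction run."""

    ap: float
    snr_db: float
    roi: Roi
    r_net: float | None = None
    lines: dict = field(default_factory=dict)

    @property
    def ap_percent(self) -> float:
        return 100.0 * self.ap

    def to_json_dict(self) -> dict:
        return {
            "ap_percent": self.ap_percent,
            "snr_db": "inf" if np.isinf(self.snr_db) else self.snr_db,
            "r_net": self.r_net,
            "lines": self.lines,
            "roi": [self.roi.y0, self.roi.y1, self.roi.x0, self.roi.x1],
        }


def sos_combine(coil_imgs: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares magnitude combination over the coil axis."""
    coil_imgs = np.asarray(coil_imgs)
    if coil_imgs.ndim != 3 or coil_imgs.shape[0] < 1:
        raise ValueError("coil images must be a non-empty (L, ny, nx) stack")
    return np.sqrt((np.abs(coil_imgs) ** 2).sum(axis=0))


def _check_pair(recon: np.ndarray, reference: np.ndarray) -> None:
    if recon.shape != reference.shape:
        raise ValueError("reconstruction and reference shapes differ")


def artifact_power(
    recon: np.ndarray, reference: np.ndarray, roi: Roi | None = None
) -> float:
    """Normalized squared magnitude error over the ROI (fraction, not %)."""
    recon, reference = np.asarray(recon), np.asarray(reference)
    _check_pair(recon, reference)
    roi = roi or Roi.full(recon.shape)
    sl = roi.slices()
    ref = np.abs(reference[sl])
    rec = np.abs(recon[sl])
    denom = float((ref**2).sum())
    if denom == 0.0:
        raise ValueError("reference has zero energy on the ROI")
    return float(((ref - rec) ** 2).sum() / denom)


def snr_db(
    recon: np.ndarray, reference: np.ndarray, roi: Roi | None = None
) -> float:
    """Energy ratio of the reconstruction to its error, in dB.

    Returns ``+inf`` when the two images agree exactly on the ROI (a defined
    outcome, serialized as the string ``"inf"``).
    """
    recon, reference = np.asarray(recon), np.asarray(reference)
    _check_pair(recon, reference)
    roi = roi or Roi.full(recon.shape)
    sl = roi.slices()
    err = float((np.abs(recon[sl] - reference[sl]) ** 2).sum())
    sig = float((np.abs(recon[sl]) ** 2).sum())
    if err == 0.0:
        return float("inf")
    return 10.0 * np.log10(sig / err)


def difference_map(
    recon: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Signed magnitude difference ``|recon| − |ref|`` and its absolute value."""
    recon, reference = np.asarray(recon), np.asarray(reference)
    _check_pair(recon, reference)
    signed = np.abs(recon) - np.abs(reference)
    return signed, np.abs(signed)


def evaluate(
    recon: np.ndarray,
    reference: np.ndarray,
    roi: Roi | None = None,
    r_net: float | None = None,
    lines: dict | None = None,
) -> MetricsReport:
    """Bundle AP and SNR against a reference into a :class:`MetricsReport`."""
    roi = roi or Roi.full(np.asarray(recon).shape)
    return MetricsReport(
        ap=artifact_power(recon, reference, roi),
        snr_db=snr_db(recon, reference, roi),
        roi=roi,
        r_net=r_net,
        lines=lines or {},
    )
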