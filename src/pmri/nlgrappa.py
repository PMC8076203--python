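"""Nonlinear GRAPPA: explicit second-order polynomial feature expansion.

The polynomial kernel ``k(a_i, a_j) = (γ aᵢᵀaⱼ + r)^d`` with γ = r = 1,
d = 2 motivates lifting each GRAPPA source neighborhood into a
higher-dimensional space before the linear fit.  Rather than the kernel
trick, the lift is the explicit truncated second-order map: for every coil
``l``, block ``b`` and column ``h`` of the neighborhood the feature vector
contains

1. a constant ``1``,
2. the first-order samples ``S_l(b, h)`` (the plain GRAPPA features),
3. their squares ``S_l(b, h)²``,
4. adjacent-column products ``S_l(b, h) · S_l(b, h+1)``,
5. gap-2 products ``S_l(b, h) · S_l(b, h+2)``,

giving ``N_k = 1 + 4 · L · n_blocks · n_cols`` complex features (no
conjugates are introduced).  The ``h+1`` / ``h+2`` factors beyond the last
kernel column are read from the same acquired line along the fully sampled
kx axis, zero outside the matrix, so all four second-order blocks keep the
same size.

Because the second-order terms are not homogeneous in the data scale, the
k-space is normalized by its maximum modulus before calibration and
synthesis and the synthesized samples are rescaled afterwards; this makes
the reconstruction scale-equivariant.  Since the linear features are a
coordinate subspace of the lifted space, the training residual of the
nonlinear fit can never exceed the linear one on the same system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grappa import KernelGeometry, grappa_reconstruct
from .sampling import SamplingMask
from .simulate import KSpace

__all__ = ["NLConfig", "feature_map", "nl_feature_map", "nlgrappa_reconstruct"]


@dataclass(frozen=True)
class NLConfig:
    """Polynomial-kernel parameters; only the γ = r = 1, d = 2 expansion is
    implemented, so ``degree`` values other than 2 are rejected."""

    gamma: float = 1.0
    r_offset: float = 1.0
    degree: int = 2

    def __post_init__(self) -> None:
        if self.degree != 2:
            raise ValueError(
                "only the explicit second-order expansion (degree=2) is "
                "implemented; other polynomial degrees are not supported"
            )


def nl_feature_map(sources: np.ndarray) -> np.ndarray:
    """Second-order feature matrix from a neighborhood tensor.

    ``sources`` has shape ``(M, L, n_blocks, n_cols + 2)`` — the principal
    kernel columns plus the two kx-extension columns (already zero-filled
    outside the matrix).  Returns ``(M, 1 + 4·L·n_blocks·n_cols)`` laid out
    as [1 | first-order | squares | adjacent products | gap-2 products],
    each block in C-order over (coil, block, column).
    """
    m = sources.shape[0]
    v = sources[..., :-2]
    v1 = sources[..., 1:-1]
    v2 = sources[..., 2:]
    blocks = [
        np.ones((m, 1), dtype=sources.dtype),
        v.reshape(m, -1),
        (v * v).reshape(m, -1),
        (v * v1).reshape(m, -1),
        (v * v2).reshape(m, -1),
    ]
    return np.concatenate(blocks, axis=1)


def feature_map(neighborhood: np.ndarray, config: NLConfig = NLConfig()) -> np.ndarray:
    """Feature vector(s) for one or more neighborhoods.

    Accepts a single ``(L, n_blocks, n_cols + 2)`` neighborhood or a batch
    with a leading instance axis; returns the corresponding feature vector
    or matrix.
    """
    del config  # degree validated at construction; expansion is fixed
    nbh = np.asarray(neighborhood)
    single = nbh.ndim == 3
    if single:
        nbh = nbh[None]
    out = nl_feature_map(nbh)
    return out[0] if single else out


def feature_length(n_coils: int, n_blocks: int, n_cols: int) -> int:
    """N_k = 1 + 4 · L · n_blocks · n_cols."""
    return 1 + 4 * n_coils * n_blocks * n_cols


def nlgrappa_reconstruct(
    kspace: KSpace,
    mask: SamplingMask,
    geom: KernelGeometry | None = None,
    config: NLConfig = NLConfig(),
    ridge: float = 1e-6,
    return_weights: bool = False,
):
    """Per-region NL-GRAPPA reconstruction.

    Identical driver to :func:`pmri.grappa.grappa_reconstruct` with the
    second-order feature map applied to every calibration row and synthesis
    neighborhood.  The default ridge (relative to the largest singular
    value) regularizes the frequently underdetermined fits (M < N_k is
    expected at small ACS and simply yields the minimum-norm solution when
    ``ridge`` is zero).
    """
    del config  # construction already validated degree == 2
    scale = float(np.abs(kspace.data).max())
    return grappa_reconstruct(
        kspace,
        mask,
        geom=geom,
        ridge=ridge,
        feature_map=nl_feature_map,
        model_order=2,
        scale=scale if scale > 0 else None,
        return_weights=return_weights,
    )
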