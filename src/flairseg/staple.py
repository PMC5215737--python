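"""STAPLE: simultaneous truth and performance level estimation.

Given several binary tracings of the same structure, STAPLE treats the
unknown true segmentation as a latent binary field and each rater j as a
noisy channel with sensitivity p_j = P(D_ij = 1 | T_i = 1) and specificity
q_j = P(D_ij = 0 | T_i = 0), with voxel-wise independent errors. EM
alternates between

* E-step: the posterior probability W_i that voxel i is truly foreground,
  from the current (p, q) and a global prior on foreground prevalence;
* M-step: re-estimating each rater's (p_j, q_j) as W-weighted agreement
  rates.

The observed-data log-likelihood is non-decreasing across iterations (the
EM guarantee; the prior is held fixed). Estimation is restricted to an
analysis region — by default the bounding box of the rater union dilated
by 5 voxels — because the specificity estimate depends on how much empty
background is counted; voxels outside the region get W = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from .volumes import BinaryMask, Volume, require_same_grid

__all__ = ["StapleResult", "staple_fuse", "consensus_mask", "default_region"]

_EPS = 1e-6


@dataclass
class StapleResult:
    """Consensus probability field plus per-rater performance estimates."""

    consensus_prob: Volume
    sensitivities: np.ndarray  # p_j
    specificities: np.ndarray  # q_j
    n_iterations: int
    converged: bool
    prior: float
    log_likelihood: list[float]
    degenerate_raters: list[int]


def default_region(raters: list[BinaryMask], dilation: int = 5) -> BinaryMask:
    """Bounding box of the rater union, dilated by ``dilation`` voxels."""
    union = np.zeros(raters[0].shape, dtype=bool)
    for r in raters:
        union |= r.data
    region = np.zeros_like(union)
    if union.any():
        sl = ndimage.find_objects(union.astype(np.uint8))[0]
        grown = tuple(
            slice(max(s.start - dilation, 0), min(s.stop + dilation, dim))
            for s, dim in zip(sl, union.shape)
        )
        region[grown] = True
    else:
        region[:] = True
    return raters[0].with_data(region)


def staple_fuse(
    raters: list[BinaryMask],
    region: BinaryMask | None = None,
    prior: float | str = "from-raters",
    tol: float = 1e-7,
    max_iter: int = 100,
) -> StapleResult:
    """Fuse rater masks into a probabilistic consensus by EM.

    Parameters
    ----------
    raters
        At least two binary masks on a common grid.
    region
        Analysis domain (e.g. brain mask). Defaults to the dilated bounding
        box of the rater union. Voxels outside get consensus probability 0
        and are excluded from estimation.
    prior
        Global prior probability that a voxel is foreground, or
        ``"from-raters"``: the mean foreground fraction across raters over
        the region.
    tol, max_iter
        Stop when the max voxel-wise change in W drops below ``tol``, or
        after ``max_iter`` iterations.
    """
    if len(raters) < 2:
        raise ValueError("at least 2 raters required")
    for r in raters[1:]:
        require_same_grid(raters[0], r, "rater masks")
    if region is None:
        region = default_region(raters)
    else:
        require_same_grid(raters[0], region, "raters and region")
    if not region.data.any():
        raise ValueError("analysis region is empty")

    sel = region.data
    D = np.stack([r.data[sel] for r in raters]).astype(bool)  # (J, Nv)
    J, nv = D.shape

    if prior == "from-raters":
        f1 = float(D.mean())
        f1 = min(max(f1, _EPS), 1 - _EPS)
    else:
        f1 = float(prior)
        if not (0 < f1 < 1):
            raise ValueError("prior must be in (0, 1)")

    p = np.full(J, 0.99999)
    q = np.full(J, 0.99999)
    degenerate = sorted(
        {j for j in range(J) if D[j].all() or not D[j].any()}
    )

    W = np.full(nv, f1)
    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log domain)
        la = np.log(f1) + D.T @ np.log(p) + (~D).T @ np.log1p(-p)
        lb = np.log1p(-f1) + D.T @ np.log1p(-q) + (~D).T @ np.log(q)
        norm = logsumexp(np.stack([la, lb]), axis=0)
        W_new = np.exp(la - norm)
        ll_trace.append(float(norm.sum()))
        delta = float(np.max(np.abs(W_new - W)))
        W = W_new
        # M-step
        sw = W.sum()
        swc = nv - sw
        p = np.clip((D @ W) / max(sw, _EPS), _EPS, 1 - _EPS)
        q = np.clip(((~D) @ (1 - W)) / max(swc, _EPS), _EPS, 1 - _EPS)
        if delta < tol:
            converged = True
            break

    prob = np.zeros(raters[0].shape, dtype=np.float64)
    prob[sel] = W
    consensus = Volume(
        data=prob.astype(np.float32),
        spacing=raters[0].spacing,
        affine=raters[0].affine.copy(),
    )
    return StapleResult(
        consensus_prob=consensus,
        sensitivities=p,
        specificities=q,
        n_iterations=it,
        converged=converged,
        prior=f1,
        log_likelihood=ll_trace,
        degenerate_raters=degenerate,
    )


def consensus_mask(r: StapleResult, threshold: float = 0.5) -> BinaryMask:
    """Materialize the consensus: voxels with W strictly above ``threshold``."""
    return BinaryMask(
        data=r.consensus_prob.data > threshold,
        spacing=r.consensus_prob.spacing,
        affine=r.consensus_prob.affine.copy(),
    )
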