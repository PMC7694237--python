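"""STAPLE consensus over multiple binary rater masks.

Simultaneous Truth And Performance Level Estimation: an EM algorithm that
treats the unknown true segmentation as a latent voxelwise indicator and
each rater j as a noisy channel with sensitivity p_j and specificity q_j.
The E-step computes posterior truth probabilities W_i given current (p, q)
and a spatially uniform foreground prior pi; the M-step re-estimates each
rater's (p_j, q_j) from the weighted votes. The consensus ("reference")
contour is the W >= 0.5 region.

The EM runs on an explicit analysis *domain* rather than the whole grid:
including vast unanimous background drives the prior and specificities
toward degenerate values without changing the consensus inside the region
of interest. :func:`consensus_reference` builds the conventional domain —
the union of the rater masks dilated by a small margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .core import BinaryMask, GridGeometry

__all__ = ["RaterPerformance", "ConsensusResult", "run_staple", "consensus_reference"]

#: Clamp for probabilities (p_j, q_j, prior) to avoid degenerate likelihoods.
EPS = 1e-6


@dataclass(frozen=True)
class RaterPerformance:
    """Estimated sensitivity p and specificity q of one rater."""

    rater_id: str
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError("p and q must lie in [0, 1]")


@dataclass
class ConsensusResult:
    """Output of the EM: truth probabilities, per-rater performance, consensus mask."""

    weights: np.ndarray  # 3D array of W_i in [0,1]; 0 outside the domain
    performances: list[RaterPerformance]
    consensus: BinaryMask  # W >= 0.5 inside the domain
    n_iterations: int
    converged: bool
    log_likelihood_trace: list[float] = field(default_factory=list)
    degenerate: bool = False  # unanimous raters inside the domain
    prior: float = 0.5
    domain: BinaryMask | None = None


def _clamp(x: np.ndarray | float) -> np.ndarray | float:
    return np.clip(x, EPS, 1.0 - EPS)


def run_staple(
    masks: list[BinaryMask],
    domain: BinaryMask,
    prior: float | str = "rater-mean",
    tol: float = 1e-6,
    max_iter: int = 200,
    init_pq: float = 0.9999,
) -> ConsensusResult:
    """Binary STAPLE EM over ``masks`` restricted to ``domain``.

    Parameters
    ----------
    masks:
        At least two rater masks sharing one geometry.
    domain:
        Non-empty analysis region on the same geometry; voxels outside are
        excluded from the likelihood and always false in the consensus.
    prior:
        Foreground prior probability pi, or ``"rater-mean"`` to use the mean
        rater foreground fraction inside the domain.
    tol:
        Convergence threshold on max |delta p_j|, |delta q_j|.
    """
    if len(masks) < 2:
        raise ValueError("STAPLE needs at least 2 rater masks")
    geom: GridGeometry = masks[0].geometry
    for m in masks[1:]:
        if m.geometry != geom:
            raise ValueError("all rater masks must share one geometry")
    if domain.geometry != geom:
        raise ValueError("domain must share the rater geometry")
    dom = domain.values
    n_dom = int(np.count_nonzero(dom))
    if n_dom == 0:
        raise ValueError("analysis domain is empty")

    # decisions: (J raters, N domain voxels)
    D = np.stack([m.values[dom] for m in masks]).astype(np.float64)
    J, N = D.shape

    if prior == "rater-mean":
        pi = float(_clamp(D.mean()))
    else:
        pi = float(_clamp(float(prior)))
        if not (0.0 < pi < 1.0):  # pragma: no cover - clamp guarantees
            raise ValueError("prior must be a probability in (0, 1)")

    rater_ids = [f"rater{j:02d}" for j in range(J)]

    # Degenerate: every rater empty, or every rater full, inside the domain.
    all_empty = not D.any()
    all_full = bool(D.all())
    if all_empty or all_full:
        W = np.zeros(geom.shape, dtype=np.float64)
        cons = np.zeros(geom.shape, dtype=bool)
        if all_full:
            W[dom] = 1.0
            cons[dom] = True
        p = 1.0 - EPS if all_full else EPS
        q = 1.0 - EPS if all_empty else EPS
        perfs = [RaterPerformance(r, p, q) for r in rater_ids]
        return ConsensusResult(
            weights=W,
            performances=perfs,
            consensus=BinaryMask(geom, cons),
            n_iterations=0,
            converged=True,
            log_likelihood_trace=[],
            degenerate=True,
            prior=pi,
            domain=domain,
        )

    p = np.full(J, _clamp(init_pq))
    q = np.full(J, _clamp(init_pq))
    log_pi, log_1mpi = np.log(pi), np.log1p(-pi)
    ll_trace: list[float] = []
    converged = False
    W_dom = np.full(N, pi)
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: log a_i (truth=1) and log b_i (truth=0)
        log_a = log_pi + D.T @ np.log(p) + (1.0 - D).T @ np.log1p(-p)
        log_b = log_1mpi + (1.0 - D).T @ np.log(q) + D.T @ np.log1p(-q)
        W_dom = expit(log_a - log_b)
        ll_trace.append(float(np.logaddexp(log_a, log_b).sum()))

        # M-step
        sw = W_dom.sum()
        s1mw = N - sw
        p_new = _clamp((D @ W_dom) / sw)
        q_new = _clamp(((1.0 - D) @ (1.0 - W_dom)) / s1mw)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    W = np.zeros(geom.shape, dtype=np.float64)
    W[dom] = W_dom
    cons = np.zeros(geom.shape, dtype=bool)
    cons[dom] = W_dom >= 0.5  # ties toward foreground
    perfs = [RaterPerformance(r, float(pj), float(qj)) for r, pj, qj in zip(rater_ids, p, q)]
    return ConsensusResult(
        weights=W,
        performances=perfs,
        consensus=BinaryMask(geom, cons),
        n_iterations=it,
        converged=converged,
        log_likelihood_trace=ll_trace,
        degenerate=False,
        prior=pi,
        domain=domain,
    )


def union_dilated_domain(masks: list[BinaryMask], margin_voxels: int = 2) -> BinaryMask:
    """Union of the masks dilated by ``margin_voxels`` steps of 6-connectivity."""
    if not masks:
        raise ValueError("no masks given")
    geom = masks[0].geometry
    union = np.zeros(geom.shape, dtype=bool)
    for m in masks:
        if m.geometry != geom:
            raise ValueError("all masks must share one geometry")
        union |= m.values
    if margin_voxels > 0 and union.any():
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        union = ndimage.binary_dilation(union, structure=struct, iterations=margin_voxels)
    return BinaryMask(geom, union)


def consensus_reference(
    masks: list[BinaryMask],
    domain_policy: str = "union_dilated",
    margin_voxels: int = 2,
    **kwargs,
) -> ConsensusResult:
    """Build the analysis domain, then run STAPLE with a rater-mean prior.

    ``domain_policy`` is ``"union_dilated"`` (default: union of rater masks
    dilated by ``margin_voxels``) or ``"whole_grid"``.
    """
    if len(masks) < 2:
        raise ValueError("STAPLE needs at least 2 rater masks")
    if domain_policy == "union_dilated":
        domain = union_dilated_domain(masks, margin_voxels)
    elif domain_policy == "whole_grid":
        geom = masks[0].geometry
        domain = BinaryMask(geom, np.ones(geom.shape, dtype=bool))
    else:
        raise ValueError(f"unknown domain_policy {domain_policy!r}")
    if not domain.values.any():
        # all raters empty: degenerate by construction on the trivial domain
        geom = masks[0].geometry
        domain = BinaryMask(geom, np.ones(geom.shape, dtype=bool))
    return run_staple(masks, domain, prior=kwargs.pop("prior", "rater-mean"), **kwargs)
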