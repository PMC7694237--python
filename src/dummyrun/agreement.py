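"""Inter-rater agreement on voxel masks: Fleiss's kappa and Dice overlap.

Voxels inside an analysis domain are the "subjects", the two categories are
in-contour / out-of-contour, and each institution is a rater. As with the
consensus module, kappa is computed on a restricted domain by default (the
dilated union of the rater masks): a whole-grid domain inflates agreement
through the vast unanimous background, and reports must state the policy
used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinaryMask

from .staple import union_dilated_domain

__all__ = ["AgreementResult", "fleiss_kappa", "dice_coefficient", "cohort_agreement"]


@dataclass
class AgreementResult:
    """Fleiss's kappa with its ingredients.

    kappa = (P_bar - P_e) / (1 - P_e), where P_bar is the mean over subjects
    of the pairwise rater agreement and P_e the chance agreement implied by
    the marginal category proportions. If every rater is unanimous in one
    category at every voxel, P_e = 1 and the ratio is 0/0; agreement is then
    perfect and kappa is reported as 1.0 with ``degenerate`` set.
    """

    kappa: float
    mean_observed_agreement: float
    expected_agreement: float
    n_subjects: int
    n_raters: int
    category_proportions: tuple[float, float]  # (out-of-contour, in-contour)
    degenerate: bool = False
    domain_policy: str = "union_dilated"


def fleiss_kappa(
    masks: list[BinaryMask],
    domain: BinaryMask,
    domain_policy: str = "explicit",
) -> AgreementResult:
    """Fleiss's kappa over the voxels of ``domain`` for n >= 2 binary raters."""
    n = len(masks)
    if n < 2:
        raise ValueError("Fleiss's kappa needs at least 2 raters")
    geom = masks[0].geometry
    for m in masks[1:]:
        if m.geometry != geom:
            raise ValueError("all rater masks must share one geometry")
    if domain.geometry != geom:
        raise ValueError("domain must share the rater geometry")
    dom = domain.values
    N = int(np.count_nonzero(dom))
    if N == 0:
        raise ValueError("empty kappa domain")

    votes = np.zeros(N, dtype=np.int64)  # n_i1: raters voting in-contour
    for m in masks:
        votes += m.values[dom]
    n_i1 = votes
    n_i0 = n - votes
    # P_i = [sum_c n_ic^2 - n] / [n (n-1)]
    P_i = (n_i1.astype(np.float64) ** 2 + n_i0.astype(np.float64) ** 2 - n) / (n * (n - 1))
    P_bar = float(P_i.mean())
    p1 = float(n_i1.sum()) / (N * n)
    p0 = 1.0 - p1
    P_e = p0 * p0 + p1 * p1
    if P_e >= 1.0 - 1e-15:
        return AgreementResult(1.0, P_bar, P_e, N, n, (p0, p1), degenerate=True,
                               domain_policy=domain_policy)
    kappa = (P_bar - P_e) / (1.0 - P_e)
    return AgreementResult(float(kappa), P_bar, float(P_e), N, n, (p0, p1),
                           domain_policy=domain_policy)


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); both-empty is an error."""
    if a.geometry != b.geometry:
        raise ValueError("Dice requires a common geometry")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def cohort_agreement(
    masks: dict[str, BinaryMask],
    reference: BinaryMask,
    domain: BinaryMask | None = None,
    domain_margin_voxels: int = 2,
) -> tuple[pd.DataFrame, AgreementResult]:
    """Per-institution Dice vs the reference, plus one Fleiss kappa over all raters.

    Parameters
    ----------
    masks:
        institution_id -> mask, at least two institutions.
    reference:
        The consensus mask each institutional mask is compared against.
    domain:
        Kappa domain; defaults to the union of institutional masks dilated by
        ``domain_margin_voxels`` (the same policy the consensus module uses).

    Returns
    -------
    (table, kappa) where ``table`` has one row per institution plus
    median/min/max summary rows.
    """
    if len(masks) < 2:
        raise ValueError("cohort agreement needs at least 2 institutions")
    rater_list = [masks[k] for k in sorted(masks)]
    policy = "explicit"
    if domain is None:
        domain = union_dilated_domain(rater_list, domain_margin_voxels)
        policy = "union_dilated"
    kappa = fleiss_kappa(rater_list, domain, domain_policy=policy)

    rows = [
        {"institution_id": inst, "dsc": dice_coefficient(masks[inst], reference)}
        for inst in sorted(masks)
    ]
    table = pd.DataFrame(rows)
    dsc = table["dsc"].to_numpy()
    summary = pd.DataFrame(
        [
            {"institution_id": "median", "dsc": float(np.median(dsc))},
            {"institution_id": "min", "dsc": float(dsc.min())},
            {"institution_id": "max", "dsc": float(dsc.max())},
        ]
    )
    return pd.concat([table, summary], ignore_index=True), kappa
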