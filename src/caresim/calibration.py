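"""Prevalence-threshold search shared by the dementia and frailty modules.

Modelled prevalence ``P(theta) = #{p_i >= theta} / n`` is a right-continuous
step function of the cutoff, so the search is performed directly on the
order statistics of the predicted probabilities: the cutoff matching a
target share ``pi`` is the ``round(pi * n)``-th largest probability.  This
is the exact fixed point that interval bisection on theta converges to, and
it agrees with a sort-based oracle by construction, to person granularity.
"""

from __future__ import annotations

import numpy as np

from .errors import CalibrationError

__all__ = ["threshold_for_prevalence"]


def _achieved(values: np.ndarray, theta: float, denom: int) -> float:
    return float(np.count_nonzero(values >= theta) / denom)


def threshold_for_prevalence(
    values,
    target: float,
    tol: float = 1e-4,
    denominator: int | None = None,
) -> tuple[float, float]:
    """Find the cutoff whose labelled share matches ``target``.

    Parameters
    ----------
    values : array-like
        Predicted probabilities of the persons eligible for the label.
    target : float
        Target share, measured against ``denominator`` persons.
    tol : float
        Acceptable absolute deviation of the achieved share, in addition to
        the unavoidable one-person granularity ``1/denominator``.
    denominator : int, optional
        Population size the share refers to; defaults to ``len(values)``.
        (Used when the eligible set is a subset of the population, e.g. the
        mild-cognitive-impairment label among persons not classified as
        having dementia.)

    Returns
    -------
    (theta, achieved) : tuple of float
        The cutoff and the share actually labelled at it.

    Raises
    ------
    CalibrationError
        If the target lies outside [0, 1] or no cutoff attains it within
        ``max(tol, 1/denominator)`` (e.g. heavy ties, or a target above the
        attainable maximum).
    """
    values = np.asarray(values, dtype=float)
    denom = int(denominator) if denominator is not None else len(values)
    if denom <= 0:
        raise CalibrationError("empty population")
    if not 0.0 <= target <= 1.0:
        raise CalibrationError(f"target prevalence {target} outside [0, 1]")

    k = int(round(target * denom))
    if k > len(values):
        raise CalibrationError(
            f"target prevalence {target:.6g} unattainable: only "
            f"{len(values)} eligible persons of {denom} "
            f"(attainable range 0..{len(values) / denom:.6g})"
        )
    if k == 0:
        theta = 1.0
        achieved = _achieved(values, theta, denom)
    else:
        order = np.sort(values)[::-1]
        theta = float(order[k - 1])
        achieved = _achieved(values, theta, denom)

    slack = max(tol, 1.0 / denom)
    if abs(achieved - target) > slack:
        # ties make some shares unattainable; snap to the nearest attainable
        distinct = np.unique(values)[::-1]
        shares = np.array([_achieved(values, v, denom) for v in distinct])
        i = int(np.argmin(np.abs(shares - target)))
        theta, achieved = float(distinct[i]), float(shares[i])
        if abs(achieved - target) > slack:
            raise CalibrationError(
                f"target prevalence {target:.6g} unattainable within "
                f"{slack:.2g}; nearest achievable {achieved:.6g} "
                f"(attainable range {shares.min():.6g}..{shares.max():.6g})"
            )
    return float(theta), float(achieved)
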