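"""Biologically effective dose (BED) arithmetic for the linear-quadratic model.

The BED of a fractionation scheme delivering ``n`` fractions of ``d`` Gy to a
tissue with fraction-size sensitivity ``alpha_beta`` (the alpha/beta ratio,
in Gy) is

    BED = n * d * (1 + d / alpha_beta)

and the BED of a multi-phase course is the sum of the per-phase BEDs,
provided all phases address the same tissue (same alpha/beta).  Matching the
total BED at alpha/beta = 2 Gy (the value recommended for central-nervous-
system re-irradiation) between a candidate schedule and a reference regimen
is how isotoxicity is enforced throughout this package; alpha/beta = 10 Gy
is used for the tumor-dose covariate in the trial analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

#: alpha/beta ratio used for normal-tissue isotoxicity (CNS re-irradiation).
ALPHA_BETA_CNS = 2.0
#: alpha/beta ratio used for the tumor-BED covariate.
ALPHA_BETA_TUMOR = 10.0


class BEDError(ValueError):
    """Invalid input to a BED computation."""


@dataclass(frozen=True)
class BEDSpec:
    """A (fraction count, dose per fraction, alpha/beta) triple.

    Parameters
    ----------
    n : int
        Number of fractions, >= 1.
    d : float
        Dose per fraction in Gy, > 0.
    alpha_beta : float
        Tissue alpha/beta ratio in Gy, > 0.
    """

    n: int
    d: float
    alpha_beta: float = ALPHA_BETA_CNS

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise BEDError(f"fraction count must be a positive integer, got {self.n}")
        if self.d <= 0:
            raise BEDError(f"dose per fraction must be positive, got {self.d}")
        if self.alpha_beta <= 0:
            raise BEDError(f"alpha/beta must be positive, got {self.alpha_beta}")

    @property
    def value(self) -> float:
        """BED in Gy."""
        return bed_single(self.n, self.d, self.alpha_beta)


def bed_single(n: int, d: float, alpha_beta: float = ALPHA_BETA_CNS) -> float:
    """BED of a single uniform phase: ``n * d * (1 + d / alpha_beta)``, in Gy."""
    if n < 1 or int(n) != n:
        raise BEDError(f"fraction count must be a positive integer, got {n}")
    if d <= 0:
        raise BEDError(f"dose per fraction must be positive, got {d}")
    if alpha_beta <= 0:
        raise BEDError(f"alpha/beta must be positive, got {alpha_beta}")
    return n * d * (1.0 + d / alpha_beta)


def bed_total(specs: Sequence[BEDSpec] | Iterable[BEDSpec]) -> float:
    """Total BED of a multi-phase course (sum of per-phase BEDs).

    All phases must share the same alpha/beta ratio: BEDs computed for
    distinct tissues are not commensurable and must not be summed.
    """
    specs = list(specs)
    if not specs:
        return 0.0
    ab = specs[0].alpha_beta
    for s in specs:
        if s.alpha_beta != ab:
            raise BEDError(
                "all phases must share one alpha/beta ratio; "
                f"got {s.alpha_beta} and {ab}"
            )
    return sum(s.value for s in specs)


def solve_dose_per_fraction(
    n: int, target_bed: float, alpha_beta: float = ALPHA_BETA_CNS
) -> float:
    """Dose per fraction making ``n`` fractions reach ``target_bed``.

    Inverts the BED formula; the unique positive root of
    ``n*d*(1 + d/ab) = target_bed`` is

        d = (ab / 2) * (-1 + sqrt(1 + 4 * target_bed / (n * ab)))
    """
    if n < 1 or int(n) != n:
        raise BEDError(f"fraction count must be a positive integer, got {n}")
    if target_bed <= 0:
        raise BEDError(f"target BED must be positive, got {target_bed}")
    if alpha_beta <= 0:
        raise BEDError(f"alpha/beta must be positive, got {alpha_beta}")
    return 0.5 * alpha_beta * (-1.0 + math.sqrt(1.0 + 4.0 * target_bed / (n * alpha_beta)))


#: Named reference regimens as (n fractions, dose per fraction in Gy).
REFERENCE_REGIMENS: dict[str, tuple[int, float]] = {
    # Commonly used recurrent-GBM re-irradiation course: 35 Gy in 10 daily fx.
    "standard_reirradiation": (10, 3.5),
}


def reference_bed(label: str = "standard_reirradiation", alpha_beta: float = ALPHA_BETA_CNS) -> float:
    """BED of a named reference regimen at the requested alpha/beta."""
    try:
        n, d = REFERENCE_REGIMENS[label]
    except KeyError:
        raise KeyError(
            f"unknown reference regimen {label!r}; known: {sorted(REFERENCE_REGIMENS)}"
        ) from None
    return bed_single(n, d, alpha_beta)
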