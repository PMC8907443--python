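"""Biologically effective dose (BED) timelines and imaging-level selection.

BED aligns different fractionation schemes on a common radiobiological
scale via the linear-quadratic formula ``BED = n * d * (1 + d / (alpha/beta))``.
Imaging timepoints are chosen as the treatment fractions at which cumulative
BED reaches (or comes closest to) a set of target levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Cumulative BED levels (Gy) at which follow-up images are selected.
DEFAULT_TARGET_LEVELS: tuple[float, ...] = (13.0, 26.0, 40.0, 54.0, 67.0)

#: Default alpha/beta ratio (Gy) for tumor tissue.
DEFAULT_ALPHA_BETA: float = 10.0


def bed_total(n: int, d: float, alpha_beta: float = DEFAULT_ALPHA_BETA) -> float:
    """Total BED after ``n`` fractions of ``d`` Gy each.

    Parameters
    ----------
    n : int
        Number of fractions delivered (>= 0).
    d : float
        Physical dose per fraction in Gy (> 0).
    alpha_beta : float
        Tissue alpha/beta ratio in Gy (> 0).

    Returns
    -------
    float
        ``n * d * (1 + d / alpha_beta)`` in Gy; linear in ``n`` for fixed ``d``.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if d <= 0:
        raise ValueError(f"dose per fraction must be > 0, got {d}")
    if alpha_beta <= 0:
        raise ValueError(f"alpha/beta must be > 0, got {alpha_beta}")
    return n * d * (1.0 + d / alpha_beta)


@dataclass(frozen=True)
class FractionationScheme:
    """A uniform fractionation scheme for the analyzed target volume.

    For simultaneous-integrated-boost plans, ``dose_per_fraction`` is the
    prescription dose per fraction to the analyzed ROI (the GTV).
    """

    dose_per_fraction: float
    n_fractions_total: int
    alpha_beta: float = DEFAULT_ALPHA_BETA
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose_per_fraction <= 0:
            raise ValueError("dose_per_fraction must be > 0")
        if self.n_fractions_total < 1:
            raise ValueError("n_fractions_total must be >= 1")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")

    def cumulative_bed(self) -> np.ndarray:
        """Cumulative BED (Gy) after fractions ``1..n_fractions_total``."""
        k = np.arange(1, self.n_fractions_total + 1)
        return k * self.dose_per_fraction * (1.0 + self.dose_per_fraction / self.alpha_beta)

    def total_bed(self) -> float:
        return bed_total(self.n_fractions_total, self.dose_per_fraction, self.alpha_beta)


def fraction_for_level(
    scheme: FractionationScheme, level: float, rule: str = "nearest"
) -> int:
    """Fraction number (1-based) at which cumulative BED matches ``level``.

    ``rule='first_reaching'`` returns the smallest k with cumulative
    BED(k) >= level and raises if the level is never reached.
    ``rule='nearest'`` returns the k minimizing |BED(k) - level|
    (ties broken toward the smaller k).
    """
    if level <= 0:
        raise ValueError(f"level must be > 0, got {level}")
    cum = scheme.cumulative_bed()
    if rule == "first_reaching":
        reached = np.nonzero(cum >= level)[0]
        if reached.size == 0:
            raise ValueError(
                f"BED level {level} Gy never reached (total {cum[-1]:.2f} Gy)"
            )
        return int(reached[0]) + 1
    if rule == "nearest":
        return int(np.argmin(np.abs(cum - level))) + 1
    raise ValueError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class BedTimeline:
    """Per-fraction cumulative BED plus the fraction chosen for each level."""

    cumulative: tuple[float, ...]
    target_levels: tuple[float, ...]
    level_to_fraction: dict[float, int] = field(compare=False)

    @property
    def imaging_fractions(self) -> tuple[int, ...]:
        return tuple(self.level_to_fraction[lv] for lv in self.target_levels)


def build_timeline(
    scheme: FractionationScheme,
    target_levels: tuple[float, ...] = DEFAULT_TARGET_LEVELS,
    rule: str = "nearest",
) -> BedTimeline:
    """Map each target BED level to a treatment fraction.

    Raises if the mapped fractions are not strictly increasing across
    levels (i.e. two levels would share an imaging session).
    """
    levels = tuple(sorted(target_levels))
    fracs = [fraction_for_level(scheme, lv, rule=rule) for lv in levels]
    if any(b <= a for a, b in zip(fracs, fracs[1:])):
        raise ValueError(
            f"fractions mapped to levels {levels} are not strictly increasing: {fracs}"
        )
    return BedTimeline(
        cumulative=tuple(float(x) for x in scheme.cumulative_bed()),
        target_levels=levels,
        level_to_fraction=dict(zip(levels, fracs)),
    )
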