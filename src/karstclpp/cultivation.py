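"""Viable-count quantification from serial-dilution plating.

Colony counts on plates at dilution 10^-d convert to suspension
concentration as ``count * 10**d / volume_plated`` (CFU/mL); the per-gram
dry-mass value follows from the suspension volume and the sediment's dry
mass, ``cfu/mL * suspension_volume / (wet_mass * dry_mass_fraction)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import DilutionCount, ValidationError


@dataclass(frozen=True)
class CfuResult:
    """Mean and SD of CFU per gram dry mass over replicate plates.

    ``sd_cfu_per_g_dm`` is the sample SD (n-1) across replicate-level
    estimates; it is None for a single replicate. The SD is across plating
    replicates of one dilution record.
    """

    sample_id: str
    medium: str
    condition: str
    mean_cfu_per_g_dm: float
    sd_cfu_per_g_dm: float | None
    n_replicates: int


def cfu_per_g_dm(
    rec: DilutionCount,
    countable_range: tuple[int, int] | None = None,
) -> CfuResult:
    """Colony-forming units per gram of dry sediment from one dilution record.

    Each replicate plate yields a suspension concentration
    ``count * 10**d / volume_plated`` (CFU/mL), converted to a per-gram
    dry-mass estimate via the suspension volume and dry mass; the mean and
    sample SD are taken over replicate-level estimates.

    ``countable_range=(lo, hi)`` optionally restricts to plates with lo <=
    count <= hi (no restriction by default).
    """
    counts = np.asarray(rec.counts, dtype=float)
    if countable_range is not None:
        lo, hi = countable_range
        counts = counts[(counts >= lo) & (counts <= hi)]
        if len(counts) == 0:
            raise ValidationError(
                f"no replicate count within countable range [{lo}, {hi}]"
            )
    conc_per_ml = counts * 10.0 ** rec.dilution_exponent / rec.volume_plated_ml
    dry_mass_g = rec.wet_mass_g * rec.dry_mass_fraction
    per_g = conc_per_ml * rec.suspension_volume_ml / dry_mass_g
    sd = float(np.std(per_g, ddof=1)) if len(per_g) > 1 else None
    return CfuResult(
        sample_id=rec.sample_id, medium=rec.medium, condition=rec.condition,
        mean_cfu_per_g_dm=float(np.mean(per_g)),
        sd_cfu_per_g_dm=sd, n_replicates=len(per_g),
    )


def dilution_for_target_cfu(
    stock_cfu_per_ml: float, target_cfu: float, inoculum_volume_ml: float
) -> float:
    """Dilution factor f so that ``stock / f * volume == target`` CFU per
    well (inoculum standardization, e.g. ~150 CFU per EcoPlate well).

    If the stock is already at or below the target density, no dilution is
    possible: returns 1 with a warning.
    """
    for name, v in (("stock", stock_cfu_per_ml), ("target", target_cfu),
                    ("inoculum volume", inoculum_volume_ml)):
        if not v > 0:
            raise ValidationError(f"{name} must be > 0")
    f = stock_cfu_per_ml * inoculum_volume_ml / target_cfu
    if f < 1:
        warnings.warn(
            "stock is below the target density; no dilution applied",
            stacklevel=2,
        )
        return 1.0
    return f
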