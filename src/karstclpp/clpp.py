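"""Community-level physiological profiling statistics for EcoPlate reads.

A community's carbon-source utilization pattern is summarized by two
statistics computed from blank- and turbidity-corrected well responses R:

* AMR (average metabolic response, equivalently AWCD) — the mean response
  over the 31 carbon sources, ``AMR = sum(R_i) / 31``;
* CMD (community metabolic diversity, functional richness) — the number of
  carbon sources whose response strictly exceeds a positivity threshold
  (0.400 OD by default), also expressed as a percentage of 31.

Responses are derived from raw reads in two correction steps, each floored
at zero: 590 nm minus 750 nm (turbidity), then substrate well minus the
water-control well of the same replicate block (blank). Replicate blocks are
averaged after per-block blank subtraction, so block-level offsets cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    CultivationCondition,
    N_SUBSTRATES,
    PlateLayout,
    PlateSeries,
    ValidationError,
    logical_to_physical,
)

DEFAULT_THRESHOLD = 0.400


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (matches how the endpoint
    percentages are printed)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def correct_turbidity(od590, od750):
    """Turbidity-corrected OD: 590 nm minus 750 nm, floored at zero.

    Accepts scalars or aligned arrays/Series.
    """
    od590 = np.asarray(od590, dtype=float)
    od750 = np.asarray(od750, dtype=float)
    if (od590 < 0).any() or (od750 < 0).any():
        raise ValidationError("ODs must be non-negative")
    out = np.maximum(od590 - od750, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class SubstrateProfile:
    """Blank- and turbidity-corrected responses for the 31 carbon sources of
    one sample at one timepoint, averaged over the replicate blocks present.
    """

    sample_id: str
    condition: CultivationCondition
    time_h: float
    responses: pd.Series  # indexed by logical position, 31 entries
    layout: PlateLayout

    def __post_init__(self) -> None:
        expected = self.layout.substrate_positions
        if list(self.responses.index) != expected:
            if set(self.responses.index) == set(expected):
                self.responses = self.responses.reindex(expected)
            else:
                raise ValidationError(
                    f"profile must cover exactly the {N_SUBSTRATES} substrate "
                    f"positions"
                )
        if (self.responses < 0).any():
            raise ValidationError("responses must be >= 0")

    def named_responses(self) -> pd.Series:
        """Responses indexed by substrate name instead of position."""
        names = [self.layout.substrate_name(p) for p in self.responses.index]
        return pd.Series(self.responses.to_numpy(), index=names)


def substrate_profile(
    series: PlateSeries, time_h: float, threshold_on: str = "response"
) -> SubstrateProfile:
    """Per-substrate responses at one recorded timepoint.

    For each replicate block present, the substrate response is the
    turbidity-corrected substrate well minus the turbidity-corrected water
    control of the same block, floored at zero; responses are then averaged
    across blocks.

    ``threshold_on='raw590'`` skips both corrections and returns the raw
    590 nm reads averaged across blocks (for sensitivity analyses of where
    the positivity threshold is applied).
    """
    times = series.times_h
    if time_h not in times:
        raise ValidationError(
            f"t={time_h} not recorded; available times: {times.tolist()}"
        )
    od590 = series.od(590, time_h)
    od750 = series.od(750, time_h)
    layout = series.layout
    per_block = []
    for block in series.blocks_present:
        control_well = logical_to_physical(block, layout.control_position)
        if control_well not in od590.index:
            raise ValidationError(
                f"control well {control_well} missing in block {block}"
            )
        if threshold_on == "raw590":
            control = 0.0
            corrected = od590
        else:
            corrected = pd.Series(
                correct_turbidity(od590.to_numpy(), od750.reindex(od590.index).to_numpy()),
                index=od590.index,
            )
            control = corrected[control_well]
        block_resp = {}
        for pos in layout.substrate_positions:
            well = logical_to_physical(block, pos)
            if well not in corrected.index:
                continue
            block_resp[pos] = max(corrected[well] - control, 0.0)
        if len(block_resp) != N_SUBSTRATES:
            missing = set(layout.substrate_positions) - set(block_resp)
            raise ValidationError(
                f"block {block} lacks substrate wells {sorted(missing)}"
            )
        per_block.append(pd.Series(block_resp))
    responses = pd.concat(per_block, axis=1).mean(axis=1)
    responses = responses.reindex(layout.substrate_positions)
    return SubstrateProfile(
        sample_id=series.sample_id, condition=series.condition,
        time_h=float(time_h), responses=responses, layout=layout,
    )


def amr(profile: SubstrateProfile) -> float:
    """Average metabolic response: sum of the 31 responses divided by 31."""
    return float(profile.responses.sum() / N_SUBSTRATES)


def cmd(
    profile: SubstrateProfile, threshold: float = DEFAULT_THRESHOLD
) -> tuple[int, float]:
    """Community metabolic diversity.

    Returns ``(count, percent)``: the number of substrates whose response is
    strictly above ``threshold``, and that count as a percentage of 31
    rounded half-up to one decimal.
    """
    if not threshold > 0:
        raise ValidationError("threshold must be > 0")
    count = int((profile.responses > threshold).sum())
    return count, cmd_percent(count)


def cmd_percent(count: int) -> float:
    """Map a positive-substrate count (0-31) to a percentage of 31."""
    if not 0 <= count <= N_SUBSTRATES:
        raise ValidationError(f"count must be in [0, {N_SUBSTRATES}]")
    return round_half_up(100.0 * count / N_SUBSTRATES, 1)


@dataclass
class ClppMetrics:
    """AMR/CMD time course for one plate, with the condition's phase
    boundaries so per-phase endpoint statistics are retrievable."""

    sample_id: str
    condition: CultivationCondition
    table: pd.DataFrame  # index time_h; columns amr, cmd_count, cmd_percent

    @property
    def phase_boundaries_h(self) -> tuple[float, ...]:
        return self.condition.phase_boundaries_h

    def phase_endpoints(self) -> pd.DataFrame:
        """The last recorded reading at or before the end of each phase."""
        rows = []
        times = self.table.index.to_numpy(dtype=float)
        for i, (phase, end) in enumerate(
            zip(self.condition.phases, self.phase_boundaries_h)
        ):
            eligible = times[times <= end]
            if len(eligible) == 0:
                continue
            t = eligible.max()
            row = self.table.loc[t]
            rows.append({
                "phase": i, "oxygen": phase.oxygen, "end_h": end, "time_h": t,
                "amr": row["amr"], "cmd_count": int(row["cmd_count"]),
                "cmd_percent": row["cmd_percent"],
            })
        return pd.DataFrame(rows)


def clpp_timecourse(
    series: PlateSeries, threshold: float = DEFAULT_THRESHOLD,
    threshold_on: str = "response",
) -> ClppMetrics:
    """AMR and CMD at every recorded timepoint of a plate series."""
    rows = []
    for t in series.times_h:
        prof = substrate_profile(series, t, threshold_on=threshold_on)
        count, percent = cmd(prof, threshold)
        rows.append({
            "time_h": t, "amr": amr(prof), "cmd_count": count,
            "cmd_percent": percent,
        })
    table = pd.DataFrame(rows).set_index("time_h")
    return ClppMetrics(sample_id=series.sample_id, condition=series.condition,
                       table=table)


def substrate_prevalence(
    profiles: Sequence[SubstrateProfile],
    threshold: float = DEFAULT_THRESHOLD,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Across-sample prevalence of substrate utilization.

    For each carbon source, the fraction of profiles whose response strictly
    exceeds ``threshold``; sources metabolized by strictly less than
    ``cutoff`` of the samples are flagged (these are the "metabolized by
    fewer than half the samples" substrates).

    Returns a frame indexed by logical position with columns ``substrate,
    n_positive, fraction, flagged``.
    """
    if len(profiles) == 0:
        raise ValidationError("at least one profile required")
    layouts = {id(p.layout): p.layout for p in profiles}
    maps = {frozenset(p.layout.substrate_map.items()) for p in profiles}
    if len(maps) > 1:
        raise ValidationError("profiles have mixed plate layouts")
    layout = profiles[0].layout
    positive = pd.DataFrame(
        {p.sample_id + f"@{i}": (p.responses > threshold)
         for i, p in enumerate(profiles)}
    )
    n_positive = positive.sum(axis=1).astype(int)
    fraction = n_positive / len(profiles)
    return pd.DataFrame({
        "substrate": [layout.substrate_name(pos) for pos in n_positive.index],
        "n_positive": n_positive,
        "fraction": fraction,
        "flagged": fraction < cutoff,
    })
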