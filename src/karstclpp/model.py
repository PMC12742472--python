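"""Domain types for EcoPlate CLPP, OTU, geochemistry, and plate-count data.

The central objects are:

* :class:`PlateLayout` — the logical geometry of a Biolog EcoPlate: 31 carbon
  sources plus a water control (A1), replicated in three 4-column blocks
  across a 96-well plate.
* :class:`PlateSeries` — dual-wavelength (590/750 nm) optical-density time
  series for one inoculated plate under one cultivation condition.
* :class:`CultivationCondition` — temperature, oxygen-phase schedule, and
  reading interval.
* :class:`OtuTable` — integer taxon-by-sample count matrix.
* :class:`EnvTable` — physicochemical sample table with units, detection-limit
  censoring, and optional regulatory limits.
* :class:`DilutionCount` — serial-dilution plate-count record for CFU
  quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROW_LABELS = "ABCDEFGH"
N_SUBSTRATES = 31
CONTROL_POSITION = "A1"
WAVELENGTHS = (590, 750)

AEROBIC = "aerobic"
ANAEROBIC = "anaerobic"


class ValidationError(ValueError):
    """An input object violates a structural contract."""


class ParseError(ValueError):
    """A file cell could not be interpreted; message carries coordinates."""


def logical_positions() -> list[str]:
    """All 32 logical EcoPlate positions A1..H4 (row-major)."""
    return [f"{r}{c}" for r in ROW_LABELS for c in range(1, 5)]


def physical_to_logical(well: str) -> tuple[int, str]:
    """Map a physical well label (e.g. ``B7``) to (block, logical position).

    Physical columns 1-4, 5-8, 9-12 are replicate blocks 0, 1, 2; within a
    block the logical column is 1-4, so ``B7`` is block 1, position ``B3``.
    """
    well = well.strip()
    if len(well) < 2 or well[0] not in ROW_LABELS:
        raise ValidationError(f"unknown well label {well!r}")
    try:
        col = int(well[1:])
    except ValueError:
        raise ValidationError(f"unknown well label {well!r}") from None
    if not 1 <= col <= 12:
        raise ValidationError(f"unknown well label {well!r}: column out of range")
    block, in_block = divmod(col - 1, 4)
    return block, f"{well[0]}{in_block + 1}"


def logical_to_physical(block: int, position: str) -> str:
    """Inverse of :func:`physical_to_logical`."""
    if block not in (0, 1, 2):
        raise ValidationError(f"block must be 0, 1, or 2, got {block}")
    row, col = position[0], int(position[1:])
    if row not in ROW_LABELS or not 1 <= col <= 4:
        raise ValidationError(f"invalid logical position {position!r}")
    return f"{row}{4 * block + col}"


@dataclass(frozen=True)
class PlateLayout:
    """Substrate registry for the 32 logical positions of an EcoPlate.

    ``substrate_map`` maps every logical position to a substrate name; the
    control position (A1 by default) maps to the water blank.
    """

    substrate_map: Mapping[str, str]
    control_position: str = CONTROL_POSITION

    def __post_init__(self) -> None:
        positions = set(self.substrate_map)
        expected = set(logical_positions())
        if positions != expected:
            missing = sorted(expected - positions)
            extra = sorted(positions - expected)
            raise ValidationError(
                f"substrate map must cover exactly the 32 logical positions; "
                f"missing={missing} extra={extra}"
            )
        if self.control_position not in positions:
            raise ValidationError(
                f"control position {self.control_position!r} not in layout"
            )

    @property
    def substrate_positions(self) -> list[str]:
        """The 31 carbon-source positions, row-major order."""
        return [p for p in logical_positions() if p != self.control_position]

    def substrate_name(self, position: str) -> str:
        return self.substrate_map[position]


@dataclass(frozen=True)
class Phase:
    oxygen: str
    duration_h: float

    def __post_init__(self) -> None:
        if self.oxygen not in (AEROBIC, ANAEROBIC):
            raise ValidationError(f"oxygen must be aerobic/anaerobic, got {self.oxygen!r}")
        if not self.duration_h > 0:
            raise ValidationError("phase duration must be > 0")


@dataclass(frozen=True)
class CultivationCondition:
    """Temperature, ordered oxygen phases, and plate-reading interval.

    Anaerobic incubations are typically followed by an aerobic phase on the
    same plate; the schedule is an ordered list of phases with durations in
    hours.
    """

    temperature_c: float
    phases: tuple[Phase, ...]
    reading_interval_h: float

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValidationError("at least one cultivation phase required")
        if not self.reading_interval_h > 0:
            raise ValidationError("reading interval must be > 0")

    @property
    def total_duration_h(self) -> float:
        return float(sum(p.duration_h for p in self.phases))

    @property
    def phase_boundaries_h(self) -> tuple[float, ...]:
        """Cumulative end times of each phase."""
        return tuple(np.cumsum([p.duration_h for p in self.phases]).tolist())

    def phase_at(self, time_h: float) -> Phase:
        """The phase in effect at ``time_h`` (boundary times belong to the
        ending phase, so the endpoint read of a phase is attributed to it)."""
        for phase, end in zip(self.phases, self.phase_boundaries_h):
            if time_h <= end:
                return phase
        return self.phases[-1]

    def reading_times_h(self) -> np.ndarray:
        """Scheduled read times: 0, interval, 2*interval, ... up to the total
        cultivation time."""
        n = int(round(self.total_duration_h / self.reading_interval_h))
        return np.arange(0, n + 1) * self.reading_interval_h

    def label(self) -> str:
        ox = "-".join(p.oxygen for p in self.phases)
        return f"{self.temperature_c:g}C_{ox}"


def standard_conditions() -> dict[str, CultivationCondition]:
    """The study's cultivation schedule: aerobic and anaerobic-then-aerobic
    regimes at 10/20/30 °C, read every 48 h at 10 °C and every 12 h otherwise.
    """
    return {
        "10C_aerobic": CultivationCondition(10, (Phase(AEROBIC, 336),), 48),
        "10C_anaerobic_aerobic": CultivationCondition(
            10, (Phase(ANAEROBIC, 672), Phase(AEROBIC, 672)), 48
        ),
        "20C_aerobic": CultivationCondition(20, (Phase(AEROBIC, 336),), 12),
        "20C_anaerobic_aerobic": CultivationCondition(
            20, (Phase(ANAEROBIC, 348), Phase(AEROBIC, 324)), 12
        ),
        "30C_aerobic": CultivationCondition(30, (Phase(AEROBIC, 168),), 12),
        "30C_anaerobic_aerobic": CultivationCondition(
            30, (Phase(ANAEROBIC, 180), Phase(AEROBIC, 168)), 12
        ),
    }


@dataclass
class PlateSeries:
    """Dual-wavelength OD readings for one plate.

    ``data`` is long-format with columns ``well, wavelength_nm, time_h, od``.
    Every (well, time) pair must be read at both 590 and 750 nm; times must be
    strictly increasing; ODs non-negative. One to three replicate blocks may
    be present, but block membership must be consistent across wells.
    """

    sample_id: str
    condition: CultivationCondition
    layout: PlateLayout
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "wavelength_nm", "time_h", "od"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"plate data needs columns {sorted(required)}")
        d = self.data
        if (d["od"] < 0).any():
            bad = d.loc[d["od"] < 0].iloc[0]
            raise ValidationError(
                f"negative OD at well {bad['well']} t={bad['time_h']}"
            )
        unknown = set(d["wavelength_nm"]) - set(WAVELENGTHS)
        if unknown:
            raise ValidationError(f"unknown wavelengths {sorted(unknown)}")
        for w in d["well"].unique():
            physical_to_logical(w)  # raises on bad labels
        times = np.asarray(sorted(d["time_h"].unique()), dtype=float)
        if len(times) == 0:
            raise ValidationError("plate series has no readings")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        # both wavelengths at every (well, time)
        pivot = d.pivot_table(
            index=["well", "time_h"], columns="wavelength_nm", values="od",
            aggfunc="count",
        )
        for wl in WAVELENGTHS:
            if wl not in pivot.columns:
                some = pivot.index[0]
                raise ValidationError(
                    f"missing {wl} nm reading for well {some[0]} at t={some[1]}"
                )
            missing = pivot[pivot[wl].isna()]
            if len(missing):
                well, t = missing.index[0]
                raise ValidationError(
                    f"missing {wl} nm reading for well {well} at t={t}"
                )
        dup = pivot.to_numpy() > 1
        if dup.any():
            well, t = pivot.index[int(np.argwhere(dup)[0][0])]
            raise ValidationError(f"duplicate reading for well {well} at t={t}")

    @property
    def times_h(self) -> np.ndarray:
        return np.asarray(sorted(self.data["time_h"].unique()), dtype=float)

    @property
    def blocks_present(self) -> tuple[int, ...]:
        blocks = {physical_to_logical(w)[0] for w in self.data["well"].unique()}
        return tuple(sorted(blocks))

    def od(self, wavelength_nm: int, time_h: float) -> pd.Series:
        """ODs at one wavelength and time, indexed by physical well."""
        d = self.data
        sel = d[(d["wavelength_nm"] == wavelength_nm) & (d["time_h"] == time_h)]
        if sel.empty:
            raise ValidationError(
                f"no reading at t={time_h}; available times: "
                f"{self.times_h.tolist()}"
            )
        return sel.set_index("well")["od"]


@dataclass
class OtuTable:
    """Genus-level OTU counts, taxa (rows) by samples (columns).

    Counts are validated to be non-negative integers; taxon and sample labels
    must be unique.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon labels: {dups}")
        if c.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        self.counts = c.astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self, percent: bool = True) -> pd.DataFrame:
        rel = self.counts / self.counts.sum(axis=0)
        return rel * 100.0 if percent else rel


@dataclass
class EnvTable:
    """Physicochemical sample table.

    ``values`` is parameters (rows) by samples (columns); censored cells
    ("<x" in the source file) carry their detection limit x in ``values`` and
    True in ``censored``.  ``units`` and optional ``regulatory_limit`` are
    per-parameter; ``comparison`` optionally holds a reference profile from
    another site that is not part of the sample set.
    """

    values: pd.DataFrame
    units: pd.Series
    censored: pd.DataFrame
    regulatory_limit: pd.Series | None = None
    comparison: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.censored.index) or not (
            self.values.columns.equals(self.censored.columns)
        ):
            raise ValidationError("values and censored must be aligned")
        if not self.values.index.equals(self.units.index):
            raise ValidationError("units must cover every parameter")
        if self.censored.to_numpy().any():
            lim = self.values.to_numpy()[self.censored.to_numpy()]
            if np.isnan(lim).any():
                raise ValidationError("censored cells must store their limit")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def parameters(self) -> list[str]:
        return list(self.values.index)

    def substituted(self, policy: str = "half_limit") -> pd.DataFrame:
        """Numeric matrix with censored cells replaced per policy:
        ``half_limit`` → x/2, ``zero`` → 0, ``limit`` → x."""
        factors = {"half_limit": 0.5, "zero": 0.0, "limit": 1.0}
        if policy not in factors:
            raise ValidationError(
                f"censored policy must be one of {sorted(factors)}, got {policy!r}"
            )
        out = self.values.copy().astype(float)
        mask = self.censored.to_numpy()
        out.values[mask] = out.values[mask] * factors[policy]
        return out


@dataclass(frozen=True)
class DilutionCount:
    """One serial-dilution plating record.

    ``counts`` are replicate colony counts from plates at dilution
    ``10**-dilution_exponent``; ``volume_plated_ml`` of the diluted suspension
    was spread per plate. The original suspension held ``wet_mass_g`` of
    sediment (dry-mass fraction ``dry_mass_fraction``) in
    ``suspension_volume_ml`` of diluent.
    """

    sample_id: str
    medium: str
    condition: str
    counts: tuple[int, ...]
    dilution_exponent: int
    volume_plated_ml: float
    suspension_volume_ml: float
    wet_mass_g: float
    dry_mass_fraction: float

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValidationError("at least one replicate count required")
        if any(c < 0 for c in self.counts):
            raise ValidationError("colony counts must be >= 0")
        if not 0 < self.volume_plated_ml <= self.suspension_volume_ml:
            raise ValidationError(
                "0 < volume_plated <= suspension_volume required"
            )
        if not 0 < self.dry_mass_fraction <= 1:
            raise ValidationError("dry_mass_fraction must be in (0, 1]")
        if not self.wet_mass_g > 0:
            raise ValidationError("wet mass must be > 0")
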