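"""Seeded generators with known ground truth for every pipeline stage.

These emulate the study's raw inputs so the full analysis chain is testable
without downloads: sigmoidal well color development with a turbidity
background and additive truncated-Gaussian noise; Dirichlet-multinomial OTU
tables; Poisson dilution-plate counts; and geochemical tables with planted
group structure and an optional outlier sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ANAEROBIC,
    CultivationCondition,
    DilutionCount,
    EnvTable,
    OtuTable,
    PlateLayout,
    PlateSeries,
    ValidationError,
    logical_to_physical,
)
from .io import default_layout

#: Relative color-development rate by cultivation temperature. Peaked at
#: 20 °C with a sharper drop toward cold than warm, so simulated condition
#: sweeps show the mesophilic ordering 20 > 30 > 10 °C.
DEFAULT_TEMPERATURE_EFFECTS: Mapping[float, float] = {10.0: 0.25, 20.0: 1.0, 30.0: 0.7}


@dataclass
class PlateSimParams:
    """Parameters of the logistic color-development model.

    Each substrate well develops OD590 toward an asymptote A (OD units)
    along a logistic curve with rate r (1/h) and midpoint t_m (h); the
    750 nm channel sees only the turbidity baseline. Anaerobic phases scale
    the asymptote by ``anaerobic_effect``; temperature scales the rate.
    ``asymptotes`` maps logical position -> A for the 31 substrate wells
    (missing positions default to 0, i.e. no activity).
    """

    asymptotes: Mapping[str, float] = field(default_factory=dict)
    rate_per_h: float = 0.06
    midpoint_h: float = 120.0
    temperature_effects: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPERATURE_EFFECTS)
    )
    anaerobic_effect: float = 0.3
    control_level: float = 0.05
    turbidity_baseline: float = 0.04
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.asymptotes.values()):
            raise ValidationError("asymptotes must be >= 0")
        if not self.rate_per_h > 0 or not self.midpoint_h > 0:
            raise ValidationError("rate and midpoint must be > 0")
        if not 0 <= self.anaerobic_effect <= 1:
            raise ValidationError("anaerobic_effect must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def rate_at(self, temperature_c: float) -> float:
        return self.rate_per_h * self.temperature_effects.get(
            float(temperature_c), 1.0
        )


def simulate_plate(
    params: PlateSimParams,
    condition: CultivationCondition,
    sample_id: str = "SIM",
    layout: PlateLayout | None = None,
    n_blocks: int = 3,
) -> PlateSeries:
    """Simulate dual-wavelength reads for one plate under one condition.

    OD590(well, t) = turbidity + control_level + A_eff * logistic(t) + noise
    and OD750(well, t) = turbidity + noise, where A_eff is zero for control
    wells, and scaled by the anaerobic effect while an anaerobic phase is in
    force. Noise is Gaussian, truncated so ODs stay non-negative.
    Deterministic given ``params.seed``.
    """
    if n_blocks not in (1, 2, 3):
        raise ValidationError("n_blocks must be 1, 2, or 3")
    layout = layout or default_layout()
    rng = np.random.default_rng(params.seed)
    r_eff = params.rate_at(condition.temperature_c)
    times = condition.reading_times_h()
    records = []
    for t in times:
        anaerobic = condition.phase_at(t).oxygen == ANAEROBIC
        for block in range(n_blocks):
            for pos in [layout.control_position] + layout.substrate_positions:
                well = logical_to_physical(block, pos)
                a = 0.0 if pos == layout.control_position else float(
                    params.asymptotes.get(pos, 0.0)
                )
                if anaerobic:
                    a *= params.anaerobic_effect
                logistic = 1.0 / (1.0 + np.exp(-r_eff * (t - params.midpoint_h)))
                signal590 = params.turbidity_baseline + params.control_level + a * logistic
                signal750 = params.turbidity_baseline
                for wl, signal in ((590, signal590), (750, signal750)):
                    noise = rng.normal(0, params.noise_sd) if params.noise_sd else 0.0
                    records.append((well, wl, float(t), max(signal + noise, 0.0)))
    data = pd.DataFrame(records, columns=["well", "wavelength_nm", "time_h", "od"])
    return PlateSeries(sample_id=sample_id, condition=condition,
                       layout=layout, data=data)


@dataclass
class CommunitySimParams:
    """Dirichlet-multinomial community model: per-sample compositions drawn
    from a Dirichlet prior, read counts multinomial at each library size."""

    n_samples: int = 8
    n_taxa: int = 50
    concentration: Sequence[float] | float = 0.5
    library_sizes: Sequence[int] | int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.atleast_1d(np.asarray(self.concentration, dtype=float))
        if (conc <= 0).any():
            raise ValidationError("concentrations must be > 0")
        libs = np.atleast_1d(np.asarray(self.library_sizes, dtype=int))
        if (libs < 1).any():
            raise ValidationError("library sizes must be >= 1")

    def concentration_vector(self) -> np.ndarray:
        conc = np.atleast_1d(np.asarray(self.concentration, dtype=float))
        if conc.size == 1:
            conc = np.full(self.n_taxa, conc[0])
        if conc.size != self.n_taxa:
            raise ValidationError("concentration vector length must equal n_taxa")
        return conc

    def library_size_vector(self) -> np.ndarray:
        libs = np.atleast_1d(np.asarray(self.library_sizes, dtype=int))
        if libs.size == 1:
            libs = np.full(self.n_samples, libs[0])
        if libs.size != self.n_samples:
            raise ValidationError("library size vector length must equal n_samples")
        return libs


def simulate_otu_table(params: CommunitySimParams) -> OtuTable:
    """Draw a taxa-by-samples count table from the Dirichlet-multinomial
    model; library sizes are hit exactly. Deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    conc = params.concentration_vector()
    libs = params.library_size_vector()
    taxa = [f"Genus_{i + 1:03d}" for i in range(params.n_taxa)]
    samples = [f"S{i + 1}" for i in range(params.n_samples)]
    counts = {}
    for s, lib in zip(samples, libs):
        p = rng.dirichlet(conc)
        counts[s] = rng.multinomial(int(lib), p)
    return OtuTable(counts=pd.DataFrame(counts, index=taxa))


def simulate_dilution_counts(
    true_cfu_per_g_dm: float, rec_template: DilutionCount, seed: int = 0
) -> DilutionCount:
    """Replace a record's replicate counts with Poisson draws whose mean
    corresponds to ``true_cfu_per_g_dm`` under the template's dilution,
    volumes, and masses."""
    if not true_cfu_per_g_dm >= 0:
        raise ValidationError("true concentration must be >= 0")
    rng = np.random.default_rng(seed)
    t = rec_template
    dry_mass = t.wet_mass_g * t.dry_mass_fraction
    mean = (
        true_cfu_per_g_dm * dry_mass / t.suspension_volume_ml
        * t.volume_plated_ml / 10.0 ** t.dilution_exponent
    )
    counts = tuple(int(c) for c in rng.poisson(mean, size=len(t.counts)))
    return DilutionCount(
        sample_id=t.sample_id, medium=t.medium, condition=t.condition,
        counts=counts, dilution_exponent=t.dilution_exponent,
        volume_plated_ml=t.volume_plated_ml,
        suspension_volume_ml=t.suspension_volume_ml,
        wet_mass_g=t.wet_mass_g, dry_mass_fraction=t.dry_mass_fraction,
    )


def simulate_env_table(
    n_groups: int = 2,
    samples_per_group: int = 4,
    separation: float = 6.0,
    n_parameters: int = 10,
    outlier: bool = False,
    seed: int = 0,
) -> EnvTable:
    """Geochemical table with planted cluster structure.

    Group g's samples are centered at ``g * separation`` on every parameter
    with unit-variance Gaussian noise; sample ids encode the planted group
    (``G<g>_<i>``). With ``outlier=True`` one extra sample (``OUT``) is
    displaced by 3 x separation below group 0, forcing it to be the most
    dissimilar sample.
    """
    if n_groups < 2:
        raise ValidationError("need >= 2 groups")
    if not separation >= 0:
        raise ValidationError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    parameters = [f"param_{j + 1:02d}" for j in range(n_parameters)]
    cols = {}
    for g in range(n_groups):
        for i in range(samples_per_group):
            cols[f"G{g + 1}_{i + 1}"] = g * separation + rng.normal(0, 1, n_parameters)
    if outlier:
        cols["OUT"] = -3.0 * separation + rng.normal(0, 1, n_parameters)
    values = pd.DataFrame(cols, index=parameters)
    return EnvTable(
        values=values,
        units=pd.Series("a.u.", index=values.index),
        censored=pd.DataFrame(False, index=values.index, columns=values.columns),
    )
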