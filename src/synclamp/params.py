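"""Strain and plant parameters for the simulated yeast population.

The simulator stands in for budding-yeast cells expressing an
aggregation-prone protein (an alpha-synuclein-GFP fusion) from the
galactose-inducible GAL1 promoter, with a constitutive mCherry reporter
used for normalization.  Strain-specific defaults (aggregation-threshold
mean and dispersion, cell-cycle means before/after inclusion formation,
aggregation delay, arrest fraction) are the values measured for the
wild-type (WT) and disease-associated A53T strains; free kinetic rates of
the GAL1 promoter are the package's own calibration, chosen so that a
closed-loop experiment can reach and hold the 2-18 normalized-unit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

STRAINS = ("WT", "A53T", "A53T_dpdr5")
TREATMENTS = ("untreated", "rapamycin", "PMSF", "MG132")

#: strain -> (threshold_mean n.u., threshold_cv, cycle_pre min, cycle_post min,
#:            aggregation_delay_mean min, arrest_fraction)
_STRAIN_TABLE = {
    "WT": (13.1, 0.18, 110.0, 145.0, 12.0, 0.06),
    "A53T": (7.4, 0.28, 96.0, 140.0, 20.0, 0.11),
    # the pdr5-deletion strain used for drug treatments behaves as A53T
    "A53T_dpdr5": (7.4, 0.28, 96.0, 140.0, 20.0, 0.11),
}


@dataclass
class PlantParams:
    """Parameters of the stochastic cell-population simulator.

    Rates are per minute; fluorescence is carried directly in normalized
    units (n.u., i.e. already divided by the per-cell mCherry scale).
    """

    strain: str = "WT"
    # induction kinetics (free parameters, not measured by the study)
    production_rate_gal: float = 0.30   # n.u./min at full galactose (u=1)
    basal_rate: float = 0.0             # n.u./min under glucose
    maturation_or_decay_rate: float = 0.01  # 1/min effective first-order loss
    # division
    division_shed_fraction: float = 0.38    # fraction of fluorescence shed to the bud
    cycle_mean_pre: float = 110.0       # min, before aggregation
    cycle_mean_post: float = 145.0      # min, after aggregation
    cycle_sd: float = 12.0              # min
    budded_fraction: float = 0.6        # fraction of the cycle spent budded (S-G2-M)
    # aggregation
    threshold_mean: float = 13.1        # n.u., per-cell aggregation threshold mean
    threshold_cv: float = 0.18
    aggregation_delay_mean: float = 12.0  # min above threshold before inclusions appear
    arrest_fraction: float = 0.06       # cells that stop dividing after aggregation
    # clearance experiments
    clearance_tfb_multiplier: dict[str, float] = field(
        default_factory=lambda: {
            "untreated": 1.0, "rapamycin": 0.5, "PMSF": 2.5, "MG132": 1.5,
        }
    )
    tfb_base_mean: float = 130.0        # min, untreated time-to-first-bud scale
    tfb_cv: float = 0.35
    mg132_cycle_factor: float = 1.4     # MG132 lengthens the cell cycle
    clearance_disappear_level: float = 0.35  # n.u. below which inclusions dissolve
    # noise
    extrinsic_noise_cv: float = 0.25    # cell-to-cell CV of the production rate
    sample_noise_cv: float = 0.02       # per-sampling-period multiplicative jitter
    mcherry_mean: float = 100.0         # a.u., constitutive reporter
    position_jitter_px: float = 0.5     # per-sampling-period centroid wobble
    # bookkeeping
    chamber_capacity: int = 120         # cells retained in the monolayer field of view
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}; expected one of {STRAINS}")
        for name in ("production_rate_gal", "basal_rate", "maturation_or_decay_rate",
                     "threshold_cv", "extrinsic_noise_cv", "sample_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.division_shed_fraction < 1.0:
            raise ValueError("division_shed_fraction must lie in (0, 1)")
        if self.cycle_mean_pre <= 0 or self.cycle_mean_post <= 0:
            raise ValueError("cycle means must be positive")
        if not 0.0 < self.budded_fraction < 1.0:
            raise ValueError("budded_fraction must lie in (0, 1)")
        missing = set(TREATMENTS) - set(self.clearance_tfb_multiplier)
        if missing:
            raise ValueError(f"clearance_tfb_multiplier missing treatments: {sorted(missing)}")

    @classmethod
    def for_strain(cls, strain: str, **overrides) -> "PlantParams":
        """Parameters with the measured defaults of one strain."""
        if strain not in _STRAIN_TABLE:
            raise ValueError(f"unknown strain {strain!r}; expected one of {STRAINS}")
        tm, tcv, pre, post, delay, arrest = _STRAIN_TABLE[strain]
        base = cls(strain=strain, threshold_mean=tm, threshold_cv=tcv,
                   cycle_mean_pre=pre, cycle_mean_post=post,
                   aggregation_delay_mean=delay, arrest_fraction=arrest)
        return replace(base, **overrides) if overrides else base
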