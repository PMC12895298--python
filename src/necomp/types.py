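"""Record-level domain types.

The pipeline moves tables around as :class:`pandas.DataFrame`; these
dataclasses define the per-record contract (fields, units, invariants) and
are used wherever single records are manipulated or validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import InvalidInputError

MUTATION_METHODS = ("pedigree", "mutation_accumulation")
SITE_CLASSES = ("genome_wide", "synonymous")
SAMPLING_SCOPES = ("single_population", "range_wide", "unknown")
GROUPS = (
    "mammals",
    "birds",
    "reptiles",
    "fish",
    "arthropods",
    "fungi",
    "plants",
    "protists",
    "other",
)
REPRODUCTIVE_MODES = ("sexual", "asexual")


@dataclass
class MutationRateEstimate:
    """One study's per-site, per-generation mutation rate.

    ``effort`` is the study weight: number of trios for pedigree studies,
    lines x generations for mutation-accumulation studies.
    """

    species_id: str
    rate: float
    n_mutations: Optional[int] = None
    callable_sites: Optional[int] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    effort: float = 1.0
    method: str = "pedigree"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InvalidInputError(f"{self.species_id}: rate must be >= 0")
        if self.effort <= 0:
            raise InvalidInputError(f"{self.species_id}: effort must be > 0")
        if self.method not in MUTATION_METHODS:
            raise InvalidInputError(f"unknown method {self.method!r}")
        if self.callable_sites is not None and self.callable_sites <= 0:
            raise InvalidInputError(
                f"{self.species_id}: callable_sites must be > 0"
            )
        if self.n_mutations is not None and self.n_mutations < 0:
            raise InvalidInputError(
                f"{self.species_id}: n_mutations must be >= 0"
            )
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.rate <= self.ci_high):
                raise InvalidInputError(
                    f"{self.species_id}: CI ({self.ci_low}, {self.ci_high}) "
                    f"does not bracket rate {self.rate}"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None

    def se(self) -> Optional[float]:
        """Standard error from the CI half-width (normal 95% convention)."""
        if not self.has_ci:
            return None
        return (self.ci_high - self.ci_low) / (2.0 * 1.96)


@dataclass
class DiversityEstimate:
    """One population/study nucleotide-diversity (pi) value."""

    species_id: str
    pi: float
    site_class: str = "genome_wide"
    theta_w: Optional[float] = None
    population_label: str = ""
    sampling_scope: str = "unknown"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi < 1.0):
            raise InvalidInputError(
                f"{self.species_id}: pi must be in [0, 1), got {self.pi}"
            )
        if self.site_class not in SITE_CLASSES:
            raise InvalidInputError(f"unknown site_class {self.site_class!r}")
        if self.theta_w is not None and self.theta_w < 0:
            raise InvalidInputError(f"{self.species_id}: theta_w must be >= 0")
        if self.sampling_scope not in SAMPLING_SCOPES:
            raise InvalidInputError(
                f"unknown sampling_scope {self.sampling_scope!r}"
            )


@dataclass
class SpeciesRecord:
    """Species metadata: ploidy (the x of Ne = pi / (2 x mu)), taxonomic
    group, reproductive mode and the domestication exclusion flag."""

    species_id: str
    ploidy: int = 2
    group: str = "other"
    reproductive_mode: str = "sexual"
    domesticated: bool = False

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise InvalidInputError(f"{self.species_id}: ploidy must be >= 1")
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.reproductive_mode not in REPRODUCTIVE_MODES:
            raise InvalidInputError(
                f"unknown reproductive_mode {self.reproductive_mode!r}"
            )


@dataclass
class NeEstimate:
    """A species-level long-term effective population size with the CI
    propagated from the mutation-rate uncertainty."""

    species_id: str
    ne: float
    ci_low: float
    ci_high: float
    mu_used: float
    pi_used: float
    log10_ne_variance: float = float("nan")
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise InvalidInputError(f"{self.species_id}: ne must be > 0")
        if not (self.ci_low <= self.ne <= self.ci_high):
            raise InvalidInputError(
                f"{self.species_id}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket ne {self.ne}"
            )


@dataclass
class HeterogeneityResult:
    """Cochran's Q test result for one taxonomic group."""

    group: str
    q: float
    df: int
    p: float
    weighted_mean_log_ne: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.q < 0 or self.df < 0 or not (0.0 <= self.p <= 1.0):
            raise InvalidInputError("invalid heterogeneity result")


@dataclass
class GroupSummary:
    """Per-group Ne summary: count, median, extremes, optional log-normal fit."""

    group: str
    n: int
    median_ne: float
    min_ne: float
    max_ne: float
    min_species: str
    max_species: str
    lognormal_meanlog: Optional[float] = None
    lognormal_sdlog: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.min_ne <= self.median_ne <= self.max_ne):
            raise InvalidInputError(
                f"{self.group}: min <= median <= max violated"
            )


@dataclass
class TraitRecord:
    """Raw life-history / demographic / genomic traits for one species.

    Units are normalized at ingest: masses in grams, lengths in cm,
    areas in km^2, densities per km^2, longevity and generation time in
    years, genome size in pg.
    """

    species_id: str
    generation_time: Optional[float] = None
    adult_body_mass: Optional[float] = None
    adult_body_length: Optional[float] = None
    mass_at_weaning: Optional[float] = None
    max_longevity: Optional[float] = None
    propagule_size: Optional[float] = None
    range_area: Optional[float] = None
    density: Optional[float] = None
    genome_c_value: Optional[float] = None
    pi_n: Optional[float] = None
    pi_s: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "generation_time",
            "adult_body_mass",
            "adult_body_length",
            "mass_at_weaning",
            "max_longevity",
            "propagule_size",
            "range_area",
            "density",
            "genome_c_value",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidInputError(
                    f"{self.species_id}: {name} must be > 0, got {v}"
                )
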