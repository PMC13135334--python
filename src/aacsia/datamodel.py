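"""Core data model for amino-acid compound-specific isotope data.

A dataset is a collection of samples; each sample carries per-amino-acid
isotope measurements (the mean of triplicate GC-IRMS injections, its
replicate standard deviation, and the replicate count) for one or both
isotope systems (d13C, d15N), plus collection metadata (habitat, distance
from shore, tow depth, season, year).

Amino acids are identified by three-letter codes; Glx and Asx denote the
combined glutamine+glutamate and asparagine+aspartate pools produced by
acid hydrolysis. Functional roles:

* EAA (essential amino acids, carbon work): Ile, Leu, Lys, Phe, Thr, Val.
  Their d13C values trace primary-producer carbon with minimal trophic
  fractionation and form the "fingerprint" feature space.
* SAA (source amino acids, nitrogen work): Phe, Lys. Their d15N values
  record the nitrogen baseline, changing little per trophic step.
* TAA (trophic amino acids): Glx, Ala. Their d15N values enrich
  systematically with each trophic transfer and anchor trophic-position
  estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import DomainError, SchemaError

#: All amino-acid codes the data model accepts.
AMINO_ACIDS: frozenset[str] = frozenset(
    {"Ala", "Gly", "Thr", "Ser", "Val", "Leu", "Ile", "Pro",
     "Met", "Phe", "Tyr", "Lys", "Asx", "Glx"}
)

#: Essential amino acids used for d13C fingerprinting (canonical order).
EAA_CARBON: tuple[str, ...] = ("Ile", "Leu", "Lys", "Phe", "Thr", "Val")

#: Five-EAA subset used when Ile is unavailable (e.g. literature datasets
#: that did not report it).
EAA_CARBON_NO_ILE: tuple[str, ...] = ("Leu", "Lys", "Phe", "Thr", "Val")

#: Source amino acids for d15N baseline work.
SAA_NITROGEN: tuple[str, ...] = ("Phe", "Lys")

#: Trophic amino acids for trophic-position estimation.
TAA_NITROGEN: tuple[str, ...] = ("Glx", "Ala")

ISOTOPES: tuple[str, ...] = ("d13C", "d15N")

#: Habitat labels. Reef: within 1 km of shore over coral reefs.
#: Offshore surface: >= 1 km from shore, tow depth 0-200 m.
#: Offshore deep: >= 1 km from shore, tow depth > 200 m.
HABITATS: tuple[str, ...] = ("reef", "offshore_surface", "offshore_deep")

REEF_DISTANCE_KM: float = 1.0
SURFACE_DEPTH_M: float = 200.0


def assign_habitat(distance_km: float, tow_depth_m: float) -> str:
    """Assign a habitat label from distance-from-shore and tow depth.

    Parameters
    ----------
    distance_km : float
        Distance from the nearest shoreline in km; must be > 0.
    tow_depth_m : float
        Tow (collection) depth in m; must be >= 0. Ignored for reef
        assignments, since reef tows are surface tows over reefs.

    Returns
    -------
    str
        ``"reef"`` if distance < 1 km; ``"offshore_surface"`` if
        distance >= 1 km and depth <= 200 m; ``"offshore_deep"`` if
        distance >= 1 km and depth > 200 m.
    """
    if not (distance_km > 0):
        raise DomainError(f"distance_km must be > 0, got {distance_km}")
    if tow_depth_m < 0:
        raise DomainError(f"tow_depth_m must be >= 0, got {tow_depth_m}")
    if distance_km < REEF_DISTANCE_KM:
        return "reef"
    if tow_depth_m <= SURFACE_DEPTH_M:
        return "offshore_surface"
    return "offshore_deep"


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One amino acid's isotope value for one isotope system.

    ``value`` is the mean of triplicate injections in per-mil (permil)
    delta notation; ``sd`` the triplicate standard deviation; ``n_reps``
    the replicate count.
    """

    isotope: str
    value: float
    sd: float = 0.0
    n_reps: int = 1

    def __post_init__(self):
        if self.isotope not in ISOTOPES:
            raise SchemaError(f"unknown isotope system {self.isotope!r}")
        if not _finite(self.value):
            raise DomainError(f"non-finite delta value {self.value!r}")
        if not _finite(self.sd) or self.sd < 0:
            raise DomainError(f"sd must be finite and >= 0, got {self.sd!r}")
        if self.n_reps < 1:
            raise DomainError(f"n_reps must be >= 1, got {self.n_reps}")


@dataclass
class SampleRecord:
    """A zooplankton/consumer sample with metadata and measurements.

    Measurements are keyed by ``(amino_acid, isotope)``; a missing key
    means the value was never measured (no sentinel numbers).
    """

    sample_id: str
    distance_km: float | None = None
    tow_depth_m: float | None = None
    habitat: str | None = None
    season: str | None = None
    year: int | None = None
    size_fraction: str | None = None
    measurements: dict[tuple[str, str], IsotopeMeasurement] = field(default_factory=dict)

    def __post_init__(self):
        if self.habitat is not None and self.habitat not in HABITATS:
            raise SchemaError(
                f"sample {self.sample_id!r}: unknown habitat {self.habitat!r}"
            )
        if self.distance_km is not None and not (self.distance_km > 0):
            raise DomainError(
                f"sample {self.sample_id!r}: distance_km must be > 0"
            )
        if self.tow_depth_m is not None and self.tow_depth_m < 0:
            raise DomainError(
                f"sample {self.sample_id!r}: tow_depth_m must be >= 0"
            )

    def set(self, amino_acid: str, isotope: str, value: float,
            sd: float = 0.0, n_reps: int = 1) -> None:
        """Attach a measurement, rejecting unknown codes and duplicates."""
        if amino_acid not in AMINO_ACIDS:
            raise SchemaError(f"unknown amino-acid code {amino_acid!r}")
        key = (amino_acid, isotope)
        if key in self.measurements:
            raise SchemaError(
                f"duplicate measurement ({self.sample_id}, {amino_acid}, {isotope})"
            )
        self.measurements[key] = IsotopeMeasurement(isotope, value, sd, n_reps)

    def get(self, amino_acid: str, isotope: str) -> IsotopeMeasurement | None:
        return self.measurements.get((amino_acid, isotope))

    def has(self, amino_acid: str, isotope: str) -> bool:
        return (amino_acid, isotope) in self.measurements

    def value(self, amino_acid: str, isotope: str) -> float:
        m = self.get(amino_acid, isotope)
        if m is None:
            raise KeyError((self.sample_id, amino_acid, isotope))
        return m.value

    def assign_habitat_from_metadata(self) -> str:
        """Set (and return) the habitat implied by distance and depth."""
        if self.distance_km is None:
            raise DomainError(
                f"sample {self.sample_id!r}: cannot assign habitat without distance_km"
            )
        depth = self.tow_depth_m if self.tow_depth_m is not None else 0.0
        self.habitat = assign_habitat(self.distance_km, depth)
        return self.habitat


@dataclass
class Dataset:
    """An ordered collection of samples with free-text provenance."""

    records: list[SampleRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [r.sample_id for r in self.records]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise SchemaError(f"duplicate sample_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def require_nonempty(self, context: str = "analysis") -> None:
        if not self.records:
            raise SchemaError(f"empty dataset: {context} requires >= 1 record")

    def get(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, sample_ids) -> "Dataset":
        wanted = set(sample_ids)
        return Dataset(
            records=[r for r in self.records if r.sample_id in wanted],
            provenance=self.provenance,
        )


def _finite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))
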