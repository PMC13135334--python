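"""Within-sample mean-centering of essential amino acid d13C values.

For each essential amino acid j in a sample, the centered value is

    d13C_j,centered = d13C_j - mean(d13C over the chosen EAA set)

which removes the sample-specific baseline offset (growth conditions,
analytical batch, bulk carbon source) while preserving the relative
pattern among amino acids — the producer "fingerprint" conserved through
trophic transfer. Centering is carried out on triplicate-mean values;
replicate SDs are not re-centered.

The EAA set is configurable: six (Ile, Leu, Lys, Phe, Thr, Val) for full
fingerprints, five (dropping Ile) when comparing against datasets that
did not report it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import EAA_CARBON, Dataset, SampleRecord
from .exceptions import EmptyResultError, IncompleteProfileError, SchemaError


@dataclass(frozen=True)
class CenteredProfile:
    """A sample's mean-centered d13C EAA fingerprint.

    ``centered_values[aa] = d13C_aa - sample_mean``; the centered values
    sum to zero by construction (within 1e-9 permil).
    """

    sample_id: str
    aa_set: tuple[str, ...]
    centered_values: dict[str, float]
    sample_mean: float

    @property
    def n(self) -> int:
        return len(self.aa_set)

    def as_vector(self) -> list[float]:
        return [self.centered_values[aa] for aa in self.aa_set]


def mean_center(record: SampleRecord, aa_set=EAA_CARBON) -> CenteredProfile:
    """Mean-center one sample's d13C values over ``aa_set``.

    Raises :class:`IncompleteProfileError` naming the first amino acid in
    ``aa_set`` lacking a d13C measurement. The input record is not
    modified.
    """
    aa_set = tuple(aa_set)
    if not aa_set:
        raise SchemaError("aa_set must be non-empty")
    values = {}
    for aa in aa_set:
        m = record.get(aa, "d13C")
        if m is None:
            raise IncompleteProfileError(
                f"sample {record.sample_id!r}: missing d13C for {aa}"
            )
        values[aa] = m.value
    mean = sum(values.values()) / len(aa_set)
    centered = {aa: v - mean for aa, v in values.items()}
    return CenteredProfile(record.sample_id, aa_set, centered, mean)


def mean_center_dataset(dataset: Dataset, aa_set=EAA_CARBON):
    """Mean-center every record holding the full ``aa_set``.

    Returns ``(profiles, skipped)`` where ``skipped`` is a list of
    ``(sample_id, reason)`` pairs for records lacking any required amino
    acid. Raises :class:`EmptyResultError` if no record qualifies.
    """
    aa_set = tuple(aa_set)
    if not aa_set:
        raise SchemaError("aa_set must be non-empty")
    dataset.require_nonempty("mean_center_dataset")
    profiles: list[CenteredProfile] = []
    skipped: list[tuple[str, str]] = []
    for rec in dataset:
        try:
            profiles.append(mean_center(rec, aa_set))
        except IncompleteProfileError as exc:
            skipped.append((rec.sample_id, str(exc)))
    if not profiles:
        raise EmptyResultError(
            f"no record holds d13C for the full EAA set {aa_set}"
        )
    return profiles, skipped
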